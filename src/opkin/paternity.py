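"""Paternity assignment for open-pollinated offspring with a known mother.

Three complementary methods, plus their consensus:

**ASR (abnormal-SNP-ratio) exclusion.**  For each offspring x candidate-father
couple, the ASR is the fraction of trio-complete loci at which the offspring
carries an allele present in neither the mother nor the hypothetical father.
The true couple has an ASR near the genotyping error rate; false couples score
an order of magnitude higher.  The exclusion cutline is placed just below the
lower edge of the distribution of each offspring's *second smallest* ASR
(ssASR): the smallest ASR belongs to the true couple, so the ssASR marks the
start of the false-couple mass.  Offspring whose ASR is uniformly low against
*every* candidate are selfings -- all their alleles come from the mother, so no
father can look abnormal.

**IBS (identity-by-state) ranking.**  Allele sharing between two samples,
scored per locus as 1 (identical unordered genotypes), 0.5 (one shared
allele), 0 (opposite homozygotes) and averaged.  The acceptance threshold is
derived from the known mother-offspring pairs (their minimum IBS, rounded
down to two decimals); an offspring's IBS with the mother above a higher bound
signals selfing.

**Trio-likelihood (LOD / delta).**  Per locus, the likelihood of the offspring
genotype given mother and candidate father (with an error model that replaces
a mistyped genotype by a Hardy-Weinberg draw) is compared with the likelihood
given the mother and a random father from the population.  The LOD is the sum
of log ratios; delta is the LOD gap between the best and second-best
candidate, compared against a critical value calibrated by simulating
offspring at the observed allele frequencies.  A replicate of the mother added
to the candidate list flags selfings.

The consensus calls a father (or selfing) only when the three methods agree.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, UndefinedValueError
from .matrix import MISSING, GenotypeMatrix
from .simulate import EXTERNAL, SELFING, UNASSIGNED, _hwe_draw, mate

log = logging.getLogger(__name__)

#: named default thresholds (each with a derivation helper where one exists)
DEFAULT_ASR_CUTLINE = 0.02      # see suggest_asr_cutline
DEFAULT_ASR_SELFING = 0.008     # uniform-row bound flagging mother selfing
DEFAULT_IBS_THRESHOLD = 0.72    # see derive_ibs_threshold
DEFAULT_IBS_SELFING = 0.84      # mother-offspring IBS above this -> selfing
DEFAULT_ERROR_RATE = 0.01

METHOD_ASR = "ASR"
METHOD_IBS = "IBS"
METHOD_LIKELIHOOD = "LIKELIHOOD"

_RECORD_COLUMNS = ["offspring", "method", "verdict", "score", "threshold_used"]


# ---------------------------------------------------------------------------
# ASR


def _has_ref(g: np.ndarray) -> np.ndarray:
    return (g == 0) | (g == 1)


def _has_alt(g: np.ndarray) -> np.ndarray:
    return (g == 1) | (g == 2)


def _abnormal_mask(off: np.ndarray, mo: np.ndarray, fa: np.ndarray,
                   mode: str) -> tuple[np.ndarray, np.ndarray]:
    """(informative, abnormal) boolean masks; arrays broadcast together."""
    informative = (off != MISSING) & (mo != MISSING) & (fa != MISSING)
    if mode == "allele":
        parents_ref = _has_ref(mo) | _has_ref(fa)
        parents_alt = _has_alt(mo) | _has_alt(fa)
        abnormal = ((_has_ref(off) & ~parents_ref)
                    | (_has_alt(off) & ~parents_alt))
    elif mode == "mendelian":
        # strict transmission check: offspring genotype impossible as one
        # allele from each parent
        pm, pf = mo / 2.0, fa / 2.0
        t = np.select(
            [off == 0, off == 1, off == 2],
            [(1 - pm) * (1 - pf), pm + pf - 2 * pm * pf, pm * pf], 0.0)
        abnormal = t == 0.0
    else:
        raise ValueError(f"unknown ASR mode {mode!r}")
    return informative, abnormal & informative


def compute_asr(matrix: GenotypeMatrix, offspring: str, mother: str,
                father: str, mode: str = "allele") -> tuple[float, int]:
    """Abnormal-SNP ratio of one trio and its informative-locus count.

    A locus is informative iff all three calls are non-missing; it is abnormal
    (default ``allele`` mode) iff some offspring allele occurs in neither
    parent's call.  ``mendelian`` mode instead flags loci where the offspring
    genotype is impossible under strict biparental transmission.
    """
    off = matrix.row(offspring)
    mo = matrix.row(mother)
    fa = matrix.row(father)
    informative, abnormal = _abnormal_mask(off, mo, fa, mode)
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise UndefinedValueError(
            f"trio ({offspring}, {mother}, {father}) has no informative loci")
    return float(abnormal.sum() / n_inf), n_inf


@dataclasses.dataclass
class CoupleAsrMatrix:
    """Offspring x candidate-father grid of ASR values (NaN when a cell had no
    informative loci) plus the per-cell informative-locus counts."""

    asr: pd.DataFrame
    informative: pd.DataFrame

    @property
    def offspring(self) -> list[str]:
        return list(self.asr.index)

    @property
    def fathers(self) -> list[str]:
        return list(self.asr.columns)


def asr_matrix(matrix: GenotypeMatrix, mother: str, fathers: Sequence[str],
               offspring: Sequence[str], mode: str = "allele") -> CoupleAsrMatrix:
    """ASR of every offspring against every hypothetical (mother, father) couple."""
    off_idx = [matrix.sample_index(o) for o in offspring]
    off_g = matrix.geno[off_idx]                      # (n_off, L)
    mo_g = matrix.row(mother)[None, :]
    asr = np.full((len(offspring), len(fathers)), np.nan)
    inf = np.zeros((len(offspring), len(fathers)), dtype=np.int64)
    for k, fid in enumerate(fathers):
        fa_g = matrix.row(fid)[None, :]
        informative, abnormal = _abnormal_mask(off_g, mo_g, fa_g, mode)
        n_inf = informative.sum(axis=1)
        inf[:, k] = n_inf
        with np.errstate(invalid="ignore", divide="ignore"):
            asr[:, k] = np.where(n_inf > 0, abnormal.sum(axis=1) / n_inf, np.nan)
    n_nan = int(np.isnan(asr).sum())
    if n_nan:
        log.warning("asr_matrix: %d couple cells had no informative loci", n_nan)
    idx = pd.Index(list(offspring), name="offspring")
    cols = pd.Index(list(fathers), name="father")
    return CoupleAsrMatrix(pd.DataFrame(asr, index=idx, columns=cols),
                           pd.DataFrame(inf, index=idx, columns=cols))


def ssasr(couple_asr: CoupleAsrMatrix) -> pd.Series:
    """Second-smallest ASR of each offspring across candidate couples."""
    if len(couple_asr.fathers) < 2:
        raise ComputationError("ssASR needs at least two candidate fathers")
    vals = couple_asr.asr.to_numpy()
    out = np.full(vals.shape[0], np.nan)
    for i in range(vals.shape[0]):
        row = np.sort(vals[i][~np.isnan(vals[i])])
        if len(row) >= 2:
            out[i] = row[1]
        else:
            log.warning("ssasr: offspring %s has < 2 ASR values",
                        couple_asr.offspring[i])
    return pd.Series(out, index=couple_asr.asr.index, name="ssasr")


def suggest_asr_cutline(ssasr_values: Iterable[float],
                        default: float = DEFAULT_ASR_CUTLINE) -> float:
    """Gap-based cutline below the main ssASR mass.

    Sorts the values and looks for the widest gap between consecutive values
    whose midpoint lies in the lower half of the observed range -- the gap
    separating true-couple-like low values from the false-couple mass.
    Returns the gap midpoint, or ``default`` when no gap exceeds twice the
    median spacing (no separation evident).
    """
    vals = np.sort(np.asarray([v for v in ssasr_values if not np.isnan(v)]))
    if len(vals) < 10:
        raise ComputationError("need at least 10 ssASR values")
    rng_lo, rng_hi = vals[0], vals[-1]
    if rng_hi == rng_lo:
        return default
    gaps = np.diff(vals)
    mids = (vals[:-1] + vals[1:]) / 2.0
    in_lower = mids <= rng_lo + (rng_hi - rng_lo) / 2.0
    if not in_lower.any():
        return default
    k = int(np.flatnonzero(in_lower)[np.argmax(gaps[in_lower])])
    median_spacing = float(np.median(gaps))
    if gaps[k] <= 2.0 * median_spacing:
        return default
    return float(mids[k])


def assign_by_asr(couple_asr: CoupleAsrMatrix,
                  cutline: float = DEFAULT_ASR_CUTLINE,
                  selfing_bound: float = DEFAULT_ASR_SELFING) -> pd.DataFrame:
    """Per-offspring ASR verdicts.

    Selfing iff every couple in the row scores below ``selfing_bound``
    (no father can be excluded because all offspring alleles are maternal);
    otherwise the row-minimum father is called iff its ASR is below the
    cutline, with ties left unassigned.
    """
    if not cutline > selfing_bound > 0:
        raise ValueError("need cutline > selfing_bound > 0")
    vals = couple_asr.asr.to_numpy()
    fathers = couple_asr.fathers
    rows = []
    for i, oid in enumerate(couple_asr.offspring):
        row = vals[i]
        ok = ~np.isnan(row)
        if ok.all() and (row < selfing_bound).all():
            rows.append((oid, METHOD_ASR, SELFING, float(row.max()),
                         selfing_bound))
            continue
        if not ok.any():
            rows.append((oid, METHOD_ASR, UNASSIGNED, np.nan, cutline))
            continue
        best = np.nanmin(row)
        ties = np.flatnonzero(ok & (row == best))
        if best < cutline and len(ties) == 1:
            rows.append((oid, METHOD_ASR, fathers[ties[0]], float(best), cutline))
        else:
            rows.append((oid, METHOD_ASR, UNASSIGNED, float(best), cutline))
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def asr_couple_tally(couple_asr: CoupleAsrMatrix,
                     cutline: float = DEFAULT_ASR_CUTLINE) -> pd.Series:
    """Per-father count of offspring passing the cutline (an offspring may
    count under several fathers, as in an exclusion-table presentation)."""
    below = couple_asr.asr.lt(cutline)
    return below.sum(axis=0).rename("asr_tally")


# ---------------------------------------------------------------------------
# IBS


def _ibs_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedValueError("no loci with both samples called")
    score = 1.0 - np.abs(a[ok].astype(np.int16) - b[ok]) / 2.0
    return float(score.mean()), n


def compute_ibs(matrix: GenotypeMatrix, a: str, b: str) -> tuple[float, int]:
    """Mean allele sharing by state between two samples and the locus count.

    Per locus with both calls present: 1 for identical unordered genotypes,
    0.5 for one shared allele, 0 for opposite homozygotes (equivalently
    ``1 - |dose_a - dose_b| / 2``).
    """
    return _ibs_pair(matrix.row(a), matrix.row(b))


def ibs_table(matrix: GenotypeMatrix, rows: Sequence[str],
              cols: Sequence[str]) -> pd.DataFrame:
    """IBS for every (row sample, column sample) pair; NaN when no shared loci."""
    rg = matrix.geno[[matrix.sample_index(s) for s in rows]]
    cg = matrix.geno[[matrix.sample_index(s) for s in cols]]
    ok = (rg[:, None, :] != MISSING) & (cg[None, :, :] != MISSING)
    diff = np.abs(rg[:, None, :].astype(np.int16) - cg[None, :, :])
    score = np.where(ok, 1.0 - diff / 2.0, 0.0).sum(axis=2)
    n = ok.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(n > 0, score / n, np.nan)
    return pd.DataFrame(vals, index=pd.Index(list(rows), name="sample"),
                        columns=pd.Index(list(cols), name="candidate"))


def derive_ibs_threshold(matrix: GenotypeMatrix,
                         known_pairs: Sequence[tuple[str, str]]) -> float:
    """Exclusion threshold from known parent-offspring pairs: their minimum
    IBS rounded down to two decimals."""
    if len(known_pairs) < 5:
        raise ComputationError("need at least 5 known parent-offspring pairs")
    vals = [compute_ibs(matrix, a, b)[0] for a, b in known_pairs]
    return float(np.floor(min(vals) * 100.0) / 100.0)


def assign_by_ibs(matrix: GenotypeMatrix, mother: str, fathers: Sequence[str],
                  offspring: Sequence[str],
                  threshold: float = DEFAULT_IBS_THRESHOLD,
                  selfing_bound: float = DEFAULT_IBS_SELFING) -> pd.DataFrame:
    """Per-offspring IBS verdicts.

    Selfing iff IBS with the mother exceeds ``selfing_bound``.  Otherwise the
    top candidate father is accepted iff his IBS is at least ``threshold`` and
    the mother ranks among the top two candidates overall (mother included),
    i.e. the putative parental couple is (mother, that father).  Ties at the
    top are left unassigned.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if not selfing_bound > threshold:
        raise ValueError("selfing_bound must exceed the acceptance threshold")
    tab = ibs_table(matrix, offspring, [mother] + list(fathers))
    vals = tab.to_numpy()
    rows = []
    for i, oid in enumerate(offspring):
        ibs_mother = vals[i, 0]
        cand = vals[i, 1:]
        if np.isnan(ibs_mother) or np.isnan(cand).all():
            rows.append((oid, METHOD_IBS, UNASSIGNED, np.nan, threshold))
            continue
        if ibs_mother > selfing_bound:
            rows.append((oid, METHOD_IBS, SELFING, float(ibs_mother),
                         selfing_bound))
            continue
        best = np.nanmax(cand)
        ties = np.flatnonzero(cand == best)
        mother_in_top2 = int(np.sum(cand > ibs_mother)) <= 1
        if best >= threshold and mother_in_top2 and len(ties) == 1:
            rows.append((oid, METHOD_IBS, fathers[ties[0]], float(best),
                         threshold))
        else:
            rows.append((oid, METHOD_IBS, UNASSIGNED, float(best), threshold))
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# trio likelihood


def estimate_allele_freqs(matrix: GenotypeMatrix,
                          sample_set: Sequence[str] | None = None,
                          clamp: tuple[float, float] = (0.001, 0.999)
                          ) -> np.ndarray:
    """Per-locus alt-allele frequency over the non-missing calls of
    ``sample_set`` (default: all samples), clamped away from 0 and 1.

    Loci with no calls in the set get frequency 0.5 with a log note.
    """
    sub = matrix if sample_set is None else matrix.take_samples(sample_set)
    if sub.n_samples == 0:
        raise ValueError("sample_set must be non-empty")
    p = sub.alt_allele_freq()
    n_nan = int(np.isnan(p).sum())
    if n_nan:
        log.warning("estimate_allele_freqs: %d loci with no calls set to 0.5",
                    n_nan)
        p = np.where(np.isnan(p), 0.5, p)
    return np.clip(p, clamp[0], clamp[1])


def transmission_prob(offspring_code: int, mother_code: int,
                      father_code: int) -> float:
    """Probability of the offspring's unordered genotype given one uniformly
    drawn allele from each parent."""
    for c in (offspring_code, mother_code, father_code):
        if c not in (0, 1, 2):
            raise ValueError(f"genotype codes must be 0/1/2, got {c}")
    pm, pf = mother_code / 2.0, father_code / 2.0
    return [(1 - pm) * (1 - pf), pm + pf - 2 * pm * pf, pm * pf][offspring_code]


def _hwe_prob_of(codes: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg probability of each genotype code at frequency p."""
    return np.select([codes == 0, codes == 1, codes == 2],
                     [(1 - p) ** 2, 2 * p * (1 - p), p ** 2], 0.0)


def _trans_prob_arr(off: np.ndarray, pm: np.ndarray, pf) -> np.ndarray:
    return np.select([off == 0, off == 1, off == 2],
                     [(1 - pm) * (1 - pf), pm + pf - 2 * pm * pf, pm * pf], 0.0)


def lod_matrix(off_geno: np.ndarray, mother_geno: np.ndarray,
               cand_geno: np.ndarray, freqs: np.ndarray,
               error_rate: float = DEFAULT_ERROR_RATE
               ) -> tuple[np.ndarray, np.ndarray]:
    """Trio LOD of every offspring against every candidate father.

    Per trio-complete locus the numerator is
    ``(1-e) * P(off | mother, father) + e * P_HWE(off)`` and the denominator
    ``(1-e) * P(off | mother, random father) + e * P_HWE(off)``; the LOD is
    the summed natural-log ratio.  Returns (lod, loci_used) with shapes
    (n_offspring, n_candidates) and (n_offspring, n_candidates).
    """
    off = np.atleast_2d(off_geno)
    mo = np.asarray(mother_geno)
    cand = np.atleast_2d(cand_geno)
    p = np.asarray(freqs, dtype=float)
    e = float(error_rate)
    mo2 = mo if mo.ndim == 2 else mo[None, :]      # per-offspring mothers allowed
    pm = np.where(mo2 == MISSING, np.nan, mo2 / 2.0)
    off_ok = off != MISSING
    h = _hwe_prob_of(off, p[None, :])
    # denominator: father drawn from HWE -> transmitted allele is alt w.p. p
    t0 = _trans_prob_arr(off, pm, p[None, :])
    l0 = (1 - e) * t0 + e * h
    n_off, n_cand = off.shape[0], cand.shape[0]
    lod = np.zeros((n_off, n_cand))
    used = np.zeros((n_off, n_cand), dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_l0 = np.log(l0)
        for k in range(n_cand):
            fa = cand[k][None, :]
            pf = fa / 2.0
            t1 = _trans_prob_arr(off, pm, pf)
            l1 = (1 - e) * t1 + e * h
            informative = off_ok & (mo2 != MISSING) & (fa != MISSING)
            contrib = np.where(informative, np.log(l1) - log_l0, 0.0)
            # a locus impossible under the mother alone (only at e = 0) says
            # nothing about paternity: 0/0 is treated as no information
            contrib = np.where(informative & (l1 == 0.0) & (l0 == 0.0),
                               0.0, contrib)
            lod[:, k] = contrib.sum(axis=1)
            used[:, k] = informative.sum(axis=1)
    return lod, used


def trio_lod(matrix: GenotypeMatrix, offspring: str, mother: str, father: str,
             freqs: np.ndarray, error_rate: float = DEFAULT_ERROR_RATE
             ) -> tuple[float, int]:
    """LOD of one trio (natural log) and the number of loci used.

    With ``error_rate`` 0 a Mendelian-impossible locus drives the LOD to
    ``-inf``; any positive error rate keeps it finite.
    """
    lod, used = lod_matrix(matrix.row(offspring)[None, :], matrix.row(mother),
                           matrix.row(father)[None, :], freqs, error_rate)
    return float(lod[0, 0]), int(used[0, 0])


def simulate_critical_delta(freqs: np.ndarray, *, n_offspring: int = 10_000,
                            n_candidates: int = 15,
                            prop_loci_typed: float = 0.99,
                            error_rate: float = DEFAULT_ERROR_RATE,
                            prop_fathers_sampled: float = 0.75,
                            min_typed_loci: int = 500,
                            confidence: float = 0.99, seed: int = 0,
                            include_mother: bool = True, chunk: int = 256,
                            full_output: bool = False):
    """Simulation-calibrated critical delta for confident paternity.

    Simulates offspring whose mother is known and whose true father is among
    the candidates with probability ``prop_fathers_sampled`` (candidates and
    parents drawn from Hardy-Weinberg proportions at ``freqs``), types the
    offspring at ``prop_loci_typed`` with ``error_rate`` mistyping, and keeps
    those with at least ``min_typed_loci`` typed loci.  With
    ``include_mother`` (the default) the first candidate is a replicate of the
    offspring's own mother, mirroring an assignment run that uses a mother
    replicate to detect selfing; the true father is drawn uniformly over the
    candidate list, so a small selfing fraction arises naturally.

    Delta is the LOD gap between the two best candidates, evaluated only over
    simulated offspring that would be assignable at all (positive best LOD --
    the same rule the assignment step applies).  Returns the smallest
    threshold t such that, among those offspring with delta >= t, the best
    candidate is the true father in at least ``confidence`` of cases -- 0.0
    when the full assignment set already meets the confidence level (deltas
    are >= 0 by construction), ``+inf`` with a warning when no threshold
    achieves it.
    """
    p = np.asarray(freqs, dtype=float)
    n_loci = len(p)
    rng = np.random.default_rng(seed)
    deltas: list[np.ndarray] = []
    corrects: list[np.ndarray] = []
    done = 0
    while done < n_offspring:
        m = min(chunk, n_offspring - done)
        mothers = _hwe_draw(rng, p, (m, n_loci))
        cands = _hwe_draw(rng, p, (m, n_candidates, n_loci))
        if include_mother:
            cands[:, 0, :] = mothers
        sampled = rng.random(m) < prop_fathers_sampled
        true_idx = rng.integers(0, n_candidates, size=m)
        fathers = cands[np.arange(m), true_idx]
        ext = _hwe_draw(rng, p, (m, n_loci))
        fathers = np.where(sampled[:, None], fathers, ext)
        off = mate(mothers, fathers, rng)
        err = rng.random((m, n_loci)) < error_rate
        if err.any():
            off[err] = _hwe_draw(rng, p, (m, n_loci))[err]
        off[rng.random((m, n_loci)) >= prop_loci_typed] = MISSING
        typed = (off != MISSING).sum(axis=1)
        keep = typed >= min_typed_loci
        if keep.any():
            off_k, mo_k, ca_k = off[keep], mothers[keep], cands[keep]
            lods = np.empty((int(keep.sum()), n_candidates))
            for i in range(off_k.shape[0]):
                lods[i], _ = lod_matrix(off_k[i][None, :], mo_k[i], ca_k[i],
                                        p, error_rate)
            order = np.argsort(lods, axis=1)
            best, second = order[:, -1], order[:, -2]
            rows = np.arange(len(lods))
            d = lods[rows, best] - lods[rows, second]
            ok = sampled[keep] & (best == true_idx[keep])
            # a tied top pair cannot be a confident assignment
            ok &= d > 0
            assignable = lods[rows, best] > 0.0
            deltas.append(d[assignable])
            corrects.append(ok[assignable])
        done += m
    if not deltas:
        log.warning("simulate_critical_delta: no simulated offspring reached "
                    "min_typed_loci=%d", min_typed_loci)
        return _delta_result(np.inf, np.array([]), np.array([]), full_output)
    d = np.concatenate(deltas)
    ok = np.concatenate(corrects).astype(float)
    order = np.argsort(-d, kind="stable")
    d_sorted, ok_sorted = d[order], ok[order]
    success = np.cumsum(ok_sorted) / np.arange(1, len(d_sorted) + 1)
    # candidate thresholds: group boundaries of equal deltas, plus 0
    boundary = np.r_[d_sorted[:-1] != d_sorted[1:], True]
    crit = np.inf
    for k in np.flatnonzero(boundary):
        if success[k] >= confidence:
            crit = float(d_sorted[k])
    if crit != np.inf and success[-1] >= confidence:
        crit = 0.0
    if crit == np.inf:
        log.warning("simulate_critical_delta: no threshold reaches "
                    "confidence %.3g", confidence)
    return _delta_result(crit, d, ok, full_output)


def _delta_result(crit, deltas, correct, full_output):
    if not full_output:
        return crit
    return {"critical_delta": crit, "deltas": deltas,
            "correct": correct.astype(bool),
            "n_evaluated": int(len(deltas))}


def assign_by_likelihood(matrix: GenotypeMatrix, offspring: Sequence[str],
                         mother: str, fathers: Sequence[str],
                         freqs: np.ndarray,
                         error_rate: float = DEFAULT_ERROR_RATE,
                         critical_delta: float = 0.0,
                         include_mother_as_father: bool = True
                         ) -> pd.DataFrame:
    """Per-offspring likelihood verdicts.

    The best candidate by trio LOD is called when its LOD is positive (the
    trio beats random paternity) and the delta to the second-best candidate
    reaches ``critical_delta``.  With ``include_mother_as_father`` a replicate
    of the mother joins the candidate list; a win by the replicate is a
    selfing call.  A single-candidate list has no second-best: delta is
    treated as ``+inf`` and the candidate is called iff its LOD is positive.
    """
    cand_ids = list(fathers)
    cand_rows = [matrix.sample_index(f) for f in fathers]
    if include_mother_as_father:
        cand_ids.append(mother)
        cand_rows.append(matrix.sample_index(mother))
    off_idx = [matrix.sample_index(o) for o in offspring]
    lod, _used = lod_matrix(matrix.geno[off_idx], matrix.row(mother),
                            matrix.geno[cand_rows], freqs, error_rate)
    rows = []
    for i, oid in enumerate(offspring):
        li = lod[i]
        best = li.max()
        ties = np.flatnonzero(li == best)
        if len(cand_ids) == 1:
            delta = np.inf
        elif len(ties) > 1:
            delta = 0.0
        else:
            delta = float(best - np.partition(li, -2)[-2])
        accept = delta >= critical_delta and best > 0.0 and len(ties) == 1
        if len(cand_ids) == 1:
            accept = bool(best > 0)
        if accept:
            winner = cand_ids[ties[0]]
            verdict = SELFING if (include_mother_as_father
                                  and winner == mother) else winner
        else:
            verdict = UNASSIGNED
        rows.append((oid, METHOD_LIKELIHOOD, verdict, float(delta),
                     critical_delta))
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# consensus


@dataclasses.dataclass
class ConsensusTable:
    """Per-offspring verdicts of the three methods and their intersection."""

    records: pd.DataFrame      # long format: one row per offspring x method
    consensus: pd.Series       # offspring -> father id | SELFING | UNASSIGNED

    def couple_counts(self, asr_tally: pd.Series | None = None) -> pd.DataFrame:
        """Per-verdict tallies per method plus the common (consensus) count.

        ``asr_tally`` optionally replaces the ASR verdict counts by the
        exclusion-style multi-count (an offspring under every father passing
        the cutline), the presentation used in couple-summary tables.
        """
        wide = self.records.pivot(index="offspring", columns="method",
                                  values="verdict")
        verdicts = sorted((set(self.consensus.unique())
                           | set(wide.to_numpy().ravel())) - {UNASSIGNED})
        out = {}
        for method in (METHOD_ASR, METHOD_IBS, METHOD_LIKELIHOOD):
            out[method] = wide[method].value_counts()
        out["COMMON"] = self.consensus.value_counts()
        tab = pd.DataFrame(out).reindex(verdicts).fillna(0).astype(int)
        tab.index.name = "verdict"
        if asr_tally is not None:
            tally = asr_tally.reindex(tab.index)
            selfed = tab.loc[SELFING, METHOD_ASR] if SELFING in tab.index else 0
            tab[METHOD_ASR] = tally.fillna(0).astype(int)
            if SELFING in tab.index:
                tab.loc[SELFING, METHOD_ASR] = selfed
        return tab

    def venn(self, father: str) -> dict[str, int]:
        """Seven-cell Venn partition of the offspring assigned to ``father``
        by each method."""
        wide = self.records.pivot(index="offspring", columns="method",
                                  values="verdict")
        in_a = wide[METHOD_ASR] == father
        in_b = wide[METHOD_IBS] == father
        in_c = wide[METHOD_LIKELIHOOD] == father
        return {
            "ASR_only": int((in_a & ~in_b & ~in_c).sum()),
            "IBS_only": int((~in_a & in_b & ~in_c).sum()),
            "LIKELIHOOD_only": int((~in_a & ~in_b & in_c).sum()),
            "ASR_IBS": int((in_a & in_b & ~in_c).sum()),
            "ASR_LIKELIHOOD": int((in_a & ~in_b & in_c).sum()),
            "IBS_LIKELIHOOD": int((~in_a & in_b & in_c).sum()),
            "ALL_THREE": int((in_a & in_b & in_c).sum()),
        }


def consensus(asr_records: pd.DataFrame, ibs_records: pd.DataFrame,
              likelihood_records: pd.DataFrame) -> ConsensusTable:
    """Intersect the three methods: the consensus verdict is the common father
    (or common selfing call) when all three agree, otherwise unassigned."""
    frames = {METHOD_ASR: asr_records, METHOD_IBS: ibs_records,
              METHOD_LIKELIHOOD: likelihood_records}
    sets = [frozenset(f["offspring"]) for f in frames.values()]
    if not (sets[0] == sets[1] == sets[2]):
        raise ComputationError(
            "the three methods cover different offspring sets")
    records = pd.concat(frames.values(), ignore_index=True)
    wide = records.pivot(index="offspring", columns="method", values="verdict")
    agree = ((wide[METHOD_ASR] == wide[METHOD_IBS])
             & (wide[METHOD_ASR] == wide[METHOD_LIKELIHOOD])
             & (wide[METHOD_ASR] != UNASSIGNED))
    cons = pd.Series(np.where(agree, wide[METHOD_ASR], UNASSIGNED),
                     index=wide.index, name="consensus")
    # restore input offspring order
    order = list(asr_records["offspring"])
    return ConsensusTable(records, cons.loc[order])
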