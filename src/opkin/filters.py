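"""Variant-filtering recipes for the paternity pipeline.

The filters mirror the common command-line semantics of VCFtools-style
site filtering on a biallelic SNP matrix:

* ``filter_call_rate``   -- keep loci called in at least a given fraction of
  samples (boundary kept: a locus at exactly the threshold passes);
* ``filter_missing_count`` -- keep loci with at most N missing calls;
* ``filter_maf``         -- keep loci with minor-allele frequency >= threshold,
  computed over non-missing calls only;
* ``filter_hwe``         -- drop loci failing the exact Hardy-Weinberg test;
* ``mask_min_depth``     -- set calls below a depth floor to missing;
* ``thin_by_distance``   -- greedy per-chromosome thinning by physical distance.

All filters return a new matrix with a subset of loci and the same samples,
and are idempotent.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


def filter_call_rate(matrix: GenotypeMatrix, min_rate: float) -> GenotypeMatrix:
    """Keep loci whose fraction of non-missing calls is >= ``min_rate``."""
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError(f"min_rate must be in [0, 1], got {min_rate}")
    keep = matrix.call_rate() >= min_rate
    log.info("call-rate filter (>= %.3g): kept %d of %d loci",
             min_rate, int(keep.sum()), matrix.n_loci)
    return matrix.take_loci(keep)


def filter_missing_count(matrix: GenotypeMatrix, max_missing: int) -> GenotypeMatrix:
    """Keep loci with at most ``max_missing`` missing calls."""
    if max_missing < 0:
        raise ValueError(f"max_missing must be >= 0, got {max_missing}")
    keep = matrix.missing_count() <= max_missing
    log.info("missing-count filter (<= %d): kept %d of %d loci",
             max_missing, int(keep.sum()), matrix.n_loci)
    return matrix.take_loci(keep)


def filter_maf(matrix: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep loci with minor-allele frequency >= ``min_maf``.

    Frequencies use available-case analysis (non-missing calls only).  Loci
    with no non-missing calls are always dropped.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    p = matrix.alt_allele_freq()
    all_missing = np.isnan(p)
    if all_missing.any():
        log.info("maf filter: dropping %d loci with all calls missing",
                 int(all_missing.sum()))
    maf = np.minimum(p, 1.0 - p)
    keep = ~all_missing & (maf >= min_maf)
    log.info("maf filter (>= %.3g): kept %d of %d loci",
             min_maf, int(keep.sum()), matrix.n_loci)
    return matrix.take_loci(keep)


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over every heterozygote
    count consistent with them, the probabilities that do not exceed the
    probability of the observed configuration.  Returns 1.0 for an empty
    sample (the test is vacuous).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n == 0:
        return 1.0
    n_alt = 2 * n_hom_alt + n_het  # alt-allele count
    n_rare = min(n_alt, 2 * n - n_alt)
    # P(h hets | n, allele counts) on the log scale; h has the parity of n_rare
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.array([_log_hwe_prob(int(h), n, n_rare) for h in hs])
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    h_obs = n_het
    p_obs = prob[np.searchsorted(hs, h_obs)]
    return float(prob[prob <= p_obs * (1.0 + 1e-12)].sum())


def _log_hwe_prob(h: int, n: int, n_rare: int) -> float:
    """log P(h heterozygotes) given n diploids and n_rare copies of the rarer allele."""
    if (n_rare - h) % 2 or h < 0 or h > n_rare or (n_rare - h) // 2 > n - h:
        return -math.inf
    n_rr = (n_rare - h) // 2           # rare homozygotes
    n_cc = n - n_rr - h                # common homozygotes
    lg = math.lgamma
    return (lg(n + 1) - lg(n_rr + 1) - lg(h + 1) - lg(n_cc + 1)
            + h * math.log(2.0)
            - (lg(2 * n + 1) - lg(n_rare + 1) - lg(2 * n - n_rare + 1)))


def filter_hwe(matrix: GenotypeMatrix, alpha: float) -> GenotypeMatrix:
    """Drop loci whose exact Hardy-Weinberg p-value is below ``alpha``.

    Counts use non-missing calls only; loci with zero informative calls are
    dropped.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    counts = matrix.genotype_counts()
    cache: dict[tuple[int, int, int], float] = {}
    keep = np.zeros(matrix.n_loci, dtype=bool)
    for j in range(matrix.n_loci):
        trip = (int(counts[j, 0]), int(counts[j, 1]), int(counts[j, 2]))
        if sum(trip) == 0:
            continue
        if trip not in cache:
            cache[trip] = hwe_exact_pvalue(*trip)
        keep[j] = cache[trip] >= alpha
    log.info("HWE filter (alpha %.3g): kept %d of %d loci",
             alpha, int(keep.sum()), matrix.n_loci)
    return matrix.take_loci(keep)


def mask_min_depth(matrix: GenotypeMatrix, min_depth: int) -> GenotypeMatrix:
    """Set calls with depth below ``min_depth`` to missing.

    Calls without depth information (or a matrix without a depth layer) are
    left unchanged: absence of depth is not evidence of a bad call.
    """
    if min_depth < 0:
        raise ValueError(f"min_depth must be >= 0, got {min_depth}")
    out = matrix.copy()
    if matrix.depth is None or min_depth == 0:
        return out
    low = (out.depth >= 0) & (out.depth < min_depth)
    out.geno[low] = MISSING
    log.info("depth mask (>= %d): masked %d calls", min_depth, int(low.sum()))
    return out


def thin_by_distance(matrix: GenotypeMatrix, min_bp: int) -> GenotypeMatrix:
    """Greedy per-chromosome thinning: keep a locus only if it lies at least
    ``min_bp`` from the previously kept locus.

    Loci are sorted by position within each chromosome first (chromosome order
    follows first appearance); the first locus of every chromosome is kept.
    """
    if min_bp < 0:
        raise ValueError(f"min_bp must be >= 0, got {min_bp}")
    chrom = matrix.loci["chrom"].to_numpy()
    pos = matrix.loci["pos"].to_numpy()
    chrom_order = {c: k for k, c in enumerate(dict.fromkeys(chrom))}
    order = np.lexsort((pos, np.array([chrom_order[c] for c in chrom])))
    kept: list[int] = []
    last_chrom = None
    last_pos = -np.inf
    for j in order:
        if chrom[j] != last_chrom or pos[j] - last_pos >= min_bp:
            kept.append(int(j))
            last_chrom = chrom[j]
            last_pos = pos[j]
    log.info("thin filter (%d bp): kept %d of %d loci",
             min_bp, len(kept), matrix.n_loci)
    return matrix.take_loci(np.array(kept, dtype=int))


#: stage name -> filter implementation, for configurable recipe order
_STAGES = {
    "call_rate": lambda m, p: filter_call_rate(m, p["min_call_rate"]),
    "maf": lambda m, p: filter_maf(m, p["min_maf"]),
    "hwe": lambda m, p: filter_hwe(m, p["hwe_alpha"]),
    "depth": lambda m, p: mask_min_depth(m, p["min_depth"]),
    "missing_count": lambda m, p: filter_missing_count(m, p["max_missing"]),
    "thin": lambda m, p: thin_by_distance(m, p["thin_bp"]),
}

DEFAULT_PANEL_ORDER = ("call_rate", "maf", "hwe", "depth", "missing_count", "thin")


def likelihood_panel(matrix: GenotypeMatrix, *, min_call_rate: float = 0.8,
                     min_maf: float = 0.3, hwe_alpha: float = 0.05,
                     min_depth: int = 5, max_missing: int = 20,
                     thin_bp: int = 3_000_000,
                     order: tuple[str, ...] = DEFAULT_PANEL_ORDER) -> GenotypeMatrix:
    """Compose the filters into the high-quality, loosely linked panel used by
    the likelihood paternity method.

    The default order applies the call-rate screen first and the distance
    thinning last; ``order`` makes the sequence configurable since depth
    masking before versus after the call-rate screen is a legitimate choice.
    """
    params = dict(min_call_rate=min_call_rate, min_maf=min_maf,
                  hwe_alpha=hwe_alpha, min_depth=min_depth,
                  max_missing=max_missing, thin_bp=thin_bp)
    out = matrix
    for stage in order:
        out = _STAGES[stage](out, params)
    return out
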