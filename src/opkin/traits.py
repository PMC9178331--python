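"""Sprouting-index phenotype handling and the Kruskal-Wallis marker screen.

The sprouting index (SPI) scores the spring bud stage of each plant (0
dormant, 1 green tip, ..., 6 one bud + three leaves, averaged over 5-10 buds),
a proxy for the timing of bud flush.  This module summarises the trait,
compares the reconstructed crosses, and screens markers for minor trait
associations with per-genotype-class Kruskal-Wallis rank tests.

Reporting rules for the screen: a marker is reported when it is significant at
``P < .001`` in at least one year or ``P < .01`` in every year, and only the
highest-K marker of each chromosome (K taken in the year of its best p-value)
is kept.  Significance tiers use the seven-level star convention common in
rank-based QTL screens (one star per threshold passed among 0.1, 0.05, 0.01,
0.005, 0.001, 0.0005, 0.0001; "ns" above 0.1).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, UndefinedValueError
from .matrix import MISSING, GenotypeMatrix
from .paternity import ConsensusTable
from .simulate import UNASSIGNED

log = logging.getLogger(__name__)

STAR_LEVELS = (0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001)


def significance_stars(p: float, levels: Sequence[float] = STAR_LEVELS) -> str:
    """One star per significance level passed; ``ns`` above the loosest level."""
    n = sum(p < level for level in levels)
    return "*" * n if n else "ns"


def trait_summary(traits: pd.DataFrame, year: str) -> dict[str, float]:
    """Mean, sample SD, CV (percent), min, max and n of one year's values."""
    vals = traits[year].dropna().to_numpy(dtype=float)
    if len(vals) < 2:
        raise UndefinedValueError("need at least 2 non-missing trait values")
    mean = float(vals.mean())
    if mean == 0.0:
        raise UndefinedValueError("trait mean is 0; CV undefined")
    sd = float(vals.std(ddof=1))
    return {"mean": mean, "sd": sd, "cv": 100.0 * sd / mean,
            "min": float(vals.min()), "max": float(vals.max()),
            "n": int(len(vals))}


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> dict[str, float]:
    """Tie-corrected Kruskal-Wallis rank test.

    Returns ``{"K", "df", "p"}`` with the p-value from the chi-square
    approximation (df = number of groups - 1).  A degenerate sample in which
    every value is identical yields K = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ComputationError("Kruskal-Wallis needs at least 2 groups")
    parts = [values[groups == lab] for lab in labels]
    if any(len(p) == 0 for p in parts):
        raise ComputationError("every group needs at least one value")
    df = len(labels) - 1
    if np.all(values == values[0]):
        return {"K": 0.0, "df": df, "p": 1.0}
    k, p = stats.kruskal(*parts)
    return {"K": float(k), "df": df, "p": float(p)}


def compare_crosses(traits: pd.DataFrame, consensus: ConsensusTable, year: str,
                    min_group: int = 3) -> pd.DataFrame:
    """Pairwise two-group Kruskal-Wallis comparisons of trait values between
    the reconstructed crosses (consensus father families, selfings included;
    unassigned offspring excluded).  Groups below ``min_group`` offspring are
    skipped with a log note."""
    verdicts = consensus.consensus
    members: dict[str, np.ndarray] = {}
    for cross in pd.unique(verdicts):
        if cross == UNASSIGNED:
            continue
        ids = verdicts.index[verdicts == cross]
        vals = traits[year].reindex(ids).dropna().to_numpy(dtype=float)
        if len(vals) < min_group:
            log.info("compare_crosses: skipping cross %s with %d offspring",
                     cross, len(vals))
            continue
        members[cross] = vals
    if len(members) < 2:
        raise ComputationError("need at least 2 crosses with enough offspring")
    rows = []
    for a, b in itertools.combinations(sorted(members), 2):
        res = kruskal_wallis(np.r_[members[a], members[b]],
                             np.r_[np.zeros(len(members[a])),
                                   np.ones(len(members[b]))])
        rows.append((a, b, len(members[a]), len(members[b]),
                     float(members[a].mean()), float(members[b].mean()),
                     res["K"], res["p"]))
    return pd.DataFrame(rows, columns=["cross_a", "cross_b", "n_a", "n_b",
                                       "mean_a", "mean_b", "K", "p"])


@dataclasses.dataclass
class KWRecord:
    """One marker's screen result: per-year test, class means and the
    breeding-favorable genotype (the class with the highest mean trait)."""

    marker: str
    chrom: str
    tests: dict[str, dict[str, float]]            # year -> {K, df, p, stars}
    class_means: dict[str, dict[str, float]]      # year -> genotype label -> mean
    class_counts: dict[str, int]                  # genotype label -> n offspring
    favorable: dict[str, str]                     # year -> label(s), ties comma-joined

    @property
    def best_p(self) -> float:
        return min(t["p"] for t in self.tests.values())

    @property
    def k_at_best_p(self) -> float:
        return min(self.tests.values(), key=lambda t: t["p"])["K"]


def _genotype_labels(ref: str, alt: str) -> dict[int, str]:
    a, b = sorted((ref, alt))
    return {0: ref + ref, 1: a + b, 2: alt + alt}


def favorable_genotype(class_means: Mapping[str, float]) -> str:
    """Genotype class with the highest mean trait; ties are comma-joined."""
    if len(class_means) < 2:
        raise ComputationError("favorable genotype needs >= 2 classes")
    best = max(class_means.values())
    winners = [lab for lab, m in class_means.items() if m == best]
    return ",".join(winners)


def _marker_record(matrix: GenotypeMatrix, traits: pd.DataFrame, j: int,
                   offspring: list[str]) -> KWRecord | None:
    row = matrix.loci.iloc[j]
    labels = _genotype_labels(str(row["ref"]), str(row["alt"]))
    geno = matrix.geno[[matrix.sample_index(o) for o in offspring], j]
    present = np.unique(geno[geno != MISSING])
    if len(present) < 2:
        return None                     # monomorphic among these offspring
    tests: dict[str, dict[str, float]] = {}
    class_means: dict[str, dict[str, float]] = {}
    favorable: dict[str, str] = {}
    counts = {labels[int(g)]: int((geno == g).sum()) for g in present}
    for year in traits.columns:
        t = traits[year].reindex(offspring).to_numpy(dtype=float)
        ok = (geno != MISSING) & ~np.isnan(t)
        sub_g, sub_t = geno[ok], t[ok]
        if len(np.unique(sub_g)) < 2:
            return None
        res = kruskal_wallis(sub_t, sub_g)
        res["stars"] = significance_stars(res["p"])
        tests[year] = res
        means = {labels[int(g)]: float(sub_t[sub_g == g].mean())
                 for g in np.unique(sub_g)}
        class_means[year] = means
        favorable[year] = favorable_genotype(means)
    return KWRecord(str(row["id"]), str(row["chrom"]), tests, class_means,
                    counts, favorable)


def screen_markers(matrix: GenotypeMatrix, traits: pd.DataFrame,
                   grouping: Mapping[str, str] | None = None,
                   p_single: float = 0.001, p_all: float = 0.01,
                   min_overlap: int = 30) -> list[KWRecord]:
    """Kruskal-Wallis minor-QTL screen over all markers.

    ``grouping`` maps marker id to a linkage-group label (default: the
    chromosome from the loci table).  Markers pass when significant at
    ``p_single`` in at least one year or at ``p_all`` in every year; within
    each group only the highest-K marker (K in the year of its best p) is
    reported.  Offspring missing either the genotype or the trait are excluded
    pairwise per marker and year.
    """
    offspring = [s for s in matrix.samples if s in traits.index]
    if len(offspring) < min_overlap:
        raise ComputationError(
            f"only {len(offspring)} offspring shared between genotypes and "
            f"traits; need >= {min_overlap}")
    passing: dict[str, KWRecord] = {}
    for j in range(matrix.n_loci):
        rec = _marker_record(matrix, traits, j, offspring)
        if rec is None:
            continue
        ps = [t["p"] for t in rec.tests.values()]
        if not (min(ps) < p_single or all(p < p_all for p in ps)):
            continue
        group = (grouping[rec.marker] if grouping is not None else rec.chrom)
        held = passing.get(group)
        if held is None or rec.k_at_best_p > held.k_at_best_p:
            passing[group] = rec
    return [passing[g] for g in sorted(passing)]


def half_sib_consistency(record: KWRecord, matrix: GenotypeMatrix,
                         traits: pd.DataFrame, holdout_offspring: Sequence[str]
                         ) -> dict:
    """Check a screened marker's favorable genotype in a holdout family set.

    Recomputes the genotype-class means among ``holdout_offspring`` (which
    must be disjoint from the discovery set used for the screen) and declares
    the marker consistent iff, in every year, the discovery favorable genotype
    attains the (possibly tied) highest holdout mean.
    """
    holdout = [o for o in holdout_offspring if o in matrix._sample_index
               and o in traits.index]
    if not holdout:
        raise ComputationError("holdout offspring set is empty")
    j_hits = np.flatnonzero(matrix.loci["id"].to_numpy() == record.marker)
    if len(j_hits) == 0:
        raise ComputationError(f"marker {record.marker!r} not in matrix")
    j = int(j_hits[0])
    row = matrix.loci.iloc[j]
    labels = _genotype_labels(str(row["ref"]), str(row["alt"]))
    geno = matrix.geno[[matrix.sample_index(o) for o in holdout], j]
    holdout_means: dict[str, dict[str, float]] = {}
    consistent = True
    for year in traits.columns:
        t = traits[year].reindex(holdout).to_numpy(dtype=float)
        ok = (geno != MISSING) & ~np.isnan(t)
        means = {labels[int(g)]: float(t[ok][geno[ok] == g].mean())
                 for g in np.unique(geno[ok])}
        holdout_means[year] = means
        fav = set(record.favorable[year].split(","))
        if not means:
            consistent = False
            continue
        best = max(means.values())
        winners = {lab for lab, m in means.items() if m == best}
        if not (fav & winners):
            consistent = False
    return {"consistent": consistent, "holdout_means": holdout_means}


def records_to_frame(records: Sequence[KWRecord]) -> pd.DataFrame:
    """Flatten screen records into a wide summary table (one row per
    marker x year), ready for TSV export."""
    rows = []
    for rec in records:
        for year, t in rec.tests.items():
            means = rec.class_means[year]
            rows.append({
                "marker": rec.marker, "chrom": rec.chrom, "year": year,
                "K": t["K"], "df": t["df"], "p": t["p"], "stars": t["stars"],
                "classes": ":".join(means),
                "class_means": ":".join(f"{means[k]:.3f}" for k in means),
                "favorable": rec.favorable[year],
            })
    return pd.DataFrame(rows)
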