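"""Synthetic open-pollination half-sib populations with known pedigree.

The generator emulates the breeding design this package analyses: a single
known clonal mother surrounded by a panel of candidate fathers, open
pollination producing a mixture of full-sib families, a small selfed
fraction (self-incompatibility is only partially effective), and a fraction
of offspring sired by unsampled plants outside the panel.  Offspring calls
carry genotyping error (modelled as replacement of the whole genotype by a
Hardy-Weinberg draw at the locus frequency, the "mistyped locus" abstraction
used by likelihood paternity simulations) and random missingness; the deeply
sequenced parents are left clean.

Loci are unlinked biallelic SNPs on 15 chromosomes.  A quantitative
sprouting-index-like trait is simulated on top: a few additive QTL plus
year-correlated residual noise, affinely rescaled so that each year's
population mean and coefficient of variation hit stated targets.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

SELFING = "SELFING"
UNASSIGNED = "UNASSIGNED"
EXTERNAL = "EXTERNAL"


def default_father_weights(n_candidate_fathers: int,
                           dominant: float = 0.56,
                           selfing: float = 0.03,
                           external: float = 0.24) -> np.ndarray:
    """Mixture over (each candidate father, selfing, unsampled father).

    One candidate dominates the paternity (a widely planted cultivar close to
    the mother), a small mass goes to selfing, a sizeable mass to fathers
    outside the sampled panel, and the remainder is spread evenly over the
    other candidates.
    """
    if n_candidate_fathers < 1:
        raise ConfigError("need at least one candidate father")
    rest = 1.0 - dominant - selfing - external
    if rest < 0:
        raise ConfigError("dominant + selfing + external weights exceed 1")
    w = np.empty(n_candidate_fathers + 2)
    w[0] = dominant
    w[1:n_candidate_fathers] = (rest / (n_candidate_fathers - 1)
                                if n_candidate_fathers > 1 else 0.0)
    if n_candidate_fathers == 1:
        w[0] = dominant + rest
    w[n_candidate_fathers] = selfing
    w[n_candidate_fathers + 1] = external
    return w


@dataclasses.dataclass
class SimConfig:
    """Study-scale defaults: 1 mother, 14 candidate fathers, 388 offspring,
    2000 unlinked loci, 1% genotyping error and 1% missingness on offspring,
    alt-allele frequencies uniform on (0.05, 0.95)."""

    n_loci: int = 2000
    n_candidate_fathers: int = 14
    n_offspring: int = 388
    father_weights: np.ndarray | None = None  # len n_candidates + 2; see above
    allele_freq_law: tuple[float, float] = (0.05, 0.95)
    error_rate: float = 0.01
    missing_rate: float = 0.01
    seed: int = 0
    mother_id: str = "mother"
    n_chrom: int = 15
    chrom_length: int = 200_000_000

    def __post_init__(self) -> None:
        if min(self.n_loci, self.n_candidate_fathers, self.n_offspring) < 1:
            raise ConfigError("counts must be >= 1")
        for r in (self.error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"rates must be in [0, 1], got {r}")
        lo, hi = self.allele_freq_law
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError(f"allele_freq_law must satisfy 0 < lo <= hi < 1")
        if self.father_weights is None:
            self.father_weights = default_father_weights(self.n_candidate_fathers)
        self.father_weights = np.asarray(self.father_weights, dtype=float)
        if len(self.father_weights) != self.n_candidate_fathers + 2:
            raise ConfigError(
                "father_weights must have one entry per candidate father "
                "plus selfing and unsampled-father entries")
        if (self.father_weights < 0).any():
            raise ConfigError("father_weights must be non-negative")
        if abs(self.father_weights.sum() - 1.0) > 1e-9:
            raise ConfigError("father_weights must sum to 1")

    @property
    def father_ids(self) -> list[str]:
        return [f"father_{k + 1:02d}" for k in range(self.n_candidate_fathers)]

    @property
    def offspring_ids(self) -> list[str]:
        width = len(str(self.n_offspring))
        return [f"off_{k + 1:0{width}d}" for k in range(self.n_offspring)]

    def to_text(self, path) -> None:
        """Plain key=value dump of the configuration."""
        with open(path, "wt") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, np.ndarray):
                    v = ",".join(f"{x:.8g}" for x in v)
                fh.write(f"{f.name}={v}\n")


def _hwe_draw(rng: np.random.Generator, freqs: np.ndarray,
              shape: tuple[int, ...]) -> np.ndarray:
    """Genotype codes drawn from Hardy-Weinberg proportions at ``freqs``.

    ``freqs`` broadcasts against the trailing axis of ``shape``.
    """
    u = rng.random(shape)
    q2 = (1.0 - freqs) ** 2
    het = q2 + 2.0 * freqs * (1.0 - freqs)
    return ((u >= q2).astype(np.int8) + (u >= het).astype(np.int8))


def _locus_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chrom = np.sort(rng.integers(1, config.n_chrom + 1, size=config.n_loci))
    pos = rng.integers(1, config.chrom_length + 1, size=config.n_loci)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=config.n_loci)
    alt_i = (ref_i + rng.integers(1, 4, size=config.n_loci)) % 4
    width = len(str(config.n_loci))
    return pd.DataFrame({
        "chrom": [f"chr{c:02d}" for c in chrom],
        "pos": pos.astype(np.int64),
        "id": [f"m{k + 1:0{width}d}" for k in range(config.n_loci)],
        "ref": bases[ref_i],
        "alt": bases[alt_i],
    })


def draw_parents(config: SimConfig,
                 rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Mother plus candidate fathers, unrelated, drawn locus-wise from
    Hardy-Weinberg proportions at frequencies from ``allele_freq_law``.

    The realised alt-allele frequency of every locus is attached to the loci
    table as the extra column ``true_alt_freq``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    loci = _locus_table(config, rng)
    lo, hi = config.allele_freq_law
    freqs = rng.uniform(lo, hi, size=config.n_loci)
    loci["true_alt_freq"] = freqs
    n_parents = 1 + config.n_candidate_fathers
    geno = _hwe_draw(rng, freqs, (n_parents, config.n_loci))
    samples = [config.mother_id] + config.father_ids
    return GenotypeMatrix(samples, loci, geno)


def mate(mother_geno: np.ndarray, father_geno: np.ndarray,
         rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission: one allele drawn uniformly from each parent,
    independently per locus.  A missing parent call yields a missing
    offspring call at that locus."""
    m = np.asarray(mother_geno)
    f = np.asarray(father_geno)
    from_m = (rng.random(m.shape) < m / 2.0).astype(np.int8)
    from_f = (rng.random(f.shape) < f / 2.0).astype(np.int8)
    child = from_m + from_f
    child[(m == MISSING) | (f == MISSING)] = MISSING
    return child


def corrupt(matrix: GenotypeMatrix, error_rate: float, missing_rate: float,
            freqs: np.ndarray, rng: np.random.Generator) -> GenotypeMatrix:
    """Apply genotyping error then missingness to every call.

    With probability ``error_rate`` a call is replaced by a Hardy-Weinberg
    draw at the locus frequency (it may coincide with the truth); afterwards
    each call is set missing with probability ``missing_rate``.
    """
    for r in (error_rate, missing_rate):
        if not 0.0 <= r <= 1.0:
            raise ConfigError(f"rates must be in [0, 1], got {r}")
    out = matrix.copy()
    shape = out.geno.shape
    if error_rate > 0:
        err = rng.random(shape) < error_rate
        draws = _hwe_draw(rng, np.asarray(freqs), shape)
        out.geno[err] = draws[err]
    if missing_rate > 0:
        out.geno[rng.random(shape) < missing_rate] = MISSING
    return out


def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate the full population and its ground-truth pedigree.

    Returns the genotype matrix (mother, candidate fathers, offspring -- the
    offspring block carries error and missingness) and a truth table with one
    row per offspring: mother id and true father id, where the mother id marks
    a selfing and ``EXTERNAL`` an unsampled father.
    """
    rng = np.random.default_rng(config.seed)
    parents = draw_parents(config, rng)
    freqs = parents.loci["true_alt_freq"].to_numpy()
    nc = config.n_candidate_fathers
    mother = parents.geno[0]

    picks = rng.choice(nc + 2, size=config.n_offspring, p=config.father_weights)
    offspring = np.empty((config.n_offspring, config.n_loci), dtype=np.int8)
    father_col: list[str] = []
    for i, pick in enumerate(picks):
        if pick < nc:                      # sampled candidate father
            father = parents.geno[1 + pick]
            father_col.append(config.father_ids[pick])
        elif pick == nc:                   # selfing
            father = mother
            father_col.append(config.mother_id)
        else:                              # unsampled external father
            father = _hwe_draw(rng, freqs, (config.n_loci,))
            father_col.append(EXTERNAL)
        offspring[i] = mate(mother, father, rng)

    off_matrix = GenotypeMatrix(config.offspring_ids, parents.loci, offspring,
                                validate=False)
    off_matrix = corrupt(off_matrix, config.error_rate, config.missing_rate,
                         freqs, rng)
    geno = np.vstack([parents.geno, off_matrix.geno])
    matrix = GenotypeMatrix(parents.samples + config.offspring_ids,
                            parents.loci, geno)
    truth = pd.DataFrame({
        "offspring": config.offspring_ids,
        "mother": config.mother_id,
        "father": father_col,
    })
    return matrix, truth


# ---------------------------------------------------------------------------
# trait simulation


@dataclasses.dataclass
class QtlSpec:
    """Additive QTL model for the sprouting-index-like trait.

    ``effects`` maps locus ids to the additive effect of one alt-allele copy,
    expressed in residual-standard-deviation units.  Residuals are bivariate
    normal across years with correlation ``year_corr`` (marker effects in the
    emulated study were consistent across years, implying positive
    correlation).  Each year's values are affinely rescaled to hit
    ``target_mean`` / ``target_cv`` (defaults: the study-scale sprouting-index
    summaries for the two recording years), then clipped at 0.
    """

    effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: {})
    years: tuple[str, ...] = ("2020", "2021")
    target_mean: tuple[float, ...] = (5.465, 4.457)
    target_cv: tuple[float, ...] = (0.185, 0.176)
    residual_sd: float = 1.0
    year_corr: float = 0.6

    def __post_init__(self) -> None:
        if len(self.target_mean) != len(self.years) or \
                len(self.target_cv) != len(self.years):
            raise ConfigError("per-year targets must match the year labels")
        if min(self.target_cv) <= 0:
            raise ConfigError("target_cv must be > 0")


def default_qtl_spec(matrix: GenotypeMatrix, n_qtl: int = 3,
                     effects: Sequence[float] = (0.5, 0.35, 0.25),
                     rng: np.random.Generator | None = None) -> QtlSpec:
    """Pick ``n_qtl`` common loci (MAF >= 0.25) on distinct chromosomes and
    assign them the given standardized additive effects."""
    if rng is None:
        rng = np.random.default_rng(0)
    p = matrix.alt_allele_freq()
    maf_ok = np.minimum(p, 1 - p) >= 0.25
    chosen: dict[str, float] = {}
    used_chroms: set[str] = set()
    idx = rng.permutation(matrix.n_loci)
    for j in idx:
        if not maf_ok[j]:
            continue
        c = str(matrix.loci["chrom"].iloc[j])
        if c in used_chroms:
            continue
        chosen[str(matrix.loci["id"].iloc[j])] = float(effects[len(chosen)])
        used_chroms.add(c)
        if len(chosen) == n_qtl:
            break
    if len(chosen) < n_qtl:
        raise ConfigError("not enough polymorphic loci to place the QTLs")
    return QtlSpec(effects=chosen)


def simulate_trait(matrix: GenotypeMatrix, truth: pd.DataFrame, spec: QtlSpec,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the per-offspring trait table (offspring x year).

    Genetic value is the sum of additive QTL effects over alt-allele dosage
    (missing calls contribute the locus mean dosage); residuals are
    equicorrelated normal across years.  Each year is affinely rescaled to the
    target mean and CV and clipped at 0.  With zero genetic and residual
    variance the trait is the constant target mean (the CV target is then
    unattainable and a warning is logged).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    offspring = list(truth["offspring"])
    rows = [matrix.sample_index(o) for o in offspring]
    n = len(rows)
    g = np.zeros(n)
    for lid, eff in spec.effects.items():
        hits = np.flatnonzero(matrix.loci["id"].to_numpy() == lid)
        if len(hits) == 0:
            raise ConfigError(f"QTL locus {lid!r} not present in the matrix")
        j = int(hits[0])
        dose = matrix.geno[rows, j].astype(float)
        called = dose >= 0
        mean_dose = dose[called].mean() if called.any() else 1.0
        dose[~called] = mean_dose
        g += eff * dose
    n_years = len(spec.years)
    corr = np.full((n_years, n_years), spec.year_corr)
    np.fill_diagonal(corr, 1.0)
    eps = rng.multivariate_normal(np.zeros(n_years),
                                  corr * spec.residual_sd ** 2, size=n)
    raw = g[:, None] + eps
    out = np.empty_like(raw)
    for y in range(n_years):
        col = raw[:, y]
        sd = col.std(ddof=1) if n > 1 else 0.0
        mean, cv = spec.target_mean[y], spec.target_cv[y]
        if sd == 0.0:
            log.warning("simulate_trait: zero variance in year %s; trait is "
                        "the constant target mean, CV target unattainable",
                        spec.years[y])
            out[:, y] = mean
        else:
            z = (col - col.mean()) / sd
            out[:, y] = np.clip(mean + cv * mean * z, 0.0, None)
    return pd.DataFrame(out, index=pd.Index(offspring, name="offspring"),
                        columns=list(spec.years))


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t")


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    return df
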