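"""End-to-end pipeline: filtering -> three paternity methods -> consensus ->
optional trait stages, with a run report.

The report echoes every threshold actually used (so defaults cannot drift
silently), tallies the consensus, and renders percentages of the total
genotyped offspring rounded half-up to one decimal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import filters, paternity, traits as traits_mod
from .errors import ConfigError
from .matrix import GenotypeMatrix
from .simulate import SELFING, UNASSIGNED, read_traits
from .vcfio import read_vcf

log = logging.getLogger(__name__)

ROLE_MOTHER = "mother"
ROLE_FATHER = "candidate_father"
ROLE_OFFSPRING = "offspring"
ROLE_CONTROL = "control"


def read_manifest(path) -> pd.DataFrame:
    """Sample manifest TSV with columns ``sample`` and ``role`` (mother,
    candidate_father, offspring or control); exactly one mother required."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "role"}.issubset(df.columns):
        raise ConfigError(f"{path}: manifest needs 'sample' and 'role' columns")
    bad = set(df["role"]) - {ROLE_MOTHER, ROLE_FATHER, ROLE_OFFSPRING,
                             ROLE_CONTROL}
    if bad:
        raise ConfigError(f"{path}: unknown roles {sorted(bad)}")
    if (df["role"] == ROLE_MOTHER).sum() != 1:
        raise ConfigError(f"{path}: manifest must name exactly one mother")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal("1." + "0" * decimals) if decimals else Decimal("1")
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_percentages(consensus, total_offspring: int) -> dict[str, float]:
    """Assigned / dominant-couple / selfing percentages of the genotyped total.

    ``consensus`` may be a :class:`~opkin.paternity.ConsensusTable` or a
    mapping with counts ``{"assigned": ..., "dominant": ..., "selfing": ...}``.
    Percentages are rounded half-up to one decimal.
    """
    if total_offspring < 1:
        raise ValueError("total_offspring must be >= 1")
    if isinstance(consensus, paternity.ConsensusTable):
        verdicts = consensus.consensus
        assigned = int((verdicts != UNASSIGNED).sum())
        selfing = int((verdicts == SELFING).sum())
        father_counts = verdicts[(verdicts != UNASSIGNED)
                                 & (verdicts != SELFING)].value_counts()
        dominant = int(father_counts.iloc[0]) if len(father_counts) else 0
    else:
        assigned = int(consensus["assigned"])
        dominant = int(consensus["dominant"])
        selfing = int(consensus["selfing"])
    return {
        "assigned_pct": round_half_up(100.0 * assigned / total_offspring),
        "dominant_couple_pct": round_half_up(100.0 * dominant / total_offspring),
        "selfing_pct": round_half_up(100.0 * selfing / total_offspring),
    }


@dataclasses.dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    vcf: str
    manifest: str
    out_dir: str
    phenotype: str | None = None
    # exclusion-set filter (ASR / IBS methods)
    min_call_rate: float = 0.8
    # likelihood-panel recipe
    min_maf: float = 0.3
    hwe_alpha: float = 0.05
    min_depth: int = 5
    max_missing: int = 20
    thin_bp: int = 3_000_000
    # paternity thresholds
    asr_cutline: float = paternity.DEFAULT_ASR_CUTLINE
    asr_selfing: float = paternity.DEFAULT_ASR_SELFING
    ibs_threshold: float = paternity.DEFAULT_IBS_THRESHOLD
    ibs_selfing: float = paternity.DEFAULT_IBS_SELFING
    derive_thresholds: bool = True     # re-derive cutline/IBS threshold from data
    error_rate: float = paternity.DEFAULT_ERROR_RATE
    confidence: float = 0.99
    delta_n_offspring: int = 10_000
    delta_n_candidates: int = 15
    prop_loci_typed: float = 0.99
    prop_fathers_sampled: float = 0.75
    min_typed_loci: int = 500
    seed: int = 0
    run_traits: bool = False

    def __post_init__(self) -> None:
        for name in ("asr_cutline", "asr_selfing", "ibs_threshold",
                     "ibs_selfing", "error_rate", "confidence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.run_traits and self.phenotype is None:
            raise ConfigError("trait stage enabled but no phenotype path given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclasses.dataclass
class RunReport:
    """Counts, thresholds and percentages of one pipeline run."""

    version: str
    seed: int
    stage_counts: dict
    thresholds: dict
    consensus_counts: dict
    percentages: dict
    couple_table: pd.DataFrame

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["couple_table"] = self.couple_table.reset_index().to_dict(
            orient="records")
        return json.dumps(payload, indent=2, default=str)

    def to_text(self) -> str:
        lines = [f"opkin {self.version}  (seed {self.seed})", ""]
        lines.append("stage counts:")
        for k, v in self.stage_counts.items():
            lines.append(f"  {k}: {v}")
        lines.append("thresholds used:")
        for k, v in self.thresholds.items():
            lines.append(f"  {k}: {v}")
        lines.append("consensus:")
        for k, v in self.consensus_counts.items():
            lines.append(f"  {k}: {v}")
        lines.append("percentages of genotyped offspring:")
        for k, v in self.percentages.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
        lines.append(self.couple_table.to_string())
        return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute filters -> ASR/IBS/likelihood -> consensus (-> traits).

    All outputs are written under ``config.out_dir``; the run is deterministic
    under ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest)
    matrix = read_vcf(config.vcf)
    known = set(matrix.samples)
    missing = set(manifest["sample"]) - known
    if missing:
        raise ConfigError(f"manifest samples absent from VCF: {sorted(missing)}")
    mother = manifest.loc[manifest["role"] == ROLE_MOTHER, "sample"].iloc[0]
    fathers = list(manifest.loc[manifest["role"] == ROLE_FATHER, "sample"])
    offspring = list(manifest.loc[manifest["role"] == ROLE_OFFSPRING, "sample"])
    if not fathers or not offspring:
        raise ConfigError("manifest must list candidate fathers and offspring")

    stage_counts = {"input_loci": matrix.n_loci,
                    "input_samples": matrix.n_samples}
    base = filters.filter_call_rate(matrix, config.min_call_rate)
    stage_counts["exclusion_set_loci"] = base.n_loci
    panel = filters.likelihood_panel(
        base, min_call_rate=config.min_call_rate, min_maf=config.min_maf,
        hwe_alpha=config.hwe_alpha, min_depth=config.min_depth,
        max_missing=config.max_missing, thin_bp=config.thin_bp)
    stage_counts["likelihood_panel_loci"] = panel.n_loci
    if panel.n_loci == 0:
        raise ConfigError("likelihood panel is empty after filtering")

    # -- ASR ------------------------------------------------------------
    cam = paternity.asr_matrix(base, mother, fathers, offspring)
    cutline = config.asr_cutline
    if config.derive_thresholds and len(offspring) >= 10:
        cutline = paternity.suggest_asr_cutline(
            paternity.ssasr(cam), default=config.asr_cutline)
        cutline = max(cutline, config.asr_selfing * 1.5)
    asr_rec = paternity.assign_by_asr(cam, cutline, config.asr_selfing)
    tally = paternity.asr_couple_tally(cam, cutline)

    # -- IBS ------------------------------------------------------------
    ibs_threshold = config.ibs_threshold
    if config.derive_thresholds and len(offspring) >= 5:
        ibs_threshold = paternity.derive_ibs_threshold(
            base, [(mother, o) for o in offspring])
        ibs_threshold = min(ibs_threshold, config.ibs_selfing - 0.01)
    ibs_rec = paternity.assign_by_ibs(base, mother, fathers, offspring,
                                      ibs_threshold, config.ibs_selfing)

    # -- likelihood ------------------------------------------------------
    freqs = paternity.estimate_allele_freqs(panel)
    min_typed = min(config.min_typed_loci, int(0.9 * panel.n_loci))
    critical_delta = paternity.simulate_critical_delta(
        freqs, n_offspring=config.delta_n_offspring,
        n_candidates=config.delta_n_candidates,
        prop_loci_typed=config.prop_loci_typed,
        error_rate=config.error_rate,
        prop_fathers_sampled=config.prop_fathers_sampled,
        min_typed_loci=min_typed, confidence=config.confidence,
        seed=config.seed)
    lik_rec = paternity.assign_by_likelihood(
        panel, offspring, mother, fathers, freqs, config.error_rate,
        critical_delta, include_mother_as_father=True)

    # -- consensus --------------------------------------------------------
    cons = paternity.consensus(asr_rec, ibs_rec, lik_rec)
    couple_table = cons.couple_counts(asr_tally=tally)
    verdicts = cons.consensus
    counts = {
        "total_offspring": len(offspring),
        "assigned": int((verdicts != UNASSIGNED).sum()),
        "selfing": int((verdicts == SELFING).sum()),
    }
    father_counts = verdicts[(verdicts != UNASSIGNED)
                             & (verdicts != SELFING)].value_counts()
    counts["dominant"] = int(father_counts.iloc[0]) if len(father_counts) else 0
    counts["dominant_father"] = (str(father_counts.index[0])
                                 if len(father_counts) else "")
    pct = summarize_percentages(cons, len(offspring))

    thresholds = {"asr_cutline": cutline, "asr_selfing": config.asr_selfing,
                  "ibs_threshold": ibs_threshold,
                  "ibs_selfing": config.ibs_selfing,
                  "error_rate": config.error_rate,
                  "critical_delta": critical_delta,
                  "confidence": config.confidence,
                  "min_typed_loci": min_typed}

    # -- outputs ----------------------------------------------------------
    cons.records.to_csv(out / "assignments.tsv", sep="\t", index=False)
    verdicts.rename("consensus").to_frame().to_csv(out / "consensus.tsv",
                                                   sep="\t")
    couple_table.to_csv(out / "couple_summary.tsv", sep="\t")
    if counts["dominant_father"]:
        venn = cons.venn(counts["dominant_father"])
        pd.Series(venn, name="count").rename_axis("cell").to_frame().to_csv(
            out / "venn.tsv", sep="\t")

    if config.run_traits:
        trait_tab = read_traits(config.phenotype)
        summaries = {y: traits_mod.trait_summary(trait_tab, y)
                     for y in trait_tab.columns}
        pd.DataFrame(summaries).T.rename_axis("year").to_csv(
            out / "trait_summary.tsv", sep="\t")
        try:
            comparisons = pd.concat(
                [traits_mod.compare_crosses(trait_tab, cons, y).assign(year=y)
                 for y in trait_tab.columns], ignore_index=True)
            comparisons.to_csv(out / "cross_comparisons.tsv", sep="\t",
                               index=False)
        except Exception as exc:
            log.warning("cross comparisons skipped: %s", exc)
        records = traits_mod.screen_markers(base, trait_tab)
        traits_mod.records_to_frame(records).to_csv(
            out / "marker_screen.tsv", sep="\t", index=False)
        stage_counts["markers_reported"] = len(records)

    report = RunReport(__version__, config.seed, stage_counts, thresholds,
                       counts, pct, couple_table)
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text())
    return report
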