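"""Containers for biallelic SNP genotypes.

Genotype calls are unordered allele pairs over the two alleles of a locus, so
they are stored as alt-allele dosage codes in an ``int8`` array:

====  ======================
code  meaning
====  ======================
``0``   homozygous reference
``1``   heterozygous
``2``   homozygous alternate
``-1``  missing (``./.``)
====  ======================

Every statistic in the package (abnormal-SNP ratios, allele sharing, trio
likelihoods, Hardy-Weinberg tests) is a function of these codes, which keeps
the whole pipeline vectorisable with numpy.

Loci are kept in a :class:`pandas.DataFrame` with the mandatory columns
``chrom, pos, id, ref, alt`` (1-based positions, single-base alleles).  Extra
columns -- e.g. the true alternate-allele frequency attached by the population
simulator -- are carried along through every locus-subsetting operation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedValueError

MISSING = -1
LOCUS_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


@dataclasses.dataclass(frozen=True)
class Locus:
    """A biallelic SNP: chromosome, 1-based position, marker id, ref/alt alleles."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"locus {self.id}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError(f"locus {self.id}: position must be >= 1, got {self.pos}")


def genotype_label(code: int, ref: str, alt: str) -> str:
    """Render a dosage code as an unordered allele-pair string, e.g. ``A/G``."""
    if code == MISSING:
        return "."
    pair = {0: (ref, ref), 1: tuple(sorted((ref, alt))), 2: (alt, alt)}[int(code)]
    return "/".join(pair)


class GenotypeMatrix:
    """Samples x loci grid of biallelic genotype calls with optional read depth.

    Parameters
    ----------
    samples : sequence of str
        Unique sample identifiers, one per row of ``geno``.
    loci : pandas.DataFrame
        One row per locus with at least the columns ``chrom, pos, id, ref, alt``.
    geno : ndarray of int8, shape (n_samples, n_loci)
        Dosage codes (-1 missing, 0 hom-ref, 1 het, 2 hom-alt).
    depth : ndarray of int32 or None
        Per-call sequencing depth; -1 marks a call without depth information.
    """

    def __init__(self, samples: Sequence[str], loci: pd.DataFrame,
                 geno: np.ndarray, depth: np.ndarray | None = None,
                 validate: bool = True):
        self.samples = list(samples)
        self.loci = loci.reset_index(drop=True)
        self.geno = np.asarray(geno, dtype=np.int8)
        self.depth = None if depth is None else np.asarray(depth, dtype=np.int32)
        if validate:
            self._validate()
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    # -- construction & validation ------------------------------------------

    def _validate(self) -> None:
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"loci table lacks columns {missing_cols}")
        if self.geno.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci")
        if self.depth is not None and self.depth.shape != self.geno.shape:
            raise ValueError("depth shape does not match geno shape")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        ids = self.loci["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"locus ids are not unique (e.g. {dup!r})")
        if (self.loci["pos"] < 1).any():
            raise ValueError("locus positions must be >= 1")
        if (self.loci["ref"] == self.loci["alt"]).any():
            raise ValueError("ref and alt alleles must differ at every locus")
        bad = ~np.isin(self.geno, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.geno[bad])}")

    # -- basic accessors -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def row(self, sample: str) -> np.ndarray:
        """Dosage codes of one sample (view, do not mutate)."""
        return self.geno[self.sample_index(sample)]

    def locus(self, i: int) -> Locus:
        r = self.loci.iloc[i]
        return Locus(str(r["chrom"]), int(r["pos"]), str(r["id"]),
                     str(r["ref"]), str(r["alt"]))

    def call_label(self, sample: str, locus_id: str) -> str:
        j = int(self.loci.index[self.loci["id"] == locus_id][0])
        r = self.loci.iloc[j]
        return genotype_label(self.geno[self.sample_index(sample), j],
                              str(r["ref"]), str(r["alt"]))

    # -- subsetting ----------------------------------------------------------

    def take_loci(self, sel) -> "GenotypeMatrix":
        """Sub-matrix keeping the loci selected by a boolean mask or index array."""
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return GenotypeMatrix(
            self.samples, self.loci.iloc[sel], self.geno[:, sel],
            None if self.depth is None else self.depth[:, sel], validate=False)

    def take_samples(self, samples: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.loci, self.geno[idx],
            None if self.depth is None else self.depth[idx], validate=False)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.loci.copy(), self.geno.copy(),
                              None if self.depth is None else self.depth.copy(),
                              validate=False)

    # -- per-locus / per-sample summaries ------------------------------------

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per locus."""
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return (self.geno != MISSING).mean(axis=0)

    def missing_count(self) -> np.ndarray:
        return (self.geno == MISSING).sum(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """Per-locus (hom-ref, het, hom-alt) counts over non-missing calls."""
        out = np.empty((self.n_loci, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.geno == g).sum(axis=0)
        return out

    def alt_allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per locus over non-missing calls (NaN if none)."""
        called = (self.geno != MISSING).sum(axis=0)
        alt = np.where(self.geno == MISSING, 0, self.geno).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, alt / (2.0 * called), np.nan)

    def het_ratio(self, sample: str) -> float:
        """Heterozygous fraction among a sample's non-missing calls."""
        g = self.row(sample)
        called = int((g != MISSING).sum())
        if called == 0:
            raise UndefinedValueError(
                f"sample {sample!r} has no non-missing calls; het ratio undefined")
        return float((g == 1).sum() / called)

    # -- export / comparison -------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write calls as TSV: sample rows, locus columns, 'A/G' strings, '.' missing."""
        ref = self.loci["ref"].to_numpy()
        alt = self.loci["alt"].to_numpy()
        cols = {}
        for j, lid in enumerate(self.loci["id"]):
            cols[lid] = [genotype_label(c, ref[j], alt[j]) for c in self.geno[:, j]]
        pd.DataFrame(cols, index=pd.Index(self.samples, name="sample")).to_csv(
            path, sep="\t")

    def equals(self, other: "GenotypeMatrix") -> bool:
        same_depth = (
            (self.depth is None and other.depth is None)
            or (self.depth is not None and other.depth is not None
                and np.array_equal(self.depth, other.depth)))
        return (self.samples == other.samples
                and self.loci[list(LOCUS_COLUMNS)].astype(str).equals(
                    other.loci[list(LOCUS_COLUMNS)].astype(str))
                and np.array_equal(self.geno, other.geno)
                and same_depth)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci, "
                f"depth={'yes' if self.depth is not None else 'no'})")
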