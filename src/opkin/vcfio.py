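"""VCF 4.2 input/output for biallelic SNP matrices.

Reading goes through cyvcf2 (htslib); only biallelic single-base SNP records
are loaded, everything else is skipped with a logged count.  A light
structural pre-scan of the text assigns line numbers to malformed records,
something htslib's error messages do not always provide.

Writing emits a minimal uncompressed VCF with GT (always) and DP (when depth
is present) so that ``read_vcf(write_vcf(m))`` reproduces the calls, locus
order and sample order exactly.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import VcfParseError
from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

# cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_TYPE_TO_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)

_BASES = {"A", "C", "G", "T"}


def _prescan(path: str) -> None:
    """Cheap structural check so parse errors can name a line number."""
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated "
                    f"fields, got {len(fields)}")
            try:
                int(fields[1])
            except ValueError:
                raise VcfParseError(
                    f"{path}: line {lineno}: POS {fields[1]!r} is not an "
                    f"integer") from None


def read_vcf(path: str) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF file.

    Multi-allelic records, indels and symbolic alleles are skipped (count
    logged).  ``./.`` maps to missing; phased separators are treated as
    unphased; per-call DP is kept when the file provides it.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _prescan(path)
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib header errors
        raise VcfParseError(f"{path}: failed to parse VCF header: {exc}") from exc
    samples = list(vcf.samples)
    rows_g: list[np.ndarray] = []
    rows_d: list[np.ndarray] = []
    loci: list[tuple] = []
    skipped = 0
    has_depth = False
    dp_in_header = True  # flipped off on the first record lacking a DP FORMAT
    try:
        for rec_no, var in enumerate(vcf, start=1):
            alts = var.ALT
            if (len(alts) != 1 or var.REF not in _BASES or alts[0] not in _BASES):
                skipped += 1
                continue
            lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
            loci.append((var.CHROM, var.POS, lid, var.REF, alts[0]))
            if samples:
                rows_g.append(_GT_TYPE_TO_CODE[var.gt_types])
                dp = None
                if dp_in_header:
                    try:
                        dp = var.format("DP")
                    except KeyError:
                        dp_in_header = False
                if dp is not None:
                    has_depth = True
                    dp = dp.reshape(-1).astype(np.int64)
                    dp = np.where(dp < 0, -1, dp).astype(np.int32)
                    rows_d.append(dp)
                else:
                    rows_d.append(np.full(len(samples), -1, dtype=np.int32))
    except Exception as exc:
        raise VcfParseError(
            f"{path}: failed to parse record {rec_no}: {exc}") from exc
    finally:
        vcf.close()
    if skipped:
        log.info("read_vcf(%s): skipped %d non-biallelic/non-SNP records",
                 path, skipped)
    loci_df = pd.DataFrame(loci, columns=["chrom", "pos", "id", "ref", "alt"])
    n_loci = len(loci_df)
    geno = (np.array(rows_g, dtype=np.int8).T if rows_g
            else np.zeros((len(samples), n_loci), dtype=np.int8))
    depth = (np.array(rows_d, dtype=np.int32).T if (rows_d and has_depth) else None)
    out = GenotypeMatrix(samples, loci_df, geno, depth)
    out.skipped_records = skipped
    return out


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file."""
    with_depth = matrix.depth is not None
    chroms = list(dict.fromkeys(matrix.loci["chrom"].astype(str)))
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=opkin\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if matrix.samples:
            cols += ["FORMAT"] + matrix.samples
        fh.write("\t".join(cols) + "\n")
        fmt = "GT:DP" if with_depth else "GT"
        loci = matrix.loci
        for j in range(matrix.n_loci):
            r = loci.iloc[j]
            fields = [str(r["chrom"]), str(int(r["pos"])), str(r["id"]),
                      str(r["ref"]), str(r["alt"]), ".", ".", "."]
            if matrix.samples:
                fields.append(fmt)
                for i in range(matrix.n_samples):
                    call = _CODE_TO_GT[int(matrix.geno[i, j])]
                    if with_depth:
                        d = int(matrix.depth[i, j])
                        call += ":" + (str(d) if d >= 0 else ".")
                    fields.append(call)
            fh.write("\t".join(fields) + "\n")
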