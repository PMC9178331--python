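import numpy as np
import pandas as pd
import pytest

from opkin import GenotypeMatrix


def make_matrix(samples, codes, chrom=None, pos=None, ref="A", alt="G",
                depth=None):
    """Build a small matrix from dosage-code rows (one row per sample)."""
    geno = np.asarray(codes, dtype=np.int8)
    n_loci = geno.shape[1]
    loci = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * n_loci,
        "pos": pos if pos is not None else np.arange(1, n_loci + 1),
        "id": [f"L{j + 1}" for j in range(n_loci)],
        "ref": [ref] * n_loci,
        "alt": [alt] * n_loci,
    })
    return GenotypeMatrix(list(samples), loci, geno,
                          None if depth is None else np.asarray(depth))


@pytest.fixture
def build_matrix():
    return make_matrix


@pytest.fixture(scope="session")
def small_population():
    """A modest synthetic population shared by read-only tests."""
    import opkin
    cfg = opkin.SimConfig(n_offspring=80, n_loci=2000, seed=11)
    matrix, truth = opkin.simulate_population(cfg)
    return cfg, matrix, truth
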