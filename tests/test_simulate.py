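import numpy as np
import pandas as pd
import pytest

import opkin
from opkin.errors import ConfigError
from opkin.matrix import MISSING


def test_same_seed_is_bit_identical():
    cfg = opkin.SimConfig(n_offspring=30, n_loci=200, seed=42)
    m1, t1 = opkin.simulate_population(cfg)
    m2, t2 = opkin.simulate_population(opkin.SimConfig(
        n_offspring=30, n_loci=200, seed=42))
    assert m1.equals(m2)
    assert t1.equals(t2)


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        opkin.SimConfig(n_loci=0)
    with pytest.raises(ConfigError):
        opkin.SimConfig(error_rate=1.5)
    with pytest.raises(ConfigError):
        opkin.SimConfig(father_weights=np.array([0.5, 0.5]))  # wrong length


def test_parent_heterozygosity_at_half_frequency():
    cfg = opkin.SimConfig(n_loci=4000, n_candidate_fathers=3,
                          allele_freq_law=(0.5, 0.5), seed=7)
    parents = opkin.draw_parents(cfg)
    # HWE at p = 0.5 -> expected het fraction 0.5, +-3 SE over loci
    se = np.sqrt(0.25 / cfg.n_loci)
    for s in parents.samples:
        assert abs(parents.het_ratio(s) - 0.5) < 3 * se


def test_mate_mendelian_ratios():
    rng = np.random.default_rng(0)
    n = 8000
    # hom-ref x hom-alt -> always het
    child = opkin.mate(np.zeros(n, np.int8), np.full(n, 2, np.int8), rng)
    assert (child == 1).all()
    # het x het -> 1:2:1
    child = opkin.mate(np.ones(n, np.int8), np.ones(n, np.int8), rng)
    frac = np.bincount(child, minlength=3) / n
    assert frac == pytest.approx([0.25, 0.5, 0.25], abs=0.02)
    # missing parent -> missing child
    child = opkin.mate(np.full(3, MISSING, np.int8), np.zeros(3, np.int8), rng)
    assert (child == MISSING).all()


def test_corrupt_edge_rates(build_matrix):
    m = build_matrix(["a", "b"], [[0, 1, 2], [2, 1, 0]])
    rng = np.random.default_rng(1)
    freqs = np.full(3, 0.5)
    same = opkin.corrupt(m, 0.0, 0.0, freqs, rng)
    assert np.array_equal(same.geno, m.geno)
    gone = opkin.corrupt(m, 0.0, 1.0, freqs, rng)
    assert (gone.geno == MISSING).all()


def test_selfing_halves_heterozygosity():
    weights = np.zeros(14 + 2)
    weights[14] = 1.0  # all selfings
    cfg = opkin.SimConfig(n_offspring=60, n_loci=2000, father_weights=weights,
                          error_rate=0.0, missing_rate=0.0, seed=5)
    matrix, truth = opkin.simulate_population(cfg)
    assert (truth["father"] == cfg.mother_id).all()
    mother_het = matrix.het_ratio(cfg.mother_id)
    off_het = np.mean([matrix.het_ratio(o) for o in cfg.offspring_ids])
    assert off_het == pytest.approx(0.5 * mother_het, rel=0.1)
    assert off_het < mother_het


def test_family_sizes_follow_weights():
    cfg = opkin.SimConfig(n_offspring=388, n_loci=50, seed=3)
    _, truth = opkin.simulate_population(cfg)
    counts = truth["father"].value_counts()
    n = cfg.n_offspring
    w_dom = cfg.father_weights[0]
    sd = np.sqrt(n * w_dom * (1 - w_dom))
    assert abs(counts.get("father_01", 0) - n * w_dom) < 4 * sd
    w_ext = cfg.father_weights[-1]
    sd = np.sqrt(n * w_ext * (1 - w_ext))
    assert abs(counts.get(opkin.EXTERNAL, 0) - n * w_ext) < 4 * sd


def test_error_free_population_is_mendelian_consistent():
    cfg = opkin.SimConfig(n_offspring=40, n_loci=400, error_rate=0.0,
                          missing_rate=0.0, seed=9)
    matrix, truth = opkin.simulate_population(cfg)
    for _, row in truth.iterrows():
        father = (row["father"] if row["father"] != opkin.EXTERNAL else None)
        if father is None:
            continue
        asr, n_inf = opkin.compute_asr(matrix, row["offspring"],
                                       row["mother"], father)
        assert asr == 0.0 and n_inf == 400


def test_offspring_mother_ibs_exceeds_unrelated(small_population):
    cfg, matrix, truth = small_population
    sampled = truth[truth["father"].isin(cfg.father_ids)]
    mother_ibs, unrelated_ibs = [], []
    for _, row in sampled.iterrows():
        mother_ibs.append(opkin.compute_ibs(matrix, row["offspring"],
                                            cfg.mother_id)[0])
        other = next(f for f in cfg.father_ids if f != row["father"])
        unrelated_ibs.append(opkin.compute_ibs(matrix, row["offspring"],
                                               other)[0])
    assert np.mean(mother_ibs) > np.mean(unrelated_ibs)


class TestTraitSimulation:
    def _population(self, seed=0):
        cfg = opkin.SimConfig(n_offspring=200, n_loci=300, seed=seed)
        return cfg, *opkin.simulate_population(cfg)

    def test_constant_trait_when_no_variance(self):
        cfg, matrix, truth = self._population()
        spec = opkin.QtlSpec(effects={}, residual_sd=0.0)
        tab = opkin.simulate_trait(matrix, truth, spec,
                                   np.random.default_rng(0))
        assert np.allclose(tab["2020"], 5.465)
        assert np.allclose(tab["2021"], 4.457)

    def test_additive_ordering_of_class_means(self):
        cfg, matrix, truth = self._population(seed=2)
        spec = opkin.default_qtl_spec(matrix, n_qtl=1, effects=(2.5,),
                                      rng=np.random.default_rng(2))
        tab = opkin.simulate_trait(matrix, truth, spec,
                                   np.random.default_rng(2))
        (qtl,) = spec.effects
        j = matrix.loci.index[matrix.loci["id"] == qtl][0]
        rows = [matrix.sample_index(o) for o in truth["offspring"]]
        dose = matrix.geno[rows, j]
        means = [tab["2020"].to_numpy()[dose == g].mean() for g in (0, 1, 2)
                 if (dose == g).sum() >= 5]
        assert means == sorted(means)

    def test_realized_cv_hits_target(self):
        # calibration across 10 seeds: CV within 10% of the target
        for seed in range(10):
            cfg, matrix, truth = self._population(seed=seed)
            spec = opkin.default_qtl_spec(matrix,
                                          rng=np.random.default_rng(seed))
            tab = opkin.simulate_trait(matrix, truth, spec,
                                       np.random.default_rng(seed))
            for year, cv in zip(spec.years, spec.target_cv):
                s = opkin.trait_summary(tab, year)
                assert 0.9 * cv * 100 <= s["cv"] <= 1.1 * cv * 100
                assert s["min"] >= 0.0
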