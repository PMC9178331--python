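import itertools

import numpy as np
import pytest

import opkin


def test_transmission_prob_point_values():
    # O het | M hom-ref, F hom-alt -> certain
    assert opkin.transmission_prob(1, 0, 2) == 1.0
    # O hom-ref | het x het -> 1/4
    assert opkin.transmission_prob(0, 1, 1) == 0.25
    # O hom-ref | M hom-alt -> impossible
    assert opkin.transmission_prob(0, 2, 2) == 0.0
    with pytest.raises(ValueError):
        opkin.transmission_prob(-1, 0, 0)


def test_transmission_prob_sums_to_one_over_offspring():
    for m, f in itertools.product((0, 1, 2), repeat=2):
        total = sum(opkin.transmission_prob(o, m, f) for o in (0, 1, 2))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_allele_freq_estimation(build_matrix):
    m = build_matrix(["a", "b", "c"], [[1, 0, 1], [1, 0, -1], [0, 0, 2]])
    freqs = opkin.estimate_allele_freqs(m, ["a", "b"])
    # locus 1: two hets of two samples -> 0.5; locus 2 monomorphic -> clamped
    assert freqs[0] == pytest.approx(0.5)
    assert freqs[1] == pytest.approx(0.001)
    # locus 3: one het call of sample a only -> 0.5... (1 alt of 2 alleles)
    assert freqs[2] == pytest.approx(0.5)
    # hand-counted over all three samples: locus 3 has 1 het + 1 hom-alt
    freqs_all = opkin.estimate_allele_freqs(m)
    assert freqs_all[2] == pytest.approx(3 / 4)


def test_trio_lod_certain_trio_is_log2(build_matrix):
    m = build_matrix(["M", "F", "O"], [[0], [0], [0]])
    lod, used = opkin.trio_lod(m, "O", "M", "F", np.array([0.5]),
                               error_rate=0.0)
    assert used == 1
    assert lod == pytest.approx(np.log(2.0))


def test_trio_lod_impossible_trio_at_zero_error(build_matrix):
    # O hom-ref impossible under father hom-alt (mother het keeps the
    # random-father alternative alive)
    m = build_matrix(["M", "F", "O"], [[1], [2], [0]])
    lod, _ = opkin.trio_lod(m, "O", "M", "F", np.array([0.5]), error_rate=0.0)
    assert lod == -np.inf
    lod_e, _ = opkin.trio_lod(m, "O", "M", "F", np.array([0.5]),
                              error_rate=0.01)
    assert np.isfinite(lod_e)
    # a locus impossible under the mother alone carries no paternal signal
    m2 = build_matrix(["M", "F", "O"], [[0], [0], [2]])
    lod2, used = opkin.trio_lod(m2, "O", "M", "F", np.array([0.5]),
                                error_rate=0.0)
    assert (lod2, used) == (0.0, 1)


def test_trio_lod_converges_to_mendelian_limit(build_matrix):
    rng = np.random.default_rng(0)
    freqs = rng.uniform(0.2, 0.8, 50)
    mo = (rng.random(50) < freqs).astype(np.int8) + \
         (rng.random(50) < freqs).astype(np.int8)
    fa = (rng.random(50) < freqs).astype(np.int8) + \
         (rng.random(50) < freqs).astype(np.int8)
    off = opkin.mate(mo, fa, rng)  # compatible trio by construction
    m = opkin.GenotypeMatrix(
        ["M", "F", "O"],
        __import__("pandas").DataFrame({
            "chrom": ["c1"] * 50, "pos": np.arange(1, 51),
            "id": [f"L{i}" for i in range(50)],
            "ref": ["A"] * 50, "alt": ["G"] * 50}),
        np.vstack([mo, fa, off]))
    exact, _ = opkin.trio_lod(m, "O", "M", "F", freqs, error_rate=0.0)
    near, _ = opkin.trio_lod(m, "O", "M", "F", freqs, error_rate=1e-6)
    assert near == pytest.approx(exact, abs=1e-3)


def test_uninformative_locus_contributes_zero(build_matrix):
    # offspring missing -> locus skipped entirely
    m = build_matrix(["M", "F", "O"], [[0, 0], [0, 0], [0, -1]])
    lod, used = opkin.trio_lod(m, "O", "M", "F", np.array([0.5, 0.5]), 0.0)
    assert used == 1 and lod == pytest.approx(np.log(2.0))


class TestAssignByLikelihood:
    def test_single_candidate_assigned_on_positive_lod(self, build_matrix):
        m = build_matrix(["M", "F", "O"], [[0] * 20, [0] * 20, [0] * 20])
        rec = opkin.assign_by_likelihood(m, ["O"], "M", ["F"],
                                         np.full(20, 0.5), 0.01,
                                         critical_delta=0.0,
                                         include_mother_as_father=False)
        assert rec["verdict"].tolist() == ["F"]
        assert np.isinf(rec["score"].iloc[0])

    def test_below_critical_delta_unassigned(self, small_population):
        cfg, matrix, truth = small_population
        freqs = opkin.estimate_allele_freqs(matrix)
        rec = opkin.assign_by_likelihood(
            matrix, list(truth["offspring"]), cfg.mother_id, cfg.father_ids,
            freqs, 0.01, critical_delta=np.inf)
        assert (rec["verdict"] == opkin.UNASSIGNED).all()

    def test_recovery_and_selfing_detection(self, small_population):
        cfg, matrix, truth = small_population
        freqs = opkin.estimate_allele_freqs(matrix)
        rec = opkin.assign_by_likelihood(
            matrix, list(truth["offspring"]), cfg.mother_id, cfg.father_ids,
            freqs, 0.01, critical_delta=0.0)
        verdicts = rec.set_index("offspring")["verdict"]
        tt = truth.set_index("offspring")["father"]
        sampled = tt[tt.isin(cfg.father_ids)]
        agree = (verdicts[sampled.index] == sampled).mean()
        assert agree >= 0.95
        selfs = tt[tt == cfg.mother_id].index
        hits = (verdicts[selfs] == opkin.SELFING).mean()
        assert hits >= 0.8
        # no sampled-candidate verdict for external-father offspring
        ext = tt[tt == opkin.EXTERNAL].index
        assert not verdicts[ext].isin(cfg.father_ids).any()


class TestCriticalDelta:
    def _freqs(self, n=120, seed=0):
        return np.random.default_rng(seed).uniform(0.3, 0.7, n)

    def test_reproducible_under_seed(self):
        freqs = self._freqs()
        kw = dict(n_offspring=300, n_candidates=5, min_typed_loci=80, seed=4)
        assert opkin.simulate_critical_delta(freqs, **kw) == \
            opkin.simulate_critical_delta(freqs, **kw)

    def test_monotone_in_confidence(self):
        # few loci and unrelated-only candidates make wrong winners common,
        # so the threshold actually moves with the confidence level
        freqs = self._freqs(n=40)
        crits = [opkin.simulate_critical_delta(
            freqs, n_offspring=600, n_candidates=5, min_typed_loci=10,
            prop_fathers_sampled=0.5, include_mother=False, seed=11,
            confidence=c) for c in (0.5, 0.8, 0.95, 0.99)]
        assert crits == sorted(crits)

    def test_easy_settings_yield_zero_threshold(self):
        res = opkin.simulate_critical_delta(
            self._freqs(), n_offspring=300, n_candidates=5,
            prop_fathers_sampled=1.0, error_rate=1e-6, prop_loci_typed=1.0,
            min_typed_loci=100, seed=2, full_output=True)
        assert res["critical_delta"] <= res["deltas"].min()
        assert res["critical_delta"] == 0.0

    def test_no_eligible_offspring_returns_inf(self):
        crit = opkin.simulate_critical_delta(
            self._freqs(n=30), n_offspring=100, n_candidates=3,
            min_typed_loci=500, seed=0)
        assert crit == np.inf
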