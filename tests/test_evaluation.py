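"""Moment statistics, prediction bounds, normalization, data splitting, and
statistical comparisons."""

import numpy as np
import pytest
from scipy.special import comb

from rtrbm.model_core import RBMParams, RTRBMParams, SpikeRaster
from rtrbm.evaluation import (
    NMSEReport,
    bootstrap_model_comparison,
    compute_moments,
    lower_bound_mse,
    model_comparison_tests,
    naive_mse,
    nmse,
    prediction_mse,
    sample_model_moments,
    spearman_compare,
    split_segments,
)
from rtrbm.simulator import SimConfig, simulate
from conftest import random_rbm


class TestComputeMoments:
    def test_all_ones_raster_gives_unit_moments(self):
        rep = compute_moments(SpikeRaster(np.ones((3, 10), dtype=int)))
        assert np.all(rep.mean_v == 1.0)
        assert np.all(rep.pair_vv == 1.0)
        assert np.all(rep.shifted_vv == 1.0)

    def test_deterministic_alternation(self):
        v = np.zeros((2, 10), dtype=int)
        v[0, ::2] = 1                       # 1,0,1,0,...
        v[1, 1::2] = 1
        rep = compute_moments(SpikeRaster(v))
        assert rep.mean_v[0] == pytest.approx(0.5)
        # lag-1 self product of an alternating unit is identically zero
        assert rep.shifted_vv[0, 0] == 0.0
        # but unit 0 at t always precedes unit 1 at t+1
        assert rep.shifted_vv[0, 1] == pytest.approx(5 / 9)

    def test_iid_bernoulli_pairs_approach_p_squared(self, rng):
        p = 0.3
        v = (rng.random((4, 40_000)) < p).astype(int)
        rep = compute_moments(SpikeRaster(v))
        assert rep.pair_vv == pytest.approx(p * p, abs=0.01)

    def test_hidden_trace_moments_attached(self, rng):
        v = (rng.random((3, 50)) < 0.5).astype(int)
        h = rng.random((2, 50))
        rep = compute_moments(SpikeRaster(v), hidden=h)
        assert rep.mean_h == pytest.approx(h.mean(axis=1))
        assert rep.shifted_hh.shape == (2, 2)

    def test_pair_symmetry_encoded_as_upper_triangle(self, rng):
        v = (rng.random((5, 100)) < 0.4).astype(int)
        rep = compute_moments(SpikeRaster(v))
        assert rep.pair_vv.shape == (10,)   # 5 choose 2


class TestSampleModelMoments:
    def test_tiny_rbm_matches_enumerated_marginal(self, rng):
        from rtrbm.model_core import exact_visible_marginal
        params = random_rbm(rng, nv=3, nh=2)
        states, probs = exact_visible_marginal(params)
        exact_mean = probs @ states
        test = SpikeRaster((rng.random((3, 200)) < 0.5).astype(int))
        rep = sample_model_moments(params, test, rng, burn_in=300,
                                   n_start_points=60, chain_len=40)
        se = np.sqrt(exact_mean * (1 - exact_mean) / rep.n_samples)
        assert np.all(np.abs(rep.mean_v - exact_mean) < 5 * se + 0.01)

    def test_zero_weight_model_means_follow_visible_bias(self, rng):
        from scipy.special import expit
        params = RBMParams(np.zeros((2, 4)), np.array([1.0, 0.0, -1.0, 2.0]),
                           np.zeros(2))
        test = SpikeRaster((rng.random((4, 100)) < 0.5).astype(int))
        rep = sample_model_moments(params, test, rng, burn_in=50,
                                   n_start_points=50, chain_len=30)
        assert rep.mean_v == pytest.approx(expit(params.bv), abs=0.05)


class TestSpearman:
    def test_identical_and_reversed(self):
        x = np.array([3.0, 1.0, 2.0, 5.0])
        assert spearman_compare(x, x) == pytest.approx(1.0)
        assert spearman_compare(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_single_swap(self):
        assert spearman_compare([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_compare([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNaiveMSE:
    def test_balanced_and_silent_units(self):
        assert naive_mse(SpikeRaster(np.tile([0, 1], (3, 5)))) == pytest.approx(0.5)
        assert naive_mse(SpikeRaster(np.zeros((3, 10), dtype=int))) == 0.0

    def test_matches_monte_carlo_naive_estimator(self, rng):
        """The closed form ⟨2p(1−p)⟩ equals the simulated MSE of the
        stochastic estimator v̂ ~ Bern(⟨v_i⟩)."""
        v = (rng.random((6, 400)) < rng.random((6, 1)) * 0.8).astype(int)
        raster = SpikeRaster(v)
        p = v.mean(axis=1)
        draws = (rng.random((6, 20_000)) < p[:, None]).astype(float)
        targets = v[:, rng.integers(0, 400, 20_000)]
        mc = np.mean((draws - targets) ** 2)
        assert naive_mse(raster) == pytest.approx(mc, abs=0.01)


class TestNMSE:
    def _report(self, mses):
        return NMSEReport(horizons=list(range(1, len(mses) + 1)),
                          mse_per_horizon=np.asarray(mses, dtype=float),
                          mse_naive=np.nan, mse_var=np.nan, mse_var_sem=0.0)

    def test_endpoints_and_midpoint(self):
        naive, var = 0.42, 0.18
        rep = nmse(self._report([naive, var, (naive + var) / 2]),
                   mse_naive=naive, mse_var=var)
        assert rep.nmse_per_horizon[0] == pytest.approx(1.0, abs=1e-12)
        assert rep.nmse_per_horizon[1] == pytest.approx(0.0, abs=1e-12)
        assert rep.nmse_per_horizon[2] == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_normalization_rejected(self):
        with pytest.raises(ValueError):
            nmse(self._report([0.3]), mse_naive=0.2, mse_var=0.2)


class TestPredictionMSE:
    def test_deterministic_model_predicts_its_own_orbit_exactly(self, rng):
        """A saturated cyclic RTRBM rolled over its own generated orbit has
        zero error; MSE = MAE on the binary predictions by construction."""
        from test_rtrbm_core import cycle_params
        from rtrbm.rtrbm_core import sample_sequence
        p = cycle_params(w=60.0, u=60.0)
        orbit = sample_sequence(p, T=40, rng=rng, K=1, n_chains=1).v[0]
        test = SpikeRaster(orbit.astype(int))
        rep = prediction_mse(p, test, [1], rng, n_chains=5, K=1,
                             n_start_points=20, start="prior")
        assert rep.mse_per_horizon[0] == 0.0

    def test_horizon_validation(self, rng):
        from conftest import random_rtrbm
        p = random_rtrbm(rng)
        test = SpikeRaster((rng.random((3, 10)) < 0.5).astype(int))
        with pytest.raises(ValueError):
            prediction_mse(p, test, [0], rng)
        with pytest.raises(ValueError):
            prediction_mse(p, test, [10], rng)


class TestLowerBound:
    def test_silent_generator_has_zero_variance_floor(self, rng):
        cfg = SimConfig(T=200, fmax=0.0)
        var, sem = lower_bound_mse(cfg, rng, n_states=20, n_instances=5)
        assert var == 0.0 and sem == 0.0

    def test_floor_below_naive_across_seeds(self):
        """The informed bound never exceeds the uninformed naive bound."""
        for seed in range(10):
            cfg = SimConfig(T=400, seed=seed)
            sim = simulate(cfg)
            var, _ = lower_bound_mse(cfg, np.random.default_rng(seed + 1),
                                     n_states=60, n_instances=10)
            assert var <= naive_mse(sim.raster)


class TestSplitSegments:
    def test_default_segmenting_of_t100(self):
        """Test segments 2, 6, 7 (1-based) of a 100-column raster are the
        columns 10–19, 50–59, 60–69 (0-based)."""
        # tag each column with a distinguishable binary code over 7 units
        codes = ((np.arange(100)[None, :] >> np.arange(7)[:, None]) & 1)
        train, test = split_segments(SpikeRaster(codes))
        decode = lambda seg: (seg.values * (1 << np.arange(7))[:, None]).sum(axis=0)
        got = np.concatenate([decode(t) for t in test])
        assert got.tolist() == list(range(10, 20)) + list(range(50, 70))
        train_cols = np.concatenate([decode(t) for t in train])
        assert sorted(np.concatenate([got, train_cols]).tolist()) == list(range(100))

    def test_column_identity_preserved(self):
        vals = (np.arange(40) % 2)[None, :]
        r = SpikeRaster(vals)
        train, test = split_segments(r, n_segments=4, test_segments=[2])
        assert np.array_equal(test[0].values[0], vals[0, 10:20])
        recombined = np.concatenate(
            [t.values for t in train[:1]] + [test[0].values] + [t.values for t in train[1:]],
            axis=1)
        assert np.array_equal(recombined, vals)

    def test_two_segment_split(self):
        r = SpikeRaster(np.zeros((1, 10), dtype=int))
        train, test = split_segments(r, n_segments=2, test_segments=[2])
        assert train[0].n_steps == 5 and test[0].n_steps == 5

    def test_remainder_goes_to_last_segment(self):
        r = SpikeRaster(np.zeros((1, 103), dtype=int))
        train, test = split_segments(r)
        assert sum(t.n_steps for t in train) + sum(t.n_steps for t in test) == 103

    def test_invalid_test_sets_rejected(self):
        r = SpikeRaster(np.zeros((1, 50), dtype=int))
        with pytest.raises(ValueError):
            split_segments(r, n_segments=5, test_segments=[])
        with pytest.raises(ValueError):
            split_segments(r, n_segments=3, test_segments=[1, 2, 3])


class TestTimescaleScan:
    def test_single_rate_scan_returns_that_rate(self):
        from rtrbm.rbm_training import TrainConfig
        from rtrbm.evaluation import timescale_scan
        cfg = SimConfig(T=600, seed=0)
        tc = TrainConfig(n_hidden=10, epochs=1, learning_rate=0.02, seed=0)
        res = timescale_scan(cfg, [1], tc, seeds=(0,), n_chains=3,
                             n_start_points=10, lower_bound_states=20,
                             lower_bound_instances=5)
        assert res.best_rate == 1 and res.best_rate_cosine == 1

    def test_rate_starving_the_training_set_is_an_error(self):
        from rtrbm.rbm_training import TrainConfig
        from rtrbm.evaluation import timescale_scan
        cfg = SimConfig(T=600, seed=0)
        tc = TrainConfig(n_hidden=10, epochs=1, seed=0)
        with pytest.raises(ValueError, match="<50"):
            timescale_scan(cfg, [10], tc, seeds=(0,), lower_bound_states=20,
                           lower_bound_instances=5)


class TestModelComparisonTests:
    def test_identical_groups_are_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = model_comparison_tests(a, a.copy(), "mannwhitney")
        assert p >= 0.5

    def test_disjoint_support_reaches_the_minimal_exact_p(self):
        a = np.arange(10, 20, dtype=float)
        b = np.arange(0, 10, dtype=float)
        _, p = model_comparison_tests(a, b, "mannwhitney")
        assert p == pytest.approx(1.0 / comb(20, 10), rel=1e-6)

    def test_wilcoxon_detects_paired_decrease(self):
        a = np.array([0.1, 0.2, 0.15, 0.12, 0.18, 0.11])
        b = a + 0.5
        _, p = model_comparison_tests(a, b, "wilcoxon")
        assert p < 0.05

    def test_bonferroni_scales_p_by_horizon_count(self, rng):
        a = rng.normal(0, 1, (8, 4))
        b = rng.normal(0, 1, (8, 4))
        raw = model_comparison_tests(a, b, "ttest_bonferroni", n_horizons=1)
        adj = model_comparison_tests(a, b, "ttest_bonferroni")
        for (_, p1), (_, p4) in zip(raw, adj):
            assert p4 == pytest.approx(min(1.0, p1 * 4))

    def test_two_way_anova_finds_a_model_effect(self, rng):
        a = rng.normal(0.0, 0.1, (6, 5)) + np.linspace(0, 1, 5)
        b = a + 0.5                     # constant model offset
        F, p = model_comparison_tests(a, b, "anova2")
        assert p < 1e-6

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            model_comparison_tests([1.0, 2.0], [1.0, 2.0], "mannwhitney")


class TestBootstrapComparison:
    def test_identical_models_indistinguishable(self, rng):
        data = rng.random(4000)
        a = data + 0.1 * rng.random(4000)
        res = bootstrap_model_comparison(data, a, a.copy(), rng, subset_size=1000)
        assert res.decision == "indistinguishable"

    def test_exact_model_beats_shuffled(self, rng):
        data = rng.random(4000)
        good = data + 0.01 * rng.random(4000)
        bad = rng.permutation(data)
        res = bootstrap_model_comparison(data, good, bad, rng, subset_size=1000)
        assert res.decision == "A better"

    def test_subsets_partition_without_overlap(self, rng):
        data = rng.random(3500)
        res = bootstrap_model_comparison(data, data, data + 0.01, rng,
                                         subset_size=1000)
        all_idx = np.concatenate(res.subsets)
        assert len(all_idx) == len(set(all_idx.tolist())) == 3000

    def test_too_few_neurons_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_model_comparison(np.zeros(500), np.zeros(500),
                                       np.zeros(500), rng, subset_size=1000)
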