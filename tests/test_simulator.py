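"""Ground-truth assembly generator: rate construction, delayed
interactions, Poisson observation, and downsampling."""

import numpy as np
import pytest

from rtrbm.model_core import SpikeRaster
from rtrbm.simulator import (
    SimConfig,
    assembly_dynamics,
    default_sim_config,
    default_U,
    downsample,
    intrinsic_rate,
    poisson_observe,
    simulate,
)
from rtrbm.simulator import _peak_train


class TestIntrinsicRate:
    def test_range_is_sum_of_renormalized_instances(self, rng):
        cfg = SimConfig(T=800, seed=0)
        rates = intrinsic_rate(cfg, rng)
        assert rates.min() >= 0.0
        assert rates.max() <= cfg.fmax * 1.1 + 1e-12

    def test_zero_peak_rate_silences_everything(self, rng):
        cfg = SimConfig(T=300, fmax=0.0)
        assert np.all(intrinsic_rate(cfg, rng) == 0.0)

    def test_trace_shorter_than_interval_bound_rejected(self, rng):
        cfg = SimConfig(T=3, tsettle=0)
        with pytest.raises(ValueError):
            intrinsic_rate(cfg, rng)

    def test_inter_peak_gaps_follow_the_stated_sampler(self, rng):
        """Gaps between successive peaks are Uniform(t1, t2) up to the
        integer-grid rounding: support, mean and variance match."""
        t1, t2 = 5.0, 10.0
        gaps = []
        for _ in range(300):
            train = _peak_train(500, t1, t2, rng)
            pos = np.flatnonzero(train)
            gaps.extend(np.diff(pos))
        gaps = np.asarray(gaps, dtype=float)
        assert len(gaps) > 10_000
        assert gaps.min() >= t1 - 1 and gaps.max() <= t2 + 1
        assert gaps.mean() == pytest.approx((t1 + t2) / 2, abs=0.1)
        assert gaps.var() == pytest.approx((t2 - t1) ** 2 / 12, rel=0.2)


class TestAssemblyDynamics:
    def test_no_interactions_is_identity_below_the_clamp(self, rng):
        cfg = SimConfig(T=300, seed=1)
        intr = intrinsic_rate(cfg, rng)
        out = assembly_dynamics(intr, np.zeros((10, 10)), 1, cfg.fmax)
        assert out == pytest.approx(intr)

    def test_strong_inhibition_floors_at_zero(self):
        intr = np.vstack([np.full(20, 0.5), np.full(20, 0.5), np.full(20, 0.5)])
        U = np.zeros((3, 3))
        U[1, 0] = -100.0
        out = assembly_dynamics(intr, U, 1, fmax=0.8)
        assert np.all(out[1, 1:] == 0.0)

    @pytest.mark.parametrize("delay", [1, 3, 4])
    def test_impulse_response_lags_by_exactly_the_delay(self, delay):
        T = 40
        intr = np.zeros((2, T))
        intr[0, 10] = 0.5                      # single pulse in the driver
        U = np.zeros((2, 2))
        U[1, 0] = 1.0
        out = assembly_dynamics(intr, U, delay, fmax=0.8)
        assert int(np.argmax(out[1])) == 10 + delay

    def test_output_respects_the_limiter_range(self, rng):
        cfg = SimConfig(T=400, seed=2)
        sim = simulate(cfg)
        assert sim.rates.min() >= 0.0
        assert sim.rates.max() <= 3 * cfg.fmax + 1e-12

    def test_non_finite_U_rejected(self):
        with pytest.raises(ValueError):
            assembly_dynamics(np.zeros((2, 10)), np.array([[np.inf, 0], [0, 0]]), 1, 0.8)


class TestPoissonObserve:
    def test_zero_rates_give_silent_raster(self, rng):
        cfg = SimConfig(T=100, tsettle=0)
        raster, _, _ = poisson_observe(np.zeros((10, 100)), cfg, rng)
        assert raster.values.sum() == 0

    def test_constant_rate_matches_bernoulli_closed_form(self, rng):
        """P(v=1) = 1 − exp(−c λ) for a nonzero Poisson count."""
        lam = 0.5
        cfg = SimConfig(Nh=3, Nv_per_unit=4, T=20_000, tsettle=0)
        rates = np.full((3, 20_000), lam)
        raster, scales, membership = poisson_observe(rates, cfg, rng)
        p_emp = raster.values.mean(axis=1)
        p_theory = 1.0 - np.exp(-scales * lam)
        se = np.sqrt(p_theory * (1 - p_theory) / raster.n_steps)
        assert np.all(np.abs(p_emp - p_theory) < 4 * se + 1e-3)

    def test_shape_and_burn_in_removal(self, rng):
        cfg = SimConfig(Nh=3, Nv_per_unit=5, T=50, tsettle=10)
        raster, scales, membership = poisson_observe(np.full((3, 60), 0.3), cfg, rng)
        assert raster.values.shape == (15, 50)
        assert membership.tolist() == [0]*5 + [1]*5 + [2]*5
        assert np.all((scales >= cfg.c1) & (scales <= cfg.c2))

    def test_negative_rates_rejected(self, rng):
        cfg = SimConfig(T=50, tsettle=0)
        with pytest.raises(ValueError):
            poisson_observe(np.full((10, 50), -0.1), cfg, rng)


class TestDefaults:
    def test_default_config_carries_the_study_conditions(self):
        cfg = default_sim_config()
        assert (cfg.Nh, cfg.Nv_per_unit) == (10, 20)
        assert (cfg.t1, cfg.t2) == (5, 10)
        assert (cfg.sigma1, cfg.sigma2) == (0.1, 0.5)
        assert (cfg.c1, cfg.c2) == (0.6, 1.4)
        assert (cfg.tsettle, cfg.fmax, cfg.delta_t_a) == (25, 0.8, 1)
        assert default_sim_config(delta_t_a=4).delta_t_a == 4

    def test_default_U_has_one_excitatory_and_one_inhibitory_per_row_and_column(self):
        U = default_U(10, 1.0)
        assert np.all(np.diag(U) == 0)
        for axis in (0, 1):
            assert np.all((U > 0).sum(axis=axis) == 1)
            assert np.all((U < 0).sum(axis=axis) == 1)

    def test_default_U_excitation_is_the_three_cycle(self):
        U = default_U(3, 1.0)
        exc = (U > 0).astype(int)
        assert exc[1, 0] == 1 and exc[2, 1] == 1 and exc[0, 2] == 1

    def test_default_U_needs_three_assemblies(self):
        with pytest.raises(ValueError):
            default_U(2, 1.0)


class TestDownsample:
    def test_rate_one_is_identity(self, rng):
        r = SpikeRaster((rng.random((4, 20)) < 0.5).astype(int), dt=0.5)
        out = downsample(r, 1)
        assert np.array_equal(out.values, r.values)

    def test_every_fourth_column_is_kept(self, rng):
        vals = np.arange(10)[None, :] % 2
        r = SpikeRaster(vals, dt=1.0)
        out = downsample(r, 4)
        assert out.values.shape == (1, 3)
        assert np.array_equal(out.values[0], vals[0, [0, 4, 8]])
        assert out.dt == 4.0

    def test_rate_exceeding_length_rejected(self, rng):
        r = SpikeRaster((rng.random((2, 5)) < 0.5).astype(int))
        with pytest.raises(ValueError):
            downsample(r, 5)


class TestWholePipeline:
    def test_same_seed_bit_identical_different_seeds_differ(self):
        a = simulate(SimConfig(T=300, seed=11))
        b = simulate(SimConfig(T=300, seed=11))
        c = simulate(SimConfig(T=300, seed=12))
        assert np.array_equal(a.raster.values, b.raster.values)
        assert np.array_equal(a.rates, b.rates)
        assert not np.array_equal(a.raster.values, c.raster.values)

    def test_membership_partitions_neurons_into_equal_blocks(self):
        sim = simulate(SimConfig(T=200, seed=0))
        counts = np.bincount(sim.membership)
        assert np.all(counts == 20)

    @pytest.mark.parametrize("delay", [1, 4])
    def test_excited_target_lags_driver_by_the_interaction_delay(self, delay):
        """Across 10 seeds, the driver→target rate cross-correlation at the
        interaction lag exceeds the concurrent one (one-sided sign test)."""
        wins = 0
        for seed in range(10):
            sim = simulate(SimConfig(T=600, seed=seed, delta_t_a=delay))
            U = sim.U_true
            diffs = []
            for j in range(10):
                i = int(np.flatnonzero(U[:, j] > 0)[0])   # j excites i
                a = sim.rates[j] - sim.rates[j].mean()
                b = sim.rates[i] - sim.rates[i].mean()
                lag_d = np.mean(a[:-delay] * b[delay:])
                lag_0 = np.mean(a * b)
                diffs.append(lag_d - lag_0)
            wins += np.mean(diffs) > 0
        # 10/10 successes: one-sided sign test p = 2^-10 < 0.05
        assert wins >= 9
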