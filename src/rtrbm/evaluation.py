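"""Model evaluation: moment statistics, prediction error with normalized
bounds, significance testing, and the timescale scan.

Two evaluation families are implemented:

* **Moment comparison** — concurrent first/second-order and lag-1
  time-shifted moments of visible and hidden units, computed on held-out
  data and on samples drawn from a trained model, compared by Spearman rank
  correlation (with a neuron-subset bootstrap for significance).

* **Predictive quality** — mean squared error of rolling the model forward
  from an observed state (Eq: MSE(t) = mean_i (v_i(t) − v̂_i(t))²; for
  binary predictions MSE = MAE = 1 − accuracy), normalized as

      nMSE = (MSE − MSEvar) / (MSEnaive − MSEvar)

  so that 1 corresponds to the naive unbiased estimator P(v̂=1) = ⟨v_i⟩
  (whose MSE has the closed form ⟨2⟨v_i⟩(1 − ⟨v_i⟩)⟩) and 0 to an optimal
  estimator limited only by the generator's intrinsic stochasticity
  (estimated empirically by paired Poisson observations of matched states).

The timescale scan trains one RTRBM per downsampling rate with an equal
gradient-update budget and locates the rate minimizing one-step-ahead nMSE,
which identifies the assembly interaction delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_core import RBMParams, RTRBMParams, SpikeRaster, gibbs_chain
from .rbm_training import TrainConfig
from .rtrbm_core import hidden_trace, sample_sequence
from .rtrbm_training import assembly_init_W, train_rtrbm
from .simulator import SimConfig, assembly_dynamics, downsample, intrinsic_rate, simulate
from .alignment import align_U, cosine_similarity_U, match_assemblies

__all__ = [
    "MomentReport",
    "NMSEReport",
    "compute_moments",
    "sample_model_moments",
    "spearman_compare",
    "bootstrap_model_comparison",
    "prediction_mse",
    "naive_mse",
    "lower_bound_mse",
    "nmse",
    "timescale_scan",
    "TimescaleScanResult",
    "split_segments",
    "model_comparison_tests",
]


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

@dataclass
class MomentReport:
    """First/second-order and lag-shifted moments of a raster or trace."""

    mean_v: np.ndarray                    # ⟨v_i⟩
    pair_vv: np.ndarray                   # ⟨v_i v_j⟩, upper triangle (i < j)
    shifted_vv: np.ndarray                # ⟨v_i[t] v_j[t+lag]⟩, full matrix
    mean_h: np.ndarray | None = None
    pair_hh: np.ndarray | None = None
    shifted_hh: np.ndarray | None = None
    provenance: str = "data"
    n_samples: int = 0


def _moments(x: np.ndarray, lag: int):
    T = x.shape[1]
    mean = x.mean(axis=1)
    pair_full = x @ x.T / T
    iu = np.triu_indices(x.shape[0], k=1)
    pair = pair_full[iu]
    if lag > 0:
        shifted = x[:, :-lag] @ x[:, lag:].T / (T - lag)
    else:
        shifted = pair_full
    return mean, pair, shifted


def compute_moments(raster, max_lag: int = 1, hidden: np.ndarray | None = None,
                    provenance: str = "data") -> MomentReport:
    """Time-averaged moments of a raster (and optionally a hidden trace).

    ``hidden`` should be the mean-field trace r when evaluating hidden-unit
    statistics of a model on data (⟨h|v⟩, not binary samples).
    """
    x = raster.values.astype(float) if isinstance(raster, SpikeRaster) else np.asarray(raster, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.shape[1] < max_lag + 1:
        raise ValueError("raster shorter than max_lag + 1")
    mean_v, pair_vv, shifted_vv = _moments(x, max_lag)
    rep = MomentReport(mean_v, pair_vv, shifted_vv, provenance=provenance,
                       n_samples=x.shape[1])
    if hidden is not None:
        h = np.asarray(hidden, dtype=float)
        rep.mean_h, rep.pair_hh, rep.shifted_hh = _moments(h, max_lag)
    return rep


def sample_model_moments(params, test: SpikeRaster, rng,
                         gibbs_steps: int = 15, burn_in: int = 4000,
                         n_start_points: int = 100, chain_len: int = 20,
                         max_lag: int = 1) -> MomentReport:
    """Moments of data sampled from a trained model.

    Chains are initialized at random test time points.  For a static RBM
    each sampled column is burned in with ``burn_in`` Gibbs sweeps and then
    advanced ``gibbs_steps`` sweeps per retained sample, ``chain_len``
    samples per start point.  For an RTRBM the chain advances sequentially:
    r is seeded on the start column and the rollout proceeds ``chain_len``
    steps with ``gibbs_steps`` Gibbs sweeps per time-step.
    """
    v_test = test.values.astype(float)
    T = v_test.shape[1]
    if T < 2 or n_start_points < 1:
        raise ValueError("insufficient data for chain placement")
    starts = rng.integers(0, T - 1, size=n_start_points)
    v0 = v_test[:, starts]                                    # (Nv, n_start)

    if isinstance(params, RTRBMParams):
        roll = sample_sequence(params, chain_len, rng, v_init=v0,
                               K=gibbs_steps, n_chains=n_start_points)
        v_samp = np.concatenate([roll.v[c] for c in range(n_start_points)], axis=1)
        h_samp = np.concatenate([roll.r[c] for c in range(n_start_points)], axis=1)
    else:
        v = v0
        if burn_in > 0:
            v, _, _, _ = gibbs_chain(v, params, burn_in, rng)
        cols_v, cols_h = [], []
        for _ in range(chain_len):
            v, _, _, p_h = gibbs_chain(v, params, gibbs_steps, rng)
            cols_v.append(v.copy())
            cols_h.append(p_h.copy())
        v_samp = np.concatenate(cols_v, axis=1)
        h_samp = np.concatenate(cols_h, axis=1)
    rep = compute_moments(v_samp, max_lag=max_lag, hidden=h_samp,
                          provenance="model")
    rep.n_samples = v_samp.shape[1]
    return rep


def spearman_compare(a, b) -> float:
    """Spearman rank correlation (average ranks on ties) between two
    flattened moment vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have equal lengths")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(a, b).statistic)


@dataclass
class BootstrapComparison:
    decision: str                      # "A better" | "B better" | "indistinguishable"
    interval_a: tuple[float, float]    # mean ± 2 SD of per-subset Spearman
    interval_b: tuple[float, float]
    spearman_a: np.ndarray
    spearman_b: np.ndarray
    subsets: list


def bootstrap_model_comparison(data_moments: np.ndarray, moments_a: np.ndarray,
                               moments_b: np.ndarray, rng,
                               subset_size: int = 1000) -> BootstrapComparison:
    """Neuron-subset bootstrap for model comparison.

    Per-neuron moment vectors (e.g. ⟨v_i⟩) are split into non-overlapping
    random subsets of ``subset_size`` neurons (each neuron sampled at most
    once); the Spearman correlation of model vs data moments is computed per
    subset and the two models are called different when the mean ± 2 SD
    intervals do not overlap.
    """
    data_moments = np.asarray(data_moments, dtype=float)
    n = data_moments.shape[0]
    if n < subset_size:
        raise ValueError(f"need at least subset_size={subset_size} neurons, got {n}")
    n_rep = n // subset_size
    if n_rep < 2:
        raise ValueError("need at least 2 non-overlapping subsets")
    perm = rng.permutation(n)
    subsets = [perm[k * subset_size:(k + 1) * subset_size] for k in range(n_rep)]
    rs_a = np.array([spearman_compare(data_moments[s], np.asarray(moments_a)[s])
                     for s in subsets])
    rs_b = np.array([spearman_compare(data_moments[s], np.asarray(moments_b)[s])
                     for s in subsets])
    ia = (rs_a.mean() - 2 * rs_a.std(), rs_a.mean() + 2 * rs_a.std())
    ib = (rs_b.mean() - 2 * rs_b.std(), rs_b.mean() + 2 * rs_b.std())
    if ia[0] > ib[1]:
        decision = "A better"
    elif ib[0] > ia[1]:
        decision = "B better"
    else:
        decision = "indistinguishable"
    return BootstrapComparison(decision, ia, ib, rs_a, rs_b,
                               [s.tolist() for s in subsets])


# ---------------------------------------------------------------------------
# prediction error and bounds
# ---------------------------------------------------------------------------

@dataclass
class NMSEReport:
    horizons: list
    mse_per_horizon: np.ndarray
    mse_naive: float
    mse_var: float
    mse_var_sem: float
    nmse_per_horizon: np.ndarray | None = None


def prediction_mse(params, test: SpikeRaster, horizons, rng,
                   n_chains: int = 100, K: int = 15,
                   n_start_points: int = 50,
                   start: str = "state") -> NMSEReport:
    """MSE of predicting visible states ``horizon`` steps ahead.

    For each start point only the mean-field hidden state is seeded on the
    observed history; the per-step visible Gibbs chains start fresh (all
    zeros) and perform K sweeps under the temporal bias, so the prediction
    carries information exclusively through r — no persistence of the
    observed column leaks into the estimate.  The static RBM, having no
    hidden recursion, is evaluated with the same fresh-chain scheme and
    therefore predicts from its stationary statistics alone.  Each of
    ``n_chains`` rollouts yields a binary prediction whose squared error
    against the observed future column is averaged over chains, units, and
    start points.  Binary predictions make MSE equal to the mean absolute
    error (1 − accuracy); this identity is asserted.
    """
    horizons = sorted(set(int(h) for h in horizons))
    if min(horizons) < 1:
        raise ValueError("horizons must be >= 1")
    v_test = test.values.astype(float)
    T = v_test.shape[1]
    hmax = max(horizons)
    if hmax >= T:
        raise ValueError(f"horizon {hmax} >= test length {T}")
    usable = T - hmax
    starts = np.sort(rng.choice(usable, size=min(n_start_points, usable), replace=False))

    sq_err = {h: [] for h in horizons}
    for t0 in starts:
        if isinstance(params, RTRBMParams):
            # seed r on the observed history up to and including t0
            r_hist = hidden_trace(v_test[:, :t0 + 1], params).r[:, -1]
            roll = sample_sequence(params, hmax, rng, r_init=r_hist,
                                   K=K, n_chains=n_chains, start=start)
        else:
            roll = _rbm_rollout(params, hmax, K, n_chains, rng)
        for h in horizons:
            target = v_test[:, t0 + h]                        # (Nv,)
            pred = roll.v[:, :, h - 1]                        # (n_chains, Nv) binary
            se = np.mean((pred - target[None, :]) ** 2)
            mae = np.mean(np.abs(pred - target[None, :]))
            assert abs(se - mae) < 1e-12, "MSE != MAE on binary predictions"
            sq_err[h].append(se)
    mse = np.array([np.mean(sq_err[h]) for h in horizons])
    return NMSEReport(horizons=horizons, mse_per_horizon=mse,
                      mse_naive=np.nan, mse_var=np.nan, mse_var_sem=np.nan)


@dataclass
class _Roll:
    v: np.ndarray


def _rbm_rollout(params: RBMParams, T, K, n_chains, rng) -> _Roll:
    """Static-RBM 'prediction': a fresh Gibbs chain (K sweeps per step).
    The RBM has no hidden recursion, so nothing connects the chain to the
    observed history — it predicts from its stationary statistics."""
    nv = params.n_visible
    v = np.zeros((nv, n_chains))
    out = np.empty((n_chains, nv, T))
    for t in range(T):
        v, _, _, _ = gibbs_chain(v, params, K, rng)
        out[:, :, t] = v.T
    return _Roll(out)


def naive_mse(raster: SpikeRaster) -> float:
    """Closed-form MSE of the naive unbiased estimator P(v̂_i=1) = ⟨v_i⟩:
    the mean over units of 2 p (1 − p)."""
    v = raster.values.astype(float) if isinstance(raster, SpikeRaster) else np.asarray(raster, dtype=float)
    p = v.mean(axis=1)
    return float(np.mean(2.0 * p * (1.0 - p)))


def lower_bound_mse(config: SimConfig, rng, n_states: int = 10000,
                    n_instances: int = 200):
    """Variance-limited lower bound MSEvar for the generator.

    Per sampled initial assembly state the deterministic interaction term is
    propagated ΔtA steps; pairs of full states are formed by adding
    independent intrinsic-rate draws, each is Poisson-observed, and the MSE
    between the paired binary observations is recorded.  This is the error
    of an ideal estimator with perfect knowledge of the previous assembly
    state, limited only by intrinsic-rate and Poisson stochasticity.

    Returns ``(MSEvar, SEM)`` with the SEM over per-initial-state means.
    """
    nh, nvpu = config.Nh, config.Nv_per_unit
    # pool of realistic assembly states and intrinsic-rate values
    intr = intrinsic_rate(config, rng)
    rates = assembly_dynamics(intr, config.U_true, config.delta_t_a,
                              config.fmax, config.limiter)[:, config.tsettle:]
    intr = intr[:, config.tsettle:]
    Tpool = rates.shape[1]
    membership = np.repeat(np.arange(nh), nvpu)

    state_means = np.empty(n_states)
    for s in range(n_states):
        lam0 = rates[:, rng.integers(0, Tpool)]
        drive = config.U_true @ lam0                 # deterministic part after ΔtA
        # paired full states: independent intrinsic draws on top of the drive
        cols = rng.integers(0, Tpool, size=(2, n_instances))
        lam_a = np.clip(intr[:, cols[0]] + drive[:, None], 0.0, 3.0 * config.fmax)
        lam_b = np.clip(intr[:, cols[1]] + drive[:, None], 0.0, 3.0 * config.fmax)
        scales = rng.uniform(config.c1, config.c2, size=nh * nvpu)
        va = rng.poisson(scales[:, None] * lam_a[membership]) >= 1
        vb = rng.poisson(scales[:, None] * lam_b[membership]) >= 1
        state_means[s] = np.mean(va != vb)
    return float(state_means.mean()), float(state_means.std(ddof=1) / np.sqrt(n_states))


def nmse(report: NMSEReport, mse_naive: float | None = None,
         mse_var: float | None = None) -> NMSEReport:
    """Normalize per-horizon MSE: nMSE = (MSE − MSEvar)/(MSEnaive − MSEvar);
    1 ⇔ naive unbiased estimator, 0 ⇔ optimal estimator."""
    if mse_naive is not None:
        report.mse_naive = mse_naive
    if mse_var is not None:
        report.mse_var = mse_var
    if not np.isfinite(report.mse_naive) or not np.isfinite(report.mse_var):
        raise ValueError("mse_naive and mse_var must be set before normalizing")
    denom = report.mse_naive - report.mse_var
    if denom <= 0:
        raise ValueError(
            f"degenerate normalization: mse_naive={report.mse_naive} <= mse_var={report.mse_var}"
        )
    report.nmse_per_horizon = (report.mse_per_horizon - report.mse_var) / denom
    return report


# ---------------------------------------------------------------------------
# data splitting and statistical tests
# ---------------------------------------------------------------------------

def split_segments(raster: SpikeRaster, n_segments: int = 10,
                   test_segments=(2, 6, 7)):
    """Contiguous equal-length segments (remainder to the last); the listed
    1-based segment indices become the test set.  Returns
    ``(train_rasters, test_rasters)``."""
    test_segments = set(int(i) for i in test_segments)
    if not test_segments or test_segments >= set(range(1, n_segments + 1)):
        raise ValueError("test segments must be a proper nonempty subset")
    if any(i < 1 or i > n_segments for i in test_segments):
        raise ValueError("test segment indices must be within 1..n_segments")
    T = raster.n_steps
    if T < n_segments:
        raise ValueError("raster shorter than the number of segments")
    seg_len = T // n_segments
    train, test = [], []
    for k in range(n_segments):
        s = k * seg_len
        e = (k + 1) * seg_len if k < n_segments - 1 else T
        seg = SpikeRaster(raster.values[:, s:e], dt=raster.dt, unit_ids=raster.unit_ids)
        (test if (k + 1) in test_segments else train).append(seg)
    return train, test


def _concat(rasters) -> SpikeRaster:
    return SpikeRaster(np.concatenate([r.values for r in rasters], axis=1),
                       dt=rasters[0].dt, unit_ids=rasters[0].unit_ids)


def model_comparison_tests(metric_a, metric_b, scheme: str,
                           n_horizons: int | None = None):
    """Dispatch the named statistical comparison.

    ``mannwhitney`` — one-sided Mann–Whitney U (A greater);
    ``wilcoxon`` — one-sided Wilcoxon signed-rank on paired samples (A less);
    ``ttest_bonferroni`` — per-horizon two-sample t-tests, p-values
    multiplied by the number of horizons (inputs are (n_runs, n_horizons));
    ``anova2`` — two-way ANOVA with horizon and model type as factors,
    returns the model-type effect.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if min(a.shape[0], b.shape[0]) < 3:
        raise ValueError("need at least 3 samples per group")
    if scheme == "mannwhitney":
        # exact rank enumeration whenever the samples are tie-free
        method = "exact" if len(np.unique(np.concatenate([a, b]))) == a.size + b.size \
            else "auto"
        res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
        return float(res.statistic), float(res.pvalue)
    if scheme == "wilcoxon":
        res = stats.wilcoxon(a, b, alternative="less")
        return float(res.statistic), float(res.pvalue)
    if scheme == "ttest_bonferroni":
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("ttest_bonferroni expects (n_runs, n_horizons) arrays")
        m = n_horizons if n_horizons is not None else a.shape[1]
        out = []
        for k in range(a.shape[1]):
            res = stats.ttest_ind(a[:, k], b[:, k])
            out.append((float(res.statistic), float(min(1.0, res.pvalue * m))))
        return out
    if scheme == "anova2":
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("anova2 expects (n_runs, n_horizons) arrays")
        y, model_f, horizon_f = [], [], []
        for arr, m in ((a, 0), (b, 1)):
            for run in range(arr.shape[0]):
                for k in range(arr.shape[1]):
                    y.append(arr[run, k]); model_f.append(m); horizon_f.append(k)
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        df = pd.DataFrame({"y": y, "model": model_f, "horizon": horizon_f})
        fit = ols("y ~ C(model) + C(horizon)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        return (float(table.loc["C(model)", "F"]),
                float(table.loc["C(model)", "PR(>F)"]))
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# timescale scan
# ---------------------------------------------------------------------------

@dataclass
class TimescaleScanResult:
    rates: list
    nmse_mean: np.ndarray              # mean one-step nMSE per rate
    nmse_per_seed: np.ndarray          # (n_rates, n_seeds)
    cosine_mean: np.ndarray            # mean |aligned-Û| cosine similarity per rate
    cosine_per_seed: np.ndarray
    best_rate: int                     # argmin of mean nMSE
    best_rate_cosine: int              # argmax of mean |cosine|


def timescale_scan(sim_config: SimConfig, rates, train_config: TrainConfig,
                   seeds=(0, 1, 2), total_updates: int | None = None,
                   n_chains: int = 20, n_start_points: int = 40,
                   lower_bound_states: int = 200,
                   lower_bound_instances: int = 20,
                   transfer_init: bool = True) -> TimescaleScanResult:
    """Train one RTRBM per downsampling rate and seed; locate the rate whose
    one-step-ahead nMSE is lowest.

    Every model receives the same number of gradient updates regardless of
    how much data survives downsampling (``total_updates``; derived from the
    train config at rate 1 when not given).  nMSE is normalized per rate
    with the closed-form naive bound of that rate's test raster and a single
    generator-level lower bound.  Also reports the aligned-Û cosine
    similarity with the generator's U per rate.
    """
    rates = [int(r) for r in rates]
    if not rates or min(rates) < 1:
        raise ValueError("rates must be nonempty, each >= 1")
    nr, ns = len(rates), len(seeds)
    nmse_arr = np.full((nr, ns), np.nan)
    cos_arr = np.full((nr, ns), np.nan)

    if total_updates is None:
        # reference budget: what the config would spend on the full-rate data
        full_cols = int(sim_config.T * 0.7)
        n_batches = max(1, int(np.ceil(full_cols / train_config.batch_length)))
        per_epoch = max(1, int(np.ceil(n_batches / train_config.batches_per_update)))
        total_updates = train_config.epochs * per_epoch

    for si, seed in enumerate(seeds):
        cfg = SimConfig(**{**sim_config.to_dict(), "seed": int(seed)})
        sim = simulate(cfg)
        bound_rng = np.random.default_rng(int(seed) + 900_001)
        mse_var, _ = lower_bound_mse(cfg, bound_rng, n_states=lower_bound_states,
                                     n_instances=lower_bound_instances)
        for ri, rate in enumerate(rates):
            ds = downsample(sim.raster, rate) if rate > 1 else sim.raster
            train_segs, test_segs = split_segments(ds)
            train_r, test_r = _concat(train_segs), _concat(test_segs)
            if train_r.n_steps < 50:
                raise ValueError(f"rate {rate} leaves {train_r.n_steps} training columns (<50)")
            tc = _budgeted_config(train_config, train_r.n_steps, total_updates,
                                  seed=int(seed) * 1000 + rate)
            init_W = assembly_init_W(train_r, tc.n_hidden) if transfer_init else None
            params, _ = train_rtrbm(train_r, tc, init_W=init_W)
            eval_rng = np.random.default_rng(int(seed) * 1000 + rate + 500_000)
            rep = prediction_mse(params, test_r, [1], eval_rng,
                                 n_chains=n_chains, K=15,
                                 n_start_points=n_start_points)
            rep = nmse(rep, mse_naive=naive_mse(test_r), mse_var=mse_var)
            nmse_arr[ri, si] = rep.nmse_per_horizon[0]
            amap = match_assemblies(params.W, sim.membership)
            u_aligned = align_U(params.U, amap)
            cos_arr[ri, si] = cosine_similarity_U(sim.U_true, u_aligned)

    nmse_mean = nmse_arr.mean(axis=1)
    cos_mean = np.abs(cos_arr).mean(axis=1)
    return TimescaleScanResult(
        rates=rates, nmse_mean=nmse_mean, nmse_per_seed=nmse_arr,
        cosine_mean=cos_mean, cosine_per_seed=cos_arr,
        best_rate=rates[int(np.argmin(nmse_mean))],
        best_rate_cosine=rates[int(np.argmax(cos_mean))],
    )


def _budgeted_config(base: TrainConfig, n_train_cols: int,
                     total_updates: int | None, seed: int) -> TrainConfig:
    """Rescale epochs so every rate gets the same number of gradient updates."""
    from dataclasses import replace
    n_batches = max(1, int(np.ceil(n_train_cols / base.batch_length)))
    updates_per_epoch = max(1, int(np.ceil(n_batches / base.batches_per_update)))
    if total_updates is None:
        total_updates = base.epochs * updates_per_epoch
    epochs = max(1, int(round(total_updates / updates_per_epoch)))
    return replace(base, epochs=epochs, seed=seed)
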