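"""RTRBM maximum-likelihood training: contrastive divergence through time.

The sequence log-likelihood factorizes over time as

    L = Σ_t log P(v[t] | r[t-1]),

where each factor is a static-RBM likelihood with hidden bias bh + U r[t-1]
(binit at t = 1) and r is the deterministic mean-field recursion over the
*data*.  The gradient therefore has two parts:

* a static part — per-time-step CD gradients under the conditional RBM at t,
  summed over t (teacher forcing: the negative chain at t is conditioned on
  the data-derived r[t-1]);
* a temporal part — the likelihood also depends on the parameters through
  r[t], which feeds every later factor.  The adjoint d[t] = ∂L/∂r[t] is
  accumulated backward through time,

      d[T] = 0,
      d[t] = Uᵀ [ (r[t+1] − q[t+1]) + d[t+1] ⊙ r[t+1] ⊙ (1 − r[t+1]) ],

  with q[t] the model-side hidden expectation at t, and chained into the
  parameter blocks through the sigmoid recursion.

On the data side the hidden "samples" are the conditional means r[t]
(mean-field); the model side uses K-step Gibbs negatives, or exact enumerated
moments on tiny models (the oracle route used to validate the estimator
against finite differences of the exact sequence log-likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as sigmoid

from .model_core import (
    RBMParams,
    RTRBMParams,
    SpikeRaster,
    exact_model_moments,
    exact_partition_small,
    gibbs_chain,
)
from .rbm_training import TrainConfig, make_batches
from .rtrbm_core import hidden_trace

__all__ = [
    "RTRBMGradients",
    "bptt_gradients",
    "train_rtrbm",
    "reconstruction_mse",
    "exact_sequence_loglik",
    "init_rtrbm_params",
    "assembly_init_W",
]


@dataclass
class RTRBMGradients:
    W: np.ndarray
    U: np.ndarray
    bv: np.ndarray
    bh: np.ndarray
    binit: np.ndarray

    def scaled_add(self, other, weight=1.0):
        for name in ("W", "U", "bv", "bh", "binit"):
            getattr(self, name).__iadd__(weight * getattr(other, name))

    def norm(self) -> float:
        return float(np.sqrt(sum(np.sum(getattr(self, n) ** 2)
                                 for n in ("W", "U", "bv", "bh", "binit"))))


def _zeros_like(params: RTRBMParams) -> RTRBMGradients:
    return RTRBMGradients(np.zeros_like(params.W), np.zeros_like(params.U),
                          np.zeros_like(params.bv), np.zeros_like(params.bh),
                          np.zeros_like(params.binit))


def _bias_trace(params: RTRBMParams, r: np.ndarray) -> np.ndarray:
    """Conditional hidden biases C (Nh × T): binit at t=0, bh + U r[t-1] after."""
    T = r.shape[1]
    C = np.empty((params.n_hidden, T))
    C[:, 0] = params.binit
    if T > 1:
        C[:, 1:] = params.bh[:, None] + params.U @ r[:, :-1]
    return C


def bptt_gradients(v_seq, params: RTRBMParams, K: int, rng,
                   negative: str = "cd", average: bool = True) -> RTRBMGradients:
    """Gradient of the sequence log-likelihood (ascent direction).

    ``negative="cd"`` runs a K-step Gibbs chain per time-step, all steps in
    parallel, each conditioned on the data-derived r[t-1]; ``"exact"``
    substitutes enumerated model moments (small models only).  With
    ``average=True`` the gradient is per-time-step (divided by T).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    v = v_seq.values if isinstance(v_seq, SpikeRaster) else np.asarray(v_seq)
    v = v.astype(float)
    if v.ndim == 1:
        v = v[:, None]
    T = v.shape[1]
    r = hidden_trace(v, params).r                   # (Nh, T), data side
    C = _bias_trace(params, r)

    if negative == "cd":
        static = RBMParams(params.W, params.bv, np.zeros(params.n_hidden))
        v_neg, _, _, _ = gibbs_chain(v, static, K, rng, extra_hidden_bias=C)
        q_neg = sigmoid(params.W @ v_neg + C)
        ev = v_neg
        ehv = None                                  # assembled below from samples
    elif negative == "exact":
        ev = np.empty_like(v)
        q_neg = np.empty_like(r)
        ehv_sum = np.zeros_like(params.W)
        for t in range(T):
            cond = RBMParams(params.W, params.bv, C[:, t])
            mv, mh, mhv = exact_model_moments(cond)
            ev[:, t] = mv
            q_neg[:, t] = mh
            ehv_sum += mhv
        ehv = ehv_sum
    else:
        raise ValueError(f"unknown negative phase {negative!r}")

    # static part: per-time-step CD gradients summed over t
    g = _zeros_like(params)
    diff_h = r - q_neg                              # (Nh, T)
    g.W = r @ v.T - (q_neg @ ev.T if ehv is None else ehv)
    g.bv = (v - ev).sum(axis=1)
    g.binit = diff_h[:, 0].copy()
    if T > 1:
        g.bh = diff_h[:, 1:].sum(axis=1)
        g.U = diff_h[:, 1:] @ r[:, :-1].T

    # temporal part: adjoint d[t] = ∂L/∂r[t], backward through time
    d = np.zeros_like(r)
    for t in range(T - 2, -1, -1):
        slope = r[:, t + 1] * (1.0 - r[:, t + 1])
        d[:, t] = params.U.T @ (diff_h[:, t + 1] + d[:, t + 1] * slope)
    s = d * r * (1.0 - r)                           # through the sigmoid at each t
    g.W += s @ v.T
    g.binit += s[:, 0]
    if T > 1:
        g.bh += s[:, 1:].sum(axis=1)
        g.U += s[:, 1:] @ r[:, :-1].T

    if average:
        for name in ("W", "U", "bv", "bh", "binit"):
            getattr(g, name).__itruediv__(T)
    return g


def exact_sequence_loglik(v_seq, params: RTRBMParams) -> float:
    """Σ_t log P(v[t] | r[t-1]) with each conditional partition sum enumerated
    exactly (tiny models only) — the oracle the BPTT gradient is checked
    against by finite differences."""
    v = v_seq.values if isinstance(v_seq, SpikeRaster) else np.asarray(v_seq)
    v = v.astype(float)
    if v.ndim == 1:
        v = v[:, None]
    r = hidden_trace(v, params).r
    C = _bias_trace(params, r)
    total = 0.0
    for t in range(v.shape[1]):
        act = C[:, t] + params.W @ v[:, t]
        unnorm = params.bv @ v[:, t] + np.logaddexp(0.0, act).sum()
        _, logZ = exact_partition_small(RBMParams(params.W, params.bv, C[:, t]))
        total += unnorm - logZ
    return float(total)


def assembly_init_W(raster, n_hidden: int, scale: float = 3.0) -> np.ndarray:
    """Assembly-detection warm start for the visible-to-hidden weights.

    Neurons are partitioned into ``n_hidden`` groups by average-linkage
    agglomerative clustering of the correlation distance 1 − corr(v_i, v_j);
    W is the group indicator scaled by ``scale``.  Coactive neuron groups are
    static structure, so a correlation partition recovers them without any
    temporal model; handing this W to :func:`train_rtrbm` in transfer mode
    (reduced learning rate on W, L1 penalty) leaves the visible-to-hidden
    map interpretable — one dominant weight per neuron — while U, learned at
    the full rate, absorbs the between-assembly dynamics.  This mirrors the
    transfer-learning recipe used on real recordings, with the correlation
    partition standing in for an externally trained sparse model.

    De novo maximum-likelihood training from small random weights is also
    supported but tends toward mixed difference features (one positive and
    one negative assembly per hidden unit), which model the data about as
    well yet are not assembly-aligned.
    """
    from sklearn.cluster import AgglomerativeClustering

    v = raster.values.astype(float) if isinstance(raster, SpikeRaster) else np.asarray(raster, dtype=float)
    if v.shape[0] < n_hidden:
        raise ValueError("fewer neurons than requested hidden units")
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(v)
    C = np.nan_to_num(C, nan=0.0)                   # silent neurons: no evidence
    np.fill_diagonal(C, 1.0)
    D = 1.0 - C
    labels = AgglomerativeClustering(n_clusters=n_hidden, linkage="average",
                                     metric="precomputed").fit_predict(D)
    W = np.zeros((n_hidden, v.shape[0]))
    for j in range(n_hidden):
        W[j, labels == j] = scale
    return W


def init_rtrbm_params(n_visible: int, n_hidden: int, rng,
                      init_W=None) -> RTRBMParams:
    if init_W is not None:
        W = np.asarray(init_W, dtype=float).copy()
        if W.ndim != 2 or W.shape[1] != n_visible:
            raise ValueError(
                f"donor W shape {W.shape} incompatible with {n_visible} visible units"
            )
        n_hidden = W.shape[0]
    else:
        W = rng.normal(0.0, 0.01 / np.sqrt(n_visible), size=(n_hidden, n_visible))
    return RTRBMParams(W, np.zeros((n_hidden, n_hidden)), np.zeros(n_visible),
                       np.zeros(n_hidden), np.zeros(n_hidden))


def train_rtrbm(data: SpikeRaster, config: TrainConfig, init_W=None,
                init: RTRBMParams | None = None):
    """Gradient ascent on the sequence likelihood with CD+BPTT gradients.

    Mini-batches are contiguous time windows (each treated as a sequence
    starting at its own t = 1, so binit is learned from batch onsets);
    ``config.batches_per_update`` batch gradients are accumulated per
    parameter update.  Transfer mode (``init_W`` given) reduces the learning
    rate on W — by two orders of magnitude unless the config overrides — and
    applies the L1 penalty λ to W.  Deterministic given ``config.seed``.

    Returns ``(params, log)``; the log holds per-epoch reconstruction MSE and
    gradient norms, and flags degenerate (all-zero / all-one) neurons.
    """
    v_all = data.values.astype(float)
    nv, T = v_all.shape
    rng = np.random.default_rng(config.seed)
    if init is not None:
        params = init.copy()
    else:
        params = init_rtrbm_params(nv, config.n_hidden, rng, init_W=init_W)
    if params.n_visible != nv:
        raise ValueError("init params incompatible with data")

    transfer = init_W is not None
    w_factor = config.w_learning_rate_factor
    if transfer and w_factor == 1.0:
        w_factor = 1e-2

    means = v_all.mean(axis=1)
    degenerate = np.flatnonzero((means == 0.0) | (means == 1.0))

    batches = make_batches(T, config.batch_length)
    vel = _zeros_like(params)
    log = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(batches))
        grad_norm_sum, n_updates = 0.0, 0
        for i in range(0, len(order), config.batches_per_update):
            group = order[i:i + config.batches_per_update]
            acc = _zeros_like(params)
            for bi in group:
                s, e = batches[bi]
                gb = bptt_gradients(v_all[:, s:e], params, config.cd_steps, rng)
                acc.scaled_add(gb, 1.0 / len(group))
            if config.l1_weight > 0:
                acc.W -= config.l1_weight * np.sign(params.W)
            if not np.isfinite(acc.norm()):
                raise RuntimeError(f"non-finite gradient at epoch {epoch}")
            if config.momentum > 0:
                for name in ("W", "U", "bv", "bh", "binit"):
                    vnew = config.momentum * getattr(vel, name) + getattr(acc, name)
                    setattr(vel, name, vnew)
                step = vel
            else:
                step = acc
            eta = config.learning_rate
            params.W = params.W + eta * w_factor * step.W
            params.U = params.U + eta * step.U
            params.bv = params.bv + eta * step.bv
            params.bh = params.bh + eta * step.bh
            params.binit = params.binit + eta * step.binit
            grad_norm_sum += acc.norm()
            n_updates += 1
        recon = reconstruction_mse(data, params, config.cd_steps,
                                   np.random.default_rng(config.seed + 1 + epoch))
        log.append({"epoch": epoch, "recon_mse": recon,
                    "grad_norm": grad_norm_sum / max(n_updates, 1),
                    "degenerate_neurons": degenerate.tolist()})
        if config.early_stop_tol > 0 and len(log) > 1:
            if abs(log[-2]["recon_mse"] - recon) < config.early_stop_tol:
                break
    return params, log


def reconstruction_mse(data: SpikeRaster, params: RTRBMParams, K: int, rng) -> float:
    """Mean of (v_data − v_model)² after one K-step Gibbs reconstruction of
    each time column under its conditional RBM (teacher-forced biases)."""
    v = data.values.astype(float) if isinstance(data, SpikeRaster) else np.asarray(data, dtype=float)
    r = hidden_trace(v, params).r
    C = _bias_trace(params, r)
    static = RBMParams(params.W, params.bv, np.zeros(params.n_hidden))
    v_rec, _, _, _ = gibbs_chain(v, static, K, rng, extra_hidden_bias=C)
    return float(np.mean((v - v_rec) ** 2))
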