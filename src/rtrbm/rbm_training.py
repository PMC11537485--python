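"""Contrastive-divergence training of the static RBM.

Maximum-likelihood gradient ascent on ⟨log P(v)⟩_data with the intractable
model expectation replaced by a K-step Gibbs chain started at each data
column (CD-K).  Columns of the spike raster are treated as i.i.d. samples;
mini-batches are contiguous time windows so the same segmenting serves the
temporal model later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    RBMParams,
    SpikeRaster,
    exact_model_moments,
    gibbs_chain,
    p_h_given_v,
    p_v_given_h,
)

__all__ = ["TrainConfig", "Gradients", "cd_gradient", "train_rbm", "init_rbm_params"]


@dataclass
class TrainConfig:
    """Hyperparameters shared by the RBM and RTRBM trainers.

    ``learning_rate`` is the SGD step η; ``cd_steps`` the Gibbs chain length
    K (K=1 is generally sufficient during training); ``batch_length`` the
    number of contiguous time-steps per batch; ``batches_per_update`` how many
    batch gradients are accumulated before one parameter update;
    ``l1_weight`` the λ of the L1 penalty on W; ``w_learning_rate_factor``
    multiplies η for the W block (transfer learning reduces it by two orders
    of magnitude); ``momentum`` is optional plain-SGD momentum (default off).
    """

    n_hidden: int = 10
    epochs: int = 100
    learning_rate: float = 1e-3
    cd_steps: int = 1
    batch_length: int = 16
    batches_per_update: int = 20
    l1_weight: float = 0.0
    w_learning_rate_factor: float = 1.0
    momentum: float = 0.0
    seed: int = 0
    early_stop_tol: float = 0.0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        if self.batch_length < 1 or self.batches_per_update < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.l1_weight < 0 or self.w_learning_rate_factor < 0:
            raise ValueError("l1_weight and w_learning_rate_factor must be >= 0")


@dataclass
class Gradients:
    """Gradient blocks of the log-likelihood (ascent direction)."""

    W: np.ndarray
    bv: np.ndarray
    bh: np.ndarray

    def scaled_add(self, other, weight=1.0):
        self.W += weight * other.W
        self.bv += weight * other.bv
        self.bh += weight * other.bh

    def norm(self) -> float:
        return float(np.sqrt(np.sum(self.W**2) + np.sum(self.bv**2) + np.sum(self.bh**2)))


def cd_gradient(batch, params: RBMParams, K: int, rng,
                negative: str = "cd") -> Gradients:
    """CD-K estimate of ∇θ ⟨log P(v)⟩ over a batch of visible columns.

    The data-side hidden terms use the conditional means r = σ(bh + Wv); the
    model side is a K-step Gibbs chain per column (``negative="cd"``) or the
    exact enumerated model moments (``negative="exact"``, small models only —
    the oracle used to validate the estimator).
    """
    v = np.asarray(batch, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.size == 0:
        raise ValueError("empty batch")
    n = v.shape[1]

    r_data = p_h_given_v(v, params)
    gW = r_data @ v.T / n
    gbv = v.mean(axis=1)
    gbh = r_data.mean(axis=1)

    if negative == "cd":
        v_neg, _, _, _ = gibbs_chain(v, params, K, rng)
        q_neg = p_h_given_v(v_neg, params)
        gW -= q_neg @ v_neg.T / n
        gbv -= v_neg.mean(axis=1)
        gbh -= q_neg.mean(axis=1)
    elif negative == "exact":
        mean_v, mean_h, mean_hv = exact_model_moments(params)
        gW -= mean_hv
        gbv -= mean_v
        gbh -= mean_h
    else:
        raise ValueError(f"unknown negative phase {negative!r}")
    return Gradients(gW, gbv, gbh)


def init_rbm_params(n_visible: int, n_hidden: int, rng) -> RBMParams:
    """Small centered-Gaussian W (scale 0.01/√Nv), zero biases."""
    W = rng.normal(0.0, 0.01 / np.sqrt(n_visible), size=(n_hidden, n_visible))
    return RBMParams(W, np.zeros(n_visible), np.zeros(n_hidden))


def make_batches(T: int, batch_length: int):
    """Contiguous, non-overlapping time windows (remainder window kept)."""
    starts = range(0, T, batch_length)
    return [(s, min(s + batch_length, T)) for s in starts]


def train_rbm(data: SpikeRaster, config: TrainConfig,
              init: RBMParams | None = None):
    """Stochastic gradient ascent θ := θ + η ∇θL with CD-K gradients.

    Returns ``(params, log)`` where ``log`` is a list of per-epoch dicts
    (reconstruction MSE, gradient norm).  Deterministic given ``config.seed``.
    """
    v_all = data.values.astype(float)
    nv, T = v_all.shape
    rng = np.random.default_rng(config.seed)
    params = init.copy() if init is not None else init_rbm_params(nv, config.n_hidden, rng)
    if params.n_visible != nv:
        raise ValueError("init params incompatible with data")

    batches = make_batches(T, config.batch_length)
    vel = Gradients(np.zeros_like(params.W), np.zeros_like(params.bv),
                    np.zeros_like(params.bh))
    log = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(batches))
        grad_norm_sum, n_updates = 0.0, 0
        for i in range(0, len(order), config.batches_per_update):
            acc = Gradients(np.zeros_like(params.W), np.zeros_like(params.bv),
                            np.zeros_like(params.bh))
            group = order[i:i + config.batches_per_update]
            for bi in group:
                s, e = batches[bi]
                g = cd_gradient(v_all[:, s:e], params, config.cd_steps, rng)
                acc.scaled_add(g, 1.0 / len(group))
            if config.l1_weight > 0:
                acc.W -= config.l1_weight * np.sign(params.W)
            if not np.isfinite(acc.norm()):
                raise RuntimeError(f"non-finite gradient at epoch {epoch}")
            if config.momentum > 0:
                vel.W = config.momentum * vel.W + acc.W
                vel.bv = config.momentum * vel.bv + acc.bv
                vel.bh = config.momentum * vel.bh + acc.bh
                step = vel
            else:
                step = acc
            eta = config.learning_rate
            params.W = params.W + eta * config.w_learning_rate_factor * step.W
            params.bv = params.bv + eta * step.bv
            params.bh = params.bh + eta * step.bh
            grad_norm_sum += acc.norm()
            n_updates += 1
        recon = _reconstruction_mse(v_all, params, rng)
        log.append({"epoch": epoch, "recon_mse": recon,
                    "grad_norm": grad_norm_sum / max(n_updates, 1)})
        if config.early_stop_tol > 0 and len(log) > 1:
            if abs(log[-2]["recon_mse"] - recon) < config.early_stop_tol:
                break
    return params, log


def _reconstruction_mse(v_all, params, rng):
    p_h = p_h_given_v(v_all, params)
    h = (rng.random(p_h.shape) < p_h).astype(float)
    p_v = p_v_given_h(h, params)
    v_rec = (rng.random(p_v.shape) < p_v).astype(float)
    return float(np.mean((v_all - v_rec) ** 2))
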