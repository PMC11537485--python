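"""RTRBM forward recursion and sequential generative inference.

The RTRBM chains RBMs in time: the model at step t is an RBM whose hidden
bias is shifted by U r[t-1], where r[t] is the *mean-field* hidden state

    r[1] = σ(W v[1] + binit),
    r[t] = σ(W v[t] + bh + U r[t-1]),   t > 1.

Real-valued r values, never binary hidden samples, propagate to the next
step.  Generation alternates: compute r[t] from the sampled v[t], then draw
v[t+1] by K-step Gibbs under the conditional RBM at t+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as sigmoid

from .model_core import (
    HiddenTrace,
    RBMParams,
    RTRBMParams,
    SpikeRaster,
)

__all__ = ["hidden_trace", "conditional_rbm_at_t", "sample_sequence", "SequenceSample"]


def hidden_trace(v_seq: SpikeRaster | np.ndarray, params: RTRBMParams) -> HiddenTrace:
    """Deterministic mean-field hidden trajectory r (Nh × T) for a raster."""
    v = v_seq.values if isinstance(v_seq, SpikeRaster) else np.asarray(v_seq)
    v = v.astype(float)
    if v.ndim == 1:
        v = v[:, None]
    if v.shape[0] != params.n_visible:
        raise ValueError(
            f"raster has {v.shape[0]} neurons, model has {params.n_visible} visible units"
        )
    T = v.shape[1]
    act = params.W @ v                               # (Nh, T)
    r = np.empty((params.n_hidden, T))
    r[:, 0] = sigmoid(act[:, 0] + params.binit)
    for t in range(1, T):
        r[:, t] = sigmoid(act[:, t] + params.bh + params.U @ r[:, t - 1])
    return HiddenTrace(r)


def conditional_rbm_at_t(r_prev, params: RTRBMParams) -> RBMParams:
    """The static RBM governing time t given the previous mean-field state.

    ``r_prev=None`` selects the t = 1 convention (hidden bias = binit);
    otherwise the hidden bias is ``bh + U r_prev``.  All static-RBM
    operations (conditionals, Gibbs, exact partition) then apply unchanged.
    """
    if r_prev is None:
        bias = params.binit
    else:
        r_prev = np.asarray(r_prev, dtype=float)
        if r_prev.shape != (params.n_hidden,):
            raise ValueError("r_prev must have length Nh")
        if (r_prev < 0).any() or (r_prev > 1).any():
            raise ValueError("r_prev entries must lie in [0, 1]")
        bias = params.bh + params.U @ r_prev
    return RBMParams(params.W, params.bv, bias)


@dataclass
class SequenceSample:
    """Rollout bundle: per-chain binary visibles, mean-field hidden traces,
    and the across-chain mean per-step visible probabilities."""

    v: np.ndarray        # (n_chains, Nv, T)
    r: np.ndarray        # (n_chains, Nh, T)
    p_v: np.ndarray      # (Nv, T) mean conditional probability across chains


def sample_sequence(params: RTRBMParams, T: int, rng, v_init=None,
                    K: int = 1, n_chains: int = 1,
                    r_init=None, start: str = "prior") -> SequenceSample:
    """Generate ``T`` new time-steps from the RTRBM, ``n_chains`` in parallel.

    Each step draws v[t] by K-step block Gibbs under the conditional RBM at
    t (hidden bias bh + U r[t-1]); mean-field r values, never binary hidden
    samples, propagate to the next step.  Two chain initializations:

    * ``start="prior"`` — the chain opens on the hidden side from the
      temporal prior: h ~ Bern(σ(bh + U r[t-1])), then v ~ P(v|h), then K−1
      further sweeps.  K=1 is an ancestral draw through the hidden layer;
      the natural generative sampler (temporal information enters
      exclusively through the hidden bias).

    * ``start="state"`` — the chain opens on the visible side at the
      previous visible state (the observed ``v_init`` at the first step,
      the preceding sample afterwards) and performs K full sweeps.  This is
      the inference scheme used for prediction benchmarks: it interpolates
      between persistence (small K) and the conditional equilibrium, so its
      error reflects how well the learned temporal bias explains the next
      observation.

    If ``v_init`` is given it seeds r via the t = 1 conditional (the rollout
    then continues the sequence); ``r_init`` may instead supply the previous
    mean-field state directly (e.g. from :func:`hidden_trace` over observed
    history), with ``v_init`` then only providing the state-mode chain
    start.  Without either, the first step uses the binit prior (state mode
    starts from an all-zero column).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if start not in ("prior", "state"):
        raise ValueError(f"unknown chain start {start!r}")
    nv, nh = params.n_visible, params.n_hidden
    v_out = np.empty((n_chains, nv, T))
    r_out = np.empty((n_chains, nh, T))
    p_sum = np.zeros((nv, T))

    # chains advance as columns of an (Nv, n_chains) / (Nh, n_chains) matrix
    v0 = None
    if v_init is not None:
        v0 = np.asarray(v_init, dtype=float)
        v0 = np.broadcast_to(v0 if v0.ndim == 2 else v0[:, None],
                             (nv, n_chains)).copy()
    if r_init is not None:
        r_prev = np.asarray(r_init, dtype=float)
        r_prev = np.broadcast_to(
            r_prev if r_prev.ndim == 2 else r_prev[:, None], (nh, n_chains)
        ).copy()
        bias = params.bh[:, None] + params.U @ r_prev
    elif v0 is not None:
        r_prev = sigmoid(params.W @ v0 + params.binit[:, None])
        bias = params.bh[:, None] + params.U @ r_prev
    else:
        bias = np.broadcast_to(params.binit[:, None], (nh, n_chains)).copy()
    v_cur = v0 if v0 is not None else np.zeros((nv, n_chains))

    def sweep(v, n_sweeps):
        p_v = None
        for _ in range(n_sweeps):
            p_h = sigmoid(params.W @ v + bias)
            h = (rng.random((nh, n_chains)) < p_h).astype(float)
            p_v = sigmoid(params.W.T @ h + params.bv[:, None])
            v = (rng.random((nv, n_chains)) < p_v).astype(float)
        return v, p_v

    for t in range(T):
        if start == "prior":
            h = (rng.random((nh, n_chains)) < sigmoid(bias)).astype(float)
            p_v = sigmoid(params.W.T @ h + params.bv[:, None])
            v_cur = (rng.random((nv, n_chains)) < p_v).astype(float)
            if K > 1:
                v_cur, p_v = sweep(v_cur, K - 1)
        else:
            v_cur, p_v = sweep(v_cur, K)
        r_cur = sigmoid(params.W @ v_cur + bias)
        v_out[:, :, t] = v_cur.T
        r_out[:, :, t] = r_cur.T
        p_sum[:, t] = p_v.mean(axis=1)
        bias = params.bh[:, None] + params.U @ r_cur
    return SequenceSample(v_out, r_out, p_sum)
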