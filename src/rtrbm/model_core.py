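"""Static RBM core: parameter containers, conditionals, Gibbs transitions.

The restricted Boltzmann machine used here is fully binary: visible units
``v ∈ {0,1}^Nv`` carry the (spike-raster) data, hidden units ``h ∈ {0,1}^Nh``
represent neural assemblies.  The joint distribution is

    P(v, h) = exp(-E(v, h)) / Z,
    E(v, h) = -(bv·v + bh·h + hᵀ W v),

with weights stored hidden-major, ``W`` of shape ``(Nh, Nv)``, so that the
interaction term reads ``hᵀ W v``.  Because the graph is bipartite, both
conditionals factorize into independent logistic units, which is what makes
blockwise Gibbs sampling and contrastive divergence practical.

Exact enumeration oracles (partition function, marginals, model moments) are
provided for small models; they are the ground truth the samplers and the
gradient estimators are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid
from scipy.special import logsumexp

__all__ = [
    "SpikeRaster",
    "RBMParams",
    "RTRBMParams",
    "HiddenTrace",
    "rbm_energy",
    "p_h_given_v",
    "p_v_given_h",
    "gibbs_chain",
    "gibbs_step",
    "exact_partition_small",
    "exact_visible_marginal",
    "exact_model_moments",
    "enumerate_states",
]

# Enumeration budget: 2^24 joint states is the most the exact oracles accept.
MAX_ENUM_UNITS = 24


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeRaster:
    """Binary neurons × time matrix, the universal data currency.

    Parameters
    ----------
    values : ndarray of shape (Nv, T)
        Strictly 0/1 entries; rows are neurons (visible units), columns are
        time-steps.
    dt : float, optional
        Sampling interval in arbitrary time units.  Downsampling multiplies
        it by the downsampling factor.
    unit_ids : sequence, optional
        Identifier per neuron, length Nv.
    """

    values: np.ndarray
    dt: float | None = None
    unit_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("raster needs at least one neuron and one time-step")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            idx = np.argwhere(bad)[:5]
            raise ValueError(
                f"raster entries must be 0/1; offending entries at (neuron, t) = "
                f"{[tuple(map(int, ij)) for ij in idx]}"
            )
        self.values = self.values.astype(np.uint8, copy=False)
        if self.unit_ids is not None and len(self.unit_ids) != self.values.shape[0]:
            raise ValueError("unit_ids length must equal the number of neurons")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


def _as_finite(name, arr, ndim):
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class RBMParams:
    """Static RBM parameters: W (Nh × Nv), visible bias bv, hidden bias bh."""

    W: np.ndarray
    bv: np.ndarray
    bh: np.ndarray

    def __post_init__(self):
        self.W = _as_finite("W", self.W, 2)
        self.bv = _as_finite("bv", self.bv, 1)
        self.bh = _as_finite("bh", self.bh, 1)
        nh, nv = self.W.shape
        if self.bv.shape[0] != nv or self.bh.shape[0] != nh:
            raise ValueError(
                f"inconsistent shapes: W {self.W.shape}, bv {self.bv.shape}, "
                f"bh {self.bh.shape}"
            )

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.bv.copy(), self.bh.copy())


@dataclass
class RTRBMParams:
    """RTRBM parameters: static RBM blocks plus temporal weights.

    ``U`` (Nh × Nh) feeds the previous mean-field hidden state into the
    current hidden bias: the conditional model at time t is an RBM whose
    hidden bias is ``bh + U r[t-1]`` (``binit`` at t = 1).  U is directed and
    need not be symmetric; ``U[i, j]`` couples assembly j at t-1 to assembly
    i at t.
    """

    W: np.ndarray
    U: np.ndarray
    bv: np.ndarray
    bh: np.ndarray
    binit: np.ndarray

    def __post_init__(self):
        self.W = _as_finite("W", self.W, 2)
        self.U = _as_finite("U", self.U, 2)
        self.bv = _as_finite("bv", self.bv, 1)
        self.bh = _as_finite("bh", self.bh, 1)
        self.binit = _as_finite("binit", self.binit, 1)
        nh, nv = self.W.shape
        if self.U.shape != (nh, nh):
            raise ValueError(f"U must be square ({nh}, {nh}), got {self.U.shape}")
        if self.bv.shape[0] != nv or self.bh.shape[0] != nh or self.binit.shape[0] != nh:
            raise ValueError("bias shapes inconsistent with W")

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    def copy(self) -> "RTRBMParams":
        return RTRBMParams(self.W.copy(), self.U.copy(), self.bv.copy(),
                           self.bh.copy(), self.binit.copy())


@dataclass
class HiddenTrace:
    """Mean-field hidden trajectory r (Nh × T), each entry in [0, 1]."""

    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2:
            raise ValueError("hidden trace must be 2-D (Nh, T)")
        if (self.r < 0).any() or (self.r > 1).any():
            raise ValueError("hidden trace entries must lie in [0, 1]")


# ---------------------------------------------------------------------------
# energy and conditionals
# ---------------------------------------------------------------------------

def rbm_energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """E(v, h) = -(bv·v + bh·h + hᵀ W v)."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError(
            f"state shapes {v.shape}/{h.shape} do not match model "
            f"({params.n_visible} visible, {params.n_hidden} hidden)"
        )
    return float(-(params.bv @ v + params.bh @ h + h @ params.W @ v))


def p_h_given_v(v, params: RBMParams, extra_hidden_bias=None) -> np.ndarray:
    """P(h_j = 1 | v) = σ(bh_j + Σ_i W_ji v_i [+ extra_j]).

    ``v`` may be a single column (Nv,) or a matrix (Nv, T); the result matches
    in shape on the hidden side.  ``extra_hidden_bias`` is the hook the RTRBM
    uses to inject ``U r[t-1]``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[0] != params.n_visible:
        raise ValueError(f"v has {v.shape[0]} rows, model has {params.n_visible} visible units")
    act = params.W @ v
    if v.ndim == 1:
        act = act + params.bh
    else:
        act = act + params.bh[:, None]
    if extra_hidden_bias is not None:
        extra = np.asarray(extra_hidden_bias, dtype=float)
        if extra.shape[0] != params.n_hidden:
            raise ValueError("extra_hidden_bias length must equal Nh")
        act = act + (extra if act.ndim == extra.ndim else extra[:, None])
    return sigmoid(act)


def p_v_given_h(h, params: RBMParams) -> np.ndarray:
    """P(v_i = 1 | h) = σ(bv_i + Σ_j W_ji h_j); h may be (Nh,) or (Nh, T)."""
    h = np.asarray(h, dtype=float)
    if h.shape[0] != params.n_hidden:
        raise ValueError(f"h has {h.shape[0]} rows, model has {params.n_hidden} hidden units")
    act = params.W.T @ h
    act = act + (params.bv if act.ndim == 1 else params.bv[:, None])
    return sigmoid(act)


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------

def _bernoulli(p, rng):
    return (rng.random(p.shape) < p).astype(float)


def gibbs_step(v, params: RBMParams, rng, extra_hidden_bias=None):
    """One blockwise Gibbs sweep h ~ P(h|v), v' ~ P(v|h).

    Returns ``(v', h, p_v, p_h)`` where the probabilities are the conditionals
    from which the samples were drawn.  Vectorized over columns.
    """
    p_h = p_h_given_v(v, params, extra_hidden_bias)
    h = _bernoulli(p_h, rng)
    p_v = p_v_given_h(h, params)
    v_new = _bernoulli(p_v, rng)
    return v_new, h, p_v, p_h


def gibbs_chain(v0, params: RBMParams, K: int, rng, extra_hidden_bias=None):
    """Run K alternating Gibbs sweeps from ``v0``.

    Returns ``(vK, hK, p_vK, p_hK)``: the final visible/hidden samples and the
    final-step conditional probabilities.  ``v0`` may be a single column or a
    batch of columns.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    v = np.asarray(v0, dtype=float)
    for _ in range(K):
        v, h, p_v, p_h = gibbs_step(v, params, rng, extra_hidden_bias)
    # hidden conditional at the *final* visible sample
    p_h = p_h_given_v(v, params, extra_hidden_bias)
    h = _bernoulli(p_h, rng)
    return v, h, p_v, p_h


# ---------------------------------------------------------------------------
# exact enumeration oracles (small models only)
# ---------------------------------------------------------------------------

def enumerate_states(n: int) -> np.ndarray:
    """All 2^n binary vectors as a (2^n, n) float array (lexicographic)."""
    if n > MAX_ENUM_UNITS:
        raise ValueError(f"enumeration over {n} units exceeds the budget of {MAX_ENUM_UNITS}")
    grid = np.indices((2,) * n).reshape(n, -1).T
    return grid.astype(float)


def _free_energy_all_v(params: RBMParams):
    """log Σ_h exp(-E(v, h)) for every v, hidden units summed analytically."""
    V = enumerate_states(params.n_visible)          # (2^Nv, Nv)
    act = V @ params.W.T + params.bh                # (2^Nv, Nh)
    return V, V @ params.bv + np.logaddexp(0.0, act).sum(axis=1)


def exact_partition_small(params: RBMParams | RTRBMParams, r_prev=None):
    """Exact (Z, logZ) by summing the hidden layer analytically and
    enumerating visible states.

    For ``RTRBMParams`` the conditional partition sum Z_{r[t-1]} is computed:
    the hidden bias is augmented with ``U @ r_prev`` (``binit`` replaces
    ``bh`` when ``r_prev`` is None, the t = 1 convention).
    """
    params = _as_static(params, r_prev)
    if params.n_visible + params.n_hidden > MAX_ENUM_UNITS:
        raise ValueError(
            f"model with {params.n_visible}+{params.n_hidden} units exceeds the "
            f"enumeration budget ({MAX_ENUM_UNITS})"
        )
    _, log_weights = _free_energy_all_v(params)
    logZ = float(logsumexp(log_weights))
    return float(np.exp(logZ)), logZ


def _as_static(params, r_prev):
    if isinstance(params, RTRBMParams):
        if r_prev is None:
            bias = params.binit
        else:
            bias = params.bh + params.U @ np.asarray(r_prev, dtype=float)
        return RBMParams(params.W, params.bv, bias)
    return params


def exact_visible_marginal(params: RBMParams) -> tuple[np.ndarray, np.ndarray]:
    """(states, P(v)) over all visible configurations, by enumeration."""
    V, log_weights = _free_energy_all_v(params)
    logZ = logsumexp(log_weights)
    return V, np.exp(log_weights - logZ)


def exact_model_moments(params: RBMParams):
    """Exact model expectations ⟨v⟩, ⟨h⟩, ⟨h vᵀ⟩ by visible enumeration.

    Hidden units are integrated analytically: ⟨h | v⟩ = σ(bh + W v).
    """
    V, p = exact_visible_marginal(params)
    R = sigmoid(V @ params.W.T + params.bh)         # (2^Nv, Nh)
    mean_v = p @ V
    mean_h = p @ R
    mean_hv = (R * p[:, None]).T @ V                # (Nh, Nv)
    return mean_v, mean_h, mean_hv
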