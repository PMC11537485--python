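"""Ground-truth generator of temporally interacting assembly activity.

Nh latent assemblies each carry a time-varying firing rate built from two
independent trains of randomly timed peaks (inter-peak interval ~
Uniform(t1, t2)) convolved with unit-sum Gaussian bumps (width ~
Uniform(σ1, σ2)); the two instances are min–max renormalized to
[0, fmax/10] and [0, fmax] and summed into the intrinsic rate λ_init.
Assemblies then interact pairwise at a delay of ΔtA steps,

    λ_i(t) = ϕ( λ_init_i(t) + Σ_j U_ij λ_j(t − ΔtA) ),

with ϕ a limiter clamping to [0, 3·fmax].  Each assembly drives a distinct
block of neurons: neuron k in assembly i fires when a Poisson draw with mean
c_k · λ_i(t) is nonzero (c_k ~ Uniform(c1, c2)).  The first tsettle columns
are discarded as burn-in.

The default interaction matrix gives each assembly exactly one excitatory
and one inhibitory afferent from distinct other assemblies (a ring: i
excites i+1 and inhibits i−1), so each assembly also sends one of each.

``downsample`` keeps every ΔtD-th column (no averaging), emulating an
acquisition rate mismatched to the interaction timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .model_core import SpikeRaster

__all__ = [
    "SimConfig",
    "SimOutput",
    "default_U",
    "default_sim_config",
    "intrinsic_rate",
    "assembly_dynamics",
    "poisson_observe",
    "simulate",
    "downsample",
]


@dataclass
class SimConfig:
    """Generator parameters.  Defaults are the study conditions; see
    :func:`default_sim_config`.

    All times are in simulation steps.  ``limiter`` selects the range
    restriction ϕ: hard clamping to [0, 3·fmax] (default) or a scaled
    Gaussian-CDF squashing onto the same interval.
    """

    Nh: int = 10
    Nv_per_unit: int = 20
    t1: float = 5.0
    t2: float = 10.0
    sigma1: float = 0.1
    sigma2: float = 0.5
    c1: float = 0.6
    c2: float = 1.4
    tsettle: int = 25
    fmax: float = 0.8
    delta_t_a: int = 1
    U_true: np.ndarray | None = None
    T: int = 5000
    seed: int = 0
    U_magnitude: float = 1.0
    limiter: str = "clamp"

    def __post_init__(self):
        if not (self.t1 < self.t2 and self.sigma1 < self.sigma2 and self.c1 < self.c2):
            raise ValueError("bounds must satisfy t1<t2, sigma1<sigma2, c1<c2")
        if self.fmax < 0:
            raise ValueError("fmax must be >= 0")
        if self.delta_t_a < 1 or self.tsettle < 0:
            raise ValueError("delta_t_a >= 1 and tsettle >= 0 required")
        if self.U_true is None:
            self.U_true = default_U(self.Nh, self.U_magnitude)
        self.U_true = np.asarray(self.U_true, dtype=float)
        if self.U_true.shape != (self.Nh, self.Nh):
            raise ValueError("U_true must be Nh x Nh")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["U_true"] = np.asarray(d["U_true"]).tolist()
        return d


@dataclass
class SimOutput:
    raster: SpikeRaster            # (Nh*Nv_per_unit, T)
    rates: np.ndarray              # (Nh, T) interacted assembly rates
    intrinsic_rates: np.ndarray    # (Nh, T)
    membership: np.ndarray         # assembly index per neuron
    scales: np.ndarray             # per-neuron Poisson scale c_k
    U_true: np.ndarray


def default_U(Nh: int, magnitude: float = 1.0) -> np.ndarray:
    """Ring interaction structure: assembly i excites i+1 and inhibits i−1.

    Each row (incoming) and each column (outgoing) has exactly one
    +magnitude and one −magnitude entry, zero diagonal.  Restricted to its
    excitatory part this is the cycle 1 → 2 → ... → Nh → 1.
    """
    if Nh < 3:
        raise ValueError("Nh must be >= 3 for distinct excitatory/inhibitory partners")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    U = np.zeros((Nh, Nh))
    for i in range(Nh):
        U[(i + 1) % Nh, i] = magnitude      # i excites i+1
        U[(i - 1) % Nh, i] = -magnitude     # i inhibits i-1
    return U


def default_sim_config(delta_t_a: int = 1, T: int = 5000, seed: int = 0) -> SimConfig:
    """The standard generator conditions: Nh=10 assemblies of 20 neurons,
    t1=5, t2=10, σ1=0.1, σ2=0.5, c1=0.6, c2=1.4, tsettle=25, fmax=0.8.
    ΔtA=1 for model-comparison runs, 4 for the timescale scan."""
    return SimConfig(delta_t_a=delta_t_a, T=T, seed=seed)


# ---------------------------------------------------------------------------
# rate generation
# ---------------------------------------------------------------------------

def _peak_train(length: int, t1: float, t2: float, rng) -> np.ndarray:
    """Delta train with inter-peak intervals ~ Uniform(t1, t2); the first
    peak sits at a Uniform(0, t2) offset."""
    train = np.zeros(length)
    t = rng.uniform(0.0, t2)
    while t < length:
        idx = int(round(t))
        if idx < length:
            train[idx] += 1.0
        t += rng.uniform(t1, t2)
    return train


def _gaussian_kernel(sigma: float) -> np.ndarray:
    """Unit-sum Gaussian on the integer grid, truncated at ±⌈4σ⌉ bins."""
    half = int(np.ceil(4.0 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _minmax_to(x: np.ndarray, top: float) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo) * top


def intrinsic_rate(config: SimConfig, rng) -> np.ndarray:
    """Intrinsic assembly rates λ_init, shape (Nh, T + tsettle).

    Per assembly: two independent Gaussian-bump peak trains, renormalized to
    [0, fmax/10] and [0, fmax] respectively, summed.
    """
    length = config.T + config.tsettle
    if length < config.t2:
        raise ValueError("trace shorter than the maximum inter-peak interval")
    out = np.empty((config.Nh, length))
    for i in range(config.Nh):
        parts = []
        for top in (config.fmax / 10.0, config.fmax):
            train = _peak_train(length, config.t1, config.t2, rng)
            sigma = rng.uniform(config.sigma1, config.sigma2)
            bumped = np.convolve(train, _gaussian_kernel(sigma), mode="same")
            parts.append(_minmax_to(bumped, top))
        out[i] = parts[0] + parts[1]
    return out


def _limit(x: np.ndarray, fmax: float, mode: str) -> np.ndarray:
    if mode == "clamp":
        return np.clip(x, 0.0, 3.0 * fmax)
    if mode == "cdf":
        # scaled Gaussian-CDF squashing onto [0, 3 fmax]
        return 3.0 * fmax * norm.cdf(x / max(fmax, 1e-12))
    raise ValueError(f"unknown limiter {mode!r}")


def assembly_dynamics(intrinsic: np.ndarray, U: np.ndarray, delta_t_a: int,
                      fmax: float, limiter: str = "clamp") -> np.ndarray:
    """Forward recursion λ_i(t) = ϕ(λ_init_i(t) + Σ_j U_ij λ_j(t − ΔtA)).

    Steps with no history (t < ΔtA) take a zero interaction term.
    """
    if delta_t_a < 1:
        raise ValueError("delta_t_a must be >= 1")
    U = np.asarray(U, dtype=float)
    if not np.all(np.isfinite(U)):
        raise ValueError("U contains non-finite entries")
    intrinsic = np.asarray(intrinsic, dtype=float)
    rates = np.empty_like(intrinsic)
    T = intrinsic.shape[1]
    for t in range(T):
        drive = intrinsic[:, t].copy()
        if t >= delta_t_a:
            drive += U @ rates[:, t - delta_t_a]
        rates[:, t] = _limit(drive, fmax, limiter)
    return rates


def poisson_observe(rates: np.ndarray, config: SimConfig, rng):
    """Binary raster from per-neuron Poisson draws on the assembly rates.

    Neuron k in assembly i has scale c_k ~ Uniform(c1, c2); it fires at t
    when Poisson(c_k · λ_i(t)) ≥ 1.  The first tsettle columns are dropped.
    Returns ``(raster, scales, membership)``.
    """
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    nh = rates.shape[0]
    nv = nh * config.Nv_per_unit
    membership = np.repeat(np.arange(nh), config.Nv_per_unit)
    scales = rng.uniform(config.c1, config.c2, size=nv)
    lam = scales[:, None] * rates[membership, :]
    counts = rng.poisson(lam)
    values = (counts >= 1).astype(np.uint8)[:, config.tsettle:]
    return SpikeRaster(values, dt=1.0), scales, membership


def simulate(config: SimConfig, rng=None) -> SimOutput:
    """Full generator pipeline: intrinsic rates → interactions → Poisson."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    intrinsic = intrinsic_rate(config, rng)
    rates = assembly_dynamics(intrinsic, config.U_true, config.delta_t_a,
                              config.fmax, config.limiter)
    raster, scales, membership = poisson_observe(rates, config, rng)
    return SimOutput(raster=raster,
                     rates=rates[:, config.tsettle:],
                     intrinsic_rates=intrinsic[:, config.tsettle:],
                     membership=membership, scales=scales,
                     U_true=config.U_true.copy())


def downsample(raster: SpikeRaster, delta_t_d: int) -> SpikeRaster:
    """Keep columns 0, ΔtD, 2ΔtD, ... — value selection, no averaging."""
    if delta_t_d < 1:
        raise ValueError("delta_t_d must be >= 1")
    if delta_t_d >= raster.n_steps:
        raise ValueError(
            f"delta_t_d={delta_t_d} leaves fewer than two of {raster.n_steps} columns"
        )
    values = raster.values[:, ::delta_t_d]
    dt = raster.dt * delta_t_d if raster.dt is not None else None
    return SpikeRaster(values, dt=dt, unit_ids=raster.unit_ids)
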