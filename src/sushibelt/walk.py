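"""Stochastic single-cargo movement along a microtubule lattice.

Cargo bound to opposing kinesin/dynein motors performs a biased random walk:
at each timestep it steps retrograde (-1), pauses (0) or steps anterograde
(+1). A memory parameter ``k`` interpolates between a memoryless walk (k=0)
and deterministic unidirectional runs (k=1): with probability ``k`` the
previous step is repeated, otherwise a fresh step is drawn from the base
probabilities. Ensembles of such walks define the bulk drift and diffusion
that calibrate the mass-action transport model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "WalkParams",
    "EnsembleTrajectory",
    "WalkFit",
    "transition_matrix",
    "simulate",
    "analytic_rates",
    "fit_rates",
    "occupancy_cv",
    "expected_run_length",
]

_STEPS = np.array([-1, 0, 1])


@dataclass(frozen=True)
class WalkParams:
    """Step probabilities and memory of a three-state motor walk.

    ``p_minus``, ``p_zero``, ``p_plus`` are the base probabilities of a
    retrograde step, pause and anterograde step; they must sum to one.
    ``k`` in [0, 1] is the run-length memory. ``step_length_um`` and ``dt_s``
    set the physical lattice (defaults 1 µm / 1 s, the kinesin-scale
    convention).
    """

    p_minus: float
    p_zero: float
    p_plus: float
    k: float = 0.0
    step_length_um: float = 1.0
    dt_s: float = 1.0

    def __post_init__(self):
        p = np.array([self.p_minus, self.p_zero, self.p_plus], dtype=float)
        if np.any(p < 0):
            raise ValueError("step probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"step probabilities must sum to 1, got {p.sum()!r}")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("memory parameter k must lie in [0, 1]")
        if self.step_length_um <= 0 or self.dt_s <= 0:
            raise ValueError("step_length_um and dt_s must be positive")

    @property
    def base(self) -> np.ndarray:
        return np.array([self.p_minus, self.p_zero, self.p_plus])


@dataclass(frozen=True)
class EnsembleTrajectory:
    """Positions of independent walkers on the integer lattice.

    ``positions`` has shape (n_particles, n_steps + 1) in units of the step
    length; ``times_s`` has length n_steps + 1. Successive positions differ
    by at most one lattice site.
    """

    positions: np.ndarray
    times_s: np.ndarray
    seed: int
    params: WalkParams

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def positions_um(self) -> np.ndarray:
        return self.positions * self.params.step_length_um

    def to_dataframe(self) -> pd.DataFrame:
        n_p, n_t = self.positions.shape
        return pd.DataFrame(
            {
                "particle_id": np.repeat(np.arange(n_p), n_t),
                "t_s": np.tile(self.times_s, n_p),
                "x_um": self.positions_um().ravel(),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, params: WalkParams, seed: int = -1):
        pivot = df.pivot(index="particle_id", columns="t_s", values="x_um")
        times = pivot.columns.to_numpy(dtype=float)
        pos = pivot.to_numpy() / params.step_length_um
        return cls(np.rint(pos).astype(int), times, seed, params)


def transition_matrix(params: WalkParams) -> np.ndarray:
    """Conditional step distribution p(v'|v), rows indexed by previous step.

    Row r (previous step v in (-1, 0, +1) order) is
    ``base * (1 - k) + k * [v' == v]``: at k=0 all rows equal the base
    distribution, at k=1 the matrix is the identity (pure runs).
    """
    return (1.0 - params.k) * np.tile(params.base, (3, 1)) + params.k * np.eye(3)


def simulate(
    params: WalkParams,
    n_particles: int,
    n_steps: int,
    seed: int,
    boundary: str = "closed",
) -> EnsembleTrajectory:
    """Simulate independent walkers starting at the somatic end of a neurite.

    All particles start at lattice position 0. The first step is drawn from
    the memoryless base distribution; subsequent steps follow the
    history-dependent transition matrix. ``boundary="closed"`` blocks
    retrograde steps out of position 0 (a cable closed at the soma);
    ``boundary="none"`` walks on the unbounded lattice.
    """
    if n_particles < 1 or n_steps < 1:
        raise ValueError("n_particles and n_steps must be >= 1")
    if boundary not in ("closed", "none"):
        raise ValueError("boundary must be 'closed' or 'none'")
    rng = np.random.default_rng(seed)
    P = transition_matrix(params)
    cum = P.cumsum(axis=1)

    pos = np.zeros((n_particles, n_steps + 1), dtype=np.int64)
    v = rng.choice(3, size=n_particles, p=params.base)  # memoryless first step
    x = np.zeros(n_particles, dtype=np.int64)
    for n in range(n_steps):
        x = x + _STEPS[v]
        if boundary == "closed":
            np.maximum(x, 0, out=x)
        pos[:, n + 1] = x
        u = rng.random(n_particles)
        v = (u[:, None] > cum[v]).sum(axis=1)
    times = np.arange(n_steps + 1) * params.dt_s
    return EnsembleTrajectory(pos, times, seed, params)


def analytic_rates(params: WalkParams) -> tuple[float, float]:
    """Closed-form mass-action rates moment-matched to the memoryless walk.

    For k=0 the walk's drift per step is ``p+ - p-`` and its variance grows
    by ``p+ + p- - (p+ - p-)**2`` per step; matching the first two moments of
    the compartmental model gives

        a = (2 p+ - (p+ - p-)^2) / 2,   b = (2 p- - (p+ - p-)^2) / 2,

    in units of 1/dt for compartments one step length wide. The model is
    only valid while b >= 0, i.e. ``2 p- >= (p+ - p-)**2``.
    """
    if params.k != 0.0:
        raise ValueError("analytic_rates applies to the memoryless walk (k=0)")
    drift = params.p_plus - params.p_minus
    a = (2.0 * params.p_plus - drift**2) / 2.0
    b = (2.0 * params.p_minus - drift**2) / 2.0
    if b < 0:
        raise ValueError(
            "moment matching invalid: need 2*p_minus >= (p_plus - p_minus)**2 "
            f"(got b = {b:.4g} < 0)"
        )
    return a / params.dt_s, b / params.dt_s


class WalkFit(NamedTuple):
    a: float
    b: float
    r_squared: float
    drift_um_per_s: float
    variance_rate_um2_per_s: float


def fit_rates(ensemble: EnsembleTrajectory) -> WalkFit:
    """Moment-match mass-action rates to an ensemble of walks.

    Regresses the ensemble mean position (drift, a - b) and position variance
    (dispersion, a + b) on time, both through the origin since all particles
    start at one point. The fit quality R² comes from a Gaussian fit to the
    final concentration profile (the mass-action model's prediction for the
    bulk distribution).
    """
    if ensemble.times_s.size < 2:
        raise ValueError("need at least 2 timepoints to fit rates")
    params = ensemble.params
    t = ensemble.times_s[1:]
    x = ensemble.positions_um()[:, 1:]
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    if np.all(var == 0):
        if np.all(mean == 0):  # all-pause walk: nothing moves, a = b = 0
            return WalkFit(0.0, 0.0, 1.0, 0.0, 0.0)
        raise ValueError(
            "degenerate ensemble: zero variance with nonzero drift cannot be "
            "moment-matched (retrograde rate would be negative)"
        )
    tt = float(t @ t)
    drift = float(t @ mean) / tt          # µm / s
    var_rate = float(t @ var) / tt        # µm² / s
    step = params.step_length_um
    a = (var_rate / step**2 + drift / step) / 2.0
    b = (var_rate / step**2 - drift / step) / 2.0

    # Gaussian (drift-diffusion) fit to the final profile.
    final = ensemble.positions[:, -1]
    lo, hi = final.min(), final.max()
    bins = np.arange(lo, hi + 2) - 0.5
    counts, _ = np.histogram(final, bins=bins)
    centers = np.arange(lo, hi + 1).astype(float) * step
    T = ensemble.times_s[-1]
    mu, sigma2 = drift * T, max(var_rate * T, 1e-12)
    pred = np.exp(-((centers - mu) ** 2) / (2 * sigma2)) / np.sqrt(2 * np.pi * sigma2)
    pred *= ensemble.n_particles * step
    ss_res = float(np.sum((counts - pred) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return WalkFit(a, b, r2, drift, var_rate)


def occupancy_cv(p_ss: float, n: int) -> float:
    """Coefficient of variation of compartment occupancy at steady state.

    With n independent particles each occupying a compartment with
    steady-state probability ``p_ss``, the occupancy is binomial and

        CV = sqrt((1 - p_ss) / (n * p_ss)).

    Noise falls as 1/sqrt(n) in the particle count.
    """
    if not 0.0 < p_ss <= 1.0:
        raise ValueError("p_ss must lie in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.sqrt((1.0 - p_ss) / (n * p_ss)))


def expected_run_length(k: float) -> float:
    """Mean sustained-run length (in steps) implied by memory parameter k.

    A run persists each step with probability k, so run lengths are
    geometric with mean 1 / (1 - k). Documentation helper only.
    """
    if not 0.0 <= k < 1.0:
        raise ValueError("k must lie in [0, 1)")
    return 1.0 / (1.0 - k)
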