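"""Accuracy, speed and efficiency metrics, and parameter-sweep tradeoff curves.

The central quantities of the speed-precision-efficiency analysis:

* mean percent error of a delivered distribution against demand,
* L1 error of a cargo state against the demand-scaled target,
* time to deliver a given fraction of total cargo,
* time for the delivered distribution to converge within a tolerance,
* excess fraction (cargo still in transit at steady state),

plus a deterministic sweep driver that maps a swept parameter to
(error, speed, excess) operating points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .strategies import DemandProfile
from .transport import (
    StateTrajectory,
    TransportSystem,
    delivered_distribution,
    evolve,
    log_times,
    steady_state,
)

__all__ = [
    "TradeoffCurve",
    "mean_percent_error",
    "l1_error",
    "time_to_fraction_delivered",
    "delivery_time",
    "excess_fraction",
    "time_to_converge",
    "tradeoff_sweep",
]


def mean_percent_error(delivered: np.ndarray, demand: DemandProfile) -> float:
    """Mean relative deviation (%) of delivered cargo from demand.

    Both vectors are normalized to unit mass; the mean runs over
    compartments with nonzero demand only (relative error at zero demand is
    undefined, and hotspot analyses report error at the targets). Invariant
    to rescaling of the delivered vector.
    """
    dlv = np.asarray(delivered, dtype=float)
    if np.any(dlv < 0):
        raise ValueError("delivered masses must be nonnegative")
    total = dlv.sum()
    if total <= 0:
        raise ValueError("delivered mass must have positive total")
    dlv = dlv / total
    dem = demand.values
    m = dem > 0
    return float(100.0 * np.mean(np.abs(dlv[m] - dem[m]) / dem[m]))


def l1_error(state: np.ndarray, demand: DemandProfile) -> float:
    """Total error: sum of absolute deviations from the demand profile scaled
    to the state's total mass (L1 norm). Zero iff the match is exact."""
    s = np.asarray(state, dtype=float)
    return float(np.abs(s - demand.values * s.sum()).sum())


def time_to_fraction_delivered(trajectory: StateTrajectory, q: float) -> float:
    """Earliest time at which a fraction q of all cargo has detached.

    Linearly interpolated between stored timepoints; +inf (with a warning)
    if the fraction is never reached within the trajectory horizon.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    total = trajectory.total_mass
    frac = trajectory.ustar.sum(axis=0) / total
    target = q
    above = frac >= target
    if not above.any():
        warnings.warn(f"fraction {q} not delivered within the trajectory horizon", stacklevel=2)
        return np.inf
    j = int(above.argmax())
    if j == 0:
        return float(trajectory.times_s[0])
    t0, t1 = trajectory.times_s[j - 1], trajectory.times_s[j]
    f0, f1 = frac[j - 1], frac[j]
    return float(t0 + (target - f0) / (f1 - f0) * (t1 - t0))


def delivery_time(system: TransportSystem, q: float) -> float:
    """Exact time to deliver fraction q of cargo, for irreversible detachment.

    The bound mass is ``1ᵀ exp(Mt) u0`` with M the bound-state generator; the
    crossing time of ``1 - q`` is found by bisection on the spectral form.
    """
    if np.any(system.d > 0):
        raise ValueError("delivery_time requires irreversible detachment (d = 0)")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    from .transport import _bound_generator

    M = _bound_generator(system, include_detachment=True).toarray()
    lam, V = scipy.linalg.eig(M)
    alpha = scipy.linalg.solve(V, system.u0.astype(complex))
    coef = (np.ones(system.n) @ V) * alpha
    total = system.total_mass

    def bound_frac(t):
        return float(np.real(np.sum(coef * np.exp(lam * t)))) / total

    target = 1.0 - q
    lo, hi = 0.0, 1.0
    while bound_frac(hi) > target:
        hi *= 10.0
        if hi > 1e16:
            return np.inf
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if bound_frac(mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-9 * hi:
            break
    return 0.5 * (lo + hi)


def excess_fraction(u: np.ndarray, ustar: np.ndarray) -> float:
    """Fraction of cargo still in transit (bound) at steady state."""
    u_tot = float(np.asarray(u).sum())
    total = u_tot + float(np.asarray(ustar).sum())
    return u_tot / total


def time_to_converge(
    trajectory: StateTrajectory,
    demand: DemandProfile,
    tol_pct: float,
    pool: str = "detached",
) -> float:
    """Earliest time after which the mean percent error stays below tol_pct.

    ``pool`` selects which cargo is compared to demand ("detached", "bound"
    or "total"). Returns +inf with a warning if the tolerance is never held
    for the remainder of the horizon.
    """
    if tol_pct <= 0:
        raise ValueError("tol_pct must be positive")
    mass = {
        "detached": trajectory.ustar,
        "bound": trajectory.u,
        "total": trajectory.u + trajectory.ustar,
    }[pool]
    errs = np.empty(trajectory.times_s.size)
    for j in range(errs.size):
        col = mass[:, j]
        errs[j] = mean_percent_error(col, demand) if col.sum() > 0 else np.inf
    below = errs < tol_pct
    # require the tolerance to hold for the rest of the horizon
    ok_from = np.flip(np.logical_and.accumulate(np.flip(below)))
    if not ok_from.any():
        warnings.warn(
            f"trajectory never stays within {tol_pct}% of demand", stacklevel=2
        )
        return np.inf
    return float(trajectory.times_s[int(ok_from.argmax())])


@dataclass(frozen=True)
class TradeoffCurve:
    """Operating points of a parameter sweep: error vs speed vs excess."""

    parameter: np.ndarray
    error_pct: np.ndarray
    time_s: np.ndarray
    excess_frac: np.ndarray

    def __post_init__(self):
        lens = {len(self.parameter), len(self.error_pct), len(self.time_s),
                len(self.excess_frac)}
        if len(lens) != 1:
            raise ValueError("all tradeoff fields must have the same length")
        if np.any(np.diff(self.parameter) < 0):
            raise ValueError("parameter values must be sorted ascending")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "param": self.parameter,
                "error_pct": self.error_pct,
                "time_s": self.time_s,
                "excess_frac": self.excess_frac,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def tradeoff_sweep(
    build: Callable[[float], TransportSystem],
    values: Sequence[float],
    demand: DemandProfile,
    q: float = 0.95,
    tol_pct: float = 10.0,
    horizon_s: float = 1e9,
    n_times: int = 96,
) -> TradeoffCurve:
    """Sweep a parameter and record (error, speed, excess) per operating point.

    ``build`` maps each swept value to a transport system. For irreversible
    systems the error is the closed-form delivered distribution against
    demand and the speed is the exact time to deliver fraction ``q`` of
    cargo. For reversible systems the error is the steady-state delivered
    distribution against demand, the speed is the time for the evolving
    delivered pool to converge within ``tol_pct`` mean error, and the excess
    fraction is the steady-state bound share. Fully deterministic.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 1:
        raise ValueError("need at least one sweep value")
    errors, times, excesses = [], [], []
    for v in values:
        system = build(float(v))
        if np.any(system.d > 0):
            u_ss, ustar_ss = steady_state(system)
            errors.append(mean_percent_error(ustar_ss, demand))
            excesses.append(excess_fraction(u_ss, ustar_ss))
            traj = evolve(system, log_times(1.0, horizon_s, n_times))
            times.append(time_to_converge(traj, demand, tol_pct))
        else:
            dlv = delivered_distribution(system)
            errors.append(mean_percent_error(dlv, demand))
            times.append(delivery_time(system, q))
            excesses.append(0.0)
    return TradeoffCurve(values, np.array(errors), np.array(times), np.array(excesses))
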