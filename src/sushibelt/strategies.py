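"""Demand-driven trafficking strategies.

A demand profile is a nonnegative target distribution of delivered cargo
over compartments. The sushi-belt model can realize it in several ways:

* DDT (demand-dependent trafficking): local demand sets the anterograde /
  retrograde rate ratio on every edge (``b/a = demand_parent/demand_child``)
  and detachment is spatially uniform.
* DDD (demand-dependent detachment): trafficking is uniform and the local
  detachment rate is proportional to demand.
* Interpolated strategies mix the two through a scalar F in [0, 1]
  (F=1 is DDT, F=0 is DDD).
* A globally tuned anterograde bias (linearly decaying from the soma)
  compensates the proximal delivery bias of fast detachment on a cable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .morphology import CompartmentTree
from .transport import TransportSystem

__all__ = [
    "DemandProfile",
    "StrategyConfig",
    "ddt",
    "ddd",
    "interpolate",
    "tuned_bias",
    "scale_rates_to_geometry",
    "demand_from_signal",
]


@dataclass(frozen=True)
class DemandProfile:
    """Per-compartment demand, normalized to unit mass on construction.

    ``epsilon_ratio`` sets the demand floor used by trafficking-based
    strategies: compartments with zero demand receive
    ``epsilon_ratio * min(nonzero demand)`` before rate ratios are formed,
    since a hard zero creates a bottleneck of infinite strength.
    """

    values: np.ndarray
    epsilon_ratio: float = 1e-3

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("demand must be a non-empty 1-D vector")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("demand must be nonnegative and finite")
        total = v.sum()
        if total <= 0:
            raise ValueError("demand must have positive total")
        if not 0 <= self.epsilon_ratio < 1:
            raise ValueError("epsilon_ratio must lie in [0, 1)")
        object.__setattr__(self, "values", v / total)

    @property
    def n(self) -> int:
        return self.values.size

    def floored(self) -> np.ndarray:
        """Demand with zeros replaced by the epsilon floor (not renormalized)."""
        v = self.values.copy()
        zero = v == 0
        if zero.any():
            if self.epsilon_ratio == 0:
                raise ZeroDivisionError(
                    "demand contains zeros and epsilon_ratio=0: trafficking "
                    "ratios would divide by zero (a bottleneck of infinite strength)"
                )
            v[zero] = self.epsilon_ratio * v[~zero].min()
        return v


@dataclass(frozen=True)
class StrategyConfig:
    """Shared strategy parameters.

    ``c_max`` (s⁻¹) scales detachment; ``d`` (s⁻¹) is the uniform
    reattachment rate (0 = irreversible); ``D`` (µm² s⁻¹) is the diffusion
    coefficient implied by the trafficking rates; ``beta`` (µm² s⁻¹) the
    anterograde bias, constrained to ``beta < D/2``; ``F`` the DDT/DDD mix.
    ``normalization`` chooses how edge rate sums are fixed: ``"physical"``
    sets a+b = 2 D / Δ² per edge (Δ = midpoint distance), ``"unit"`` sets
    a+b = 1 (the dimensionless convention used for single-morphology
    comparisons).
    """

    F: float = 0.0
    c_max: float = 0.0
    d: float = 0.0
    beta: float = 0.0
    D: float = 10.0
    normalization: str = "physical"

    def __post_init__(self):
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must lie in [0, 1]")
        if self.c_max < 0 or self.d < 0 or self.D <= 0:
            raise ValueError("rates must be nonnegative and D positive")
        if not 0.0 <= self.beta < self.D / 2.0:
            raise ValueError(f"anterograde bias must satisfy 0 <= beta < D/2 = {self.D / 2}")
        if self.normalization not in ("physical", "unit"):
            raise ValueError("normalization must be 'physical' or 'unit'")

    def edge_rate_sums(self, tree: CompartmentTree) -> np.ndarray:
        if self.normalization == "unit":
            return np.ones(tree.n_edges)
        delta = tree.edge_midpoint_distance_um()
        return 2.0 * self.D / delta**2


def _trafficking_from_target(
    target: np.ndarray, tree: CompartmentTree, kappa: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge (a, b) with b/a = target_parent/target_child and a+b = kappa."""
    p, ch = tree.edges.T
    tp, tc = target[p], target[ch]
    a = kappa * tc / (tp + tc)
    b = kappa * tp / (tp + tc)
    return a, b


def ddt(demand: DemandProfile, tree: CompartmentTree, config: StrategyConfig) -> TransportSystem:
    """Demand-dependent trafficking: rate ratios encode demand, uniform detachment.

    The trafficking-only steady state of the returned system matches the
    (floored) demand profile exactly; uniform detachment ``c = c_max`` then
    transfers that profile to the delivered pool.
    """
    if demand.n != tree.n:
        raise ValueError("demand length must match tree size")
    target = demand.floored()
    a, b = _trafficking_from_target(target, tree, config.edge_rate_sums(tree))
    return TransportSystem(tree, a, b, c=np.full(tree.n, config.c_max),
                           d=np.full(tree.n, config.d))


def ddd(demand: DemandProfile, tree: CompartmentTree, config: StrategyConfig) -> TransportSystem:
    """Demand-dependent detachment: uniform trafficking, detachment tracks demand.

    ``c_i = c_max * demand_i / max(demand)``; zero-demand compartments get
    c = 0, so arbitrary demand patterns (including hard zeros) are reachable.
    """
    if demand.n != tree.n:
        raise ValueError("demand length must match tree size")
    kappa = config.edge_rate_sums(tree)
    a = b = kappa / 2.0
    c = config.c_max * demand.values / demand.values.max()
    return TransportSystem(tree, a, b.copy(), c=c, d=np.full(tree.n, config.d))


def interpolate(
    demand: DemandProfile, tree: CompartmentTree, F: float, config: StrategyConfig
) -> TransportSystem:
    """Mixed strategy: trafficking targets ``F*demand + (1-F)/N``, detachment
    proportional to ``demand / mixture``. F=1 reproduces DDT, F=0 DDD."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must lie in [0, 1]")
    if demand.n != tree.n:
        raise ValueError("demand length must match tree size")
    n = tree.n
    base = demand.floored() if F == 1.0 else demand.values
    mixture = F * base + (1.0 - F) / n
    a, b = _trafficking_from_target(mixture, tree, config.edge_rate_sums(tree))
    weight = demand.values / mixture
    c = config.c_max * weight / weight.max()
    return TransportSystem(tree, a, b, c=c, d=np.full(n, config.d))


def tuned_bias(
    config: StrategyConfig, n_compartments: int, spacing_um: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly decaying anterograde bias along an unbranched cable.

    Edge rates (i = 1..N-1 from the soma, in s⁻¹ for compartments of the
    given spacing):

        a_i = (D/2 + beta * (N-1-i)/(N-2)) / Δ²
        b_i = (D/2 - beta * (N-1-i)/(N-2)) / Δ²

    The sum a_i + b_i = D/Δ² is constant, so the diffusion coefficient is
    unchanged; the bias is maximal at the soma and vanishes distally.
    Requires beta < D/2 (otherwise retrograde rates would go negative).
    """
    n = int(n_compartments)
    if n < 3:
        raise ValueError("tuned bias needs at least 3 compartments")
    D, beta = config.D, config.beta
    i = np.arange(1, n)
    frac = (n - 1 - i) / (n - 2)
    a = (D / 2.0 + beta * frac) / spacing_um**2
    b = (D / 2.0 - beta * frac) / spacing_um**2
    return a, b


def scale_rates_to_geometry(D: float, tree: CompartmentTree) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-trafficking edge rates scaled to compartment geometry.

    For an edge whose compartment midpoints are Δ apart, ``a = b = D / Δ²``
    keeps the local diffusion coefficient ``(a+b)/2 * Δ²`` equal to D, making
    model behaviour insensitive to the discretization resolution.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    delta = tree.edge_midpoint_distance_um()
    if np.any(delta <= 0):
        raise ValueError("zero-length edge encountered")
    rates = D / delta**2
    return rates, rates.copy()


def demand_from_signal(
    signal: np.ndarray,
    mapping: Callable[[np.ndarray], np.ndarray] | None = None,
    epsilon_ratio: float = 1e-3,
) -> DemandProfile:
    """Demand implied by a local biochemical signal (e.g. cytosolic calcium).

    If every outgoing trafficking rate of a compartment is set by a monotone
    function f of the local signal (a = f(signal_parent), b = f(signal_child)),
    the steady state realizes demand proportional to ``1 / f(signal)``. The
    default mapping is a Hill function with coefficient 1 and half-activation
    at the median signal. The mapping must be positive and monotone
    (nondecreasing) over the supplied signal values.
    """
    s = np.asarray(signal, dtype=float)
    if np.any(s <= 0):
        raise ValueError("signal must be positive wherever the mapping is evaluated")
    if mapping is None:
        k_half = float(np.median(s))
        mapping = lambda x: x / (k_half + x)  # noqa: E731  (Hill, coefficient 1)
    order = np.argsort(s)
    f = np.asarray(mapping(s), dtype=float)
    if np.any(f <= 0):
        raise ValueError("mapping must be positive on the signal")
    if np.any(np.diff(f[order]) < -1e-12 * np.abs(f).max()):
        raise ValueError("mapping must be monotone (nondecreasing) on the signal")
    return DemandProfile(1.0 / f, epsilon_ratio=epsilon_ratio)
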