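"""Synthetic demand profiles and fixture systems.

Generators for the canonical demand patterns used to study transport
performance: evenly or randomly placed hotspots, low-demand bottleneck
regions, linear gradients, and the minimal three-compartment bottleneck
system whose convergence slows without bound as the bottleneck tightens.
"""

from __future__ import annotations

import numpy as np

from .morphology import build_cable
from .strategies import DemandProfile
from .transport import TransportSystem

__all__ = [
    "hotspots",
    "bottleneck_profile",
    "linear_gradient",
    "three_compartment_bottleneck",
    "hotspot_indices",
]


def hotspot_indices(n_compartments: int, n_hotspots: int) -> np.ndarray:
    """Evenly placed hotspot positions: round((j + 1/2) * N / n), j = 0..n-1."""
    j = np.arange(n_hotspots)
    return np.array([int(round(v)) for v in (j + 0.5) * n_compartments / n_hotspots])


def hotspots(
    n_compartments: int,
    n_hotspots: int,
    placement: str = "evenly",
    seed: int | None = None,
) -> DemandProfile:
    """Equal demand mass 1/n at each of n hotspot compartments, zero elsewhere.

    ``placement="evenly"`` centers hotspots on a regular grid;
    ``placement="random"`` draws distinct positions uniformly with the given
    seed (reproducible).
    """
    if n_hotspots < 1 or n_hotspots > n_compartments:
        raise ValueError("need 1 <= n_hotspots <= n_compartments")
    if placement == "evenly":
        idx = hotspot_indices(n_compartments, n_hotspots)
    elif placement == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_compartments, size=n_hotspots, replace=False)
    else:
        raise ValueError("placement must be 'evenly' or 'random'")
    v = np.zeros(n_compartments)
    v[idx] = 1.0
    return DemandProfile(v)


def bottleneck_profile(
    n_compartments: int, low_region: tuple[int, int], ratio: float = 10.0
) -> DemandProfile:
    """High demand everywhere except a low-demand region (demand 1/ratio).

    ``low_region`` is a half-open index range (start, stop). An
    order-of-magnitude drop (ratio 10) is the conventional bottleneck; a
    ratio of 1 recovers the uniform profile.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    start, stop = low_region
    if not (0 <= start < stop <= n_compartments):
        raise ValueError("low_region must be a non-empty range inside the profile")
    v = np.ones(n_compartments)
    v[start:stop] = 1.0 / ratio
    return DemandProfile(v)


def linear_gradient(n_compartments: int) -> DemandProfile:
    """Demand proportional to compartment index (1-based from the soma).

    Realized by demand-dependent trafficking with edge ratios
    ``b_i / a_i = i / (i + 1)``, this produces a linear steady-state
    expression gradient along an unbranched cable.
    """
    return DemandProfile(np.arange(1, n_compartments + 1, dtype=float))


def three_compartment_bottleneck(epsilon: float) -> TransportSystem:
    """Minimal bottleneck fixture: transport into the middle compartment at
    rate epsilon, out of it at rate 1, cargo starting in compartment 0.

    The relaxation time diverges as epsilon -> 0 (arbitrarily slow delivery
    past a bottleneck of vanishing conductance); epsilon = 1 recovers the
    uniform-rate cable.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    tree = build_cable(3, 3.0)
    a = np.array([epsilon, 1.0])  # into middle, out of middle
    b = np.array([1.0, epsilon])  # out of middle, into middle
    u0 = np.array([1.0, 0.0, 0.0])
    return TransportSystem(tree, a, b, u0=u0)
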