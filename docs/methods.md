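# Methods

## Model

### Single-particle walks

A cargo particle on a microtubule carries opposing motors and moves on a
1 µm lattice in 1 s steps: retrograde (−1), pause (0) or anterograde (+1)
with base probabilities `(p−, p0, p+)`. Sustained unidirectional runs are
modelled with a memory parameter `k ∈ [0, 1]`: the next step repeats the
previous one with probability `k` and is drawn fresh otherwise, so the
conditional step matrix is `(1−k)·base + k·I`. `k = 0` is the memoryless
walk, `k = 1` deterministic runs; the mean run length is `1/(1−k)` steps.
The default reference probabilities `(0.2, 0.35, 0.45)` give a drift of
0.25 µm/s = 15 µm/min, in the experimentally observed range for
microtubule transport.

Walks start at lattice position 0 with a **closed somatic boundary**
(retrograde steps out of position 0 are blocked), the geometry of cargo
injected at the soma of a neurite. This matters quantitatively: on the
unbounded lattice the run walk's asymptotic variance rate is
`(p+ + p− − (p+−p−)²)(1+k)/(1−k)` (≈1.76 µm²/s at k = 0.5), while walks on
the half-open cable fitted over a 100 s window disperse at ≈1.3 µm²/s.
The fitted rates quoted for the run-length walk (a ≈ 0.79, b ≈ 0.54 s⁻¹)
refer to the cable geometry and the 100 s fitting window; the memoryless
calibration (600 s window) is insensitive to the boundary.

### Moment matching

In the large-ensemble limit bulk cargo follows a drift–diffusion equation
with drift `(a−b)Δ` and diffusion `(a+b)/2·Δ²`. For the memoryless walk
the closed forms are

    a = (2 p+ − (p+−p−)²)/2,    b = (2 p− − (p+−p−)²)/2,

per timestep for compartments one step long, valid while
`2 p− ≥ (p+−p−)²`. `fit_rates` regresses the ensemble mean and variance of
position on time (both through the origin, since all particles start at
one point) and converts drift and dispersion to `a` and `b`; the reported
R² is from a Gaussian fit to the final concentration profile, which is
what the mass-action model predicts.

### Mass-action transport

Compartment `i` of a tree holds bound cargo `u_i` and delivered cargo
`u*_i` (arbitrary mass units). On each edge, parent→child flux `a_e u_p`
and child→parent flux `b_e u_c`; per compartment, detachment `c_i u_i` and
reattachment `d_i u*_i`. Degradation is taken as zero — the question is
how fast cargo can be distributed at all, so delivered cargo simply
accumulates. The state obeys `s' = A s` with `A` sparse, column sums zero
(mass conservation) and Hines structure; by Gershgorin all eigenvalues
have nonpositive real part, so the dynamics are stable.

Key closed forms, all exploited by the implementation:

* **Evolution** is exact: one eigendecomposition of the (dense) generator
  evaluated at every requested timepoint, with a dense
  matrix-exponential stepping fallback if the eigenbasis is
  ill-conditioned (condition number above 1e10). Both routes are checked
  against a high-order explicit integration oracle in the tests. Dense
  linear algebra is the deliberate choice here: the generators in the
  studied regimes have a few hundred state variables, where one `eig`
  plus broadcast exponentials beats repeated sparse exponential actions
  by orders of magnitude on long logarithmic time grids.
* **Steady states** (trafficking-only or reversible): every tree edge is a
  bridge, so net edge flux vanishes at steady state and
  `u_parent/u_child = b/a` edge by edge; with reversible exchange
  additionally `u*_i/u_i = c_i/d_i`. The state is computed by propagating
  these ratios from the root and normalizing to total mass — exact and
  O(N). Systems with irreversible detachment have no interior steady
  state and are redirected to the delivered distribution.
* **Delivered distribution** (irreversible detachment): with
  `M = trafficking generator − diag(c)`, the compartment-wise occupancy
  time is `−M⁻¹u(0)` and the delivered mass is `c_i (−M⁻¹u0)_i` — one
  sparse solve instead of a long simulation.
* **Convergence timescale**: `1/|λ₂|`, the nonzero eigenvalue of smallest
  magnitude of the trafficking generator.

### Strategies

Demand profiles are normalized to unit mass. Zero-demand compartments
under trafficking-based strategies receive a demand floor
`ε = 10⁻³ × min(nonzero demand)` (configurable): a hard zero is a
bottleneck of infinite strength and must be an explicit user choice.

* **DDT**: per edge `b/a = ũ_p/ũ_c` with `a+b` fixed by the normalization
  mode; uniform `c = c_max`.
* **DDD**: uniform `a = b`; `c_i = c_max·ũ*_i/max ũ*` (zero where demand
  is zero).
* **Interpolation** `F ∈ [0,1]`: trafficking targets
  `F·ũ* + (1−F)/N`, detachment proportional to `ũ*/target`; `F = 1` is
  DDT, `F = 0` is DDD.
* **Tuned anterograde bias** on a cable:
  `a_i = D/2 + β(N−1−i)/(N−2)`, `b_i = D/2 − β(N−1−i)/(N−2)` (per unit
  spacing; divided by Δ² for Δ-µm compartments), with `β < D/2`. The sum
  `a+b` — hence the diffusion coefficient — is unchanged; the added drift
  compensates the proximal delivery bias of fast detachment.
* **Geometric scaling**: `a = b = D/Δ²` per edge (Δ = midpoint distance)
  keeps the local diffusion coefficient at `D` across irregular
  compartment sizes, making results insensitive to discretization over at
  least an order of magnitude of resolution (verified in the tests on the
  reference cable at N = 100 vs N = 1000).

Two normalization conventions are provided: `physical` (default,
`a+b = 2D/Δ²` with `D = 10 µm²/s`, a deliberately optimistic experimental
value) and `unit` (`a+b = 1`, the dimensionless convention convenient for
comparing demand patterns on a single morphology).

### Metrics

* **Mean percent error**: both vectors normalized to unit mass; mean of
  `|delivered − demand|/demand` over compartments with nonzero demand.
  Mass wasted on zero-demand compartments still registers through the
  normalization.
* **Delivery time**: exact crossing time of the bound-mass decay
  `1ᵀexp(Mt)u0` (bisection on the spectral form), or interpolated from a
  trajectory.
* **Convergence time**: first time after which the mean percent error of
  the chosen pool stays below tolerance for the remainder of the horizon.
* **Excess fraction**: bound share of total mass at steady state — cargo
  permanently in transit.

## Reference conditions

The quantitative experiments use the conditions the tradeoff analysis was
designed around: an unbranched 800 µm cable with N = 100 compartments
(Δ = 8 µm), D = 10 µm²/s, six demand hotspots evenly placed at
compartments `round((j+½)N/6)`, all cargo starting bound at the somatic
end. Walk calibrations use 1000 particles (600 steps memoryless, 100 steps
for the run-length fit). These sizes keep every experiment exact and
deterministic (dense linear algebra, no Monte-Carlo in the transport
layer) and the full test suite runs in well under a minute.

## Synthetic data and what it does not show

Demand generators (hotspots, bottleneck regions, linear gradients) and
synthetic tree morphologies emulate the *spatial structure* of demand and
of dendritic arbors. They do not emulate: biochemical demand signalling
dynamics (demand is a fixed target vector; the calcium-style mapping
`demand ∝ 1/f(signal)` is a static monotone transform), cargo degradation,
finite-copy-number noise (covered only by the binomial occupancy CV
formula), interactions between cargoes, or the detailed geometry of real
reconstructions (synthetic trees are regular; real arbors have irregular
segment lengths and diameters). Conclusions about *which* strategy wins on
a given morphology class should therefore be read qualitatively; the SWC
reader accepts real reconstructions when those are available.

## Numerical choices

* Negative state values beyond roundoff raise; tiny negatives are clipped
  to zero. Trajectory mass conservation is held to 1e-8 relative.
* Steady-state and delivered solves require every edge to carry nonzero
  rates (else an informative error names the edge) and every compartment
  to reach an absorbing one.
* Time grids default to 64 logarithmically spaced points.
* The convergence-time criterion requires the error to *stay* below
  tolerance, guarding against transient dips.
* Hotspot placement uses the centered grid `round((j+½)N/n)`; random
  placement draws distinct positions from a seeded generator.
* In `simulate`, one seeded generator drives the whole particle array in
  lock-step (vectorized over particles per timestep), which is exactly
  reproducible for a given seed and particle count.

## Known limitations

* The reattachment analysis reproduces the qualitative tradeoff (excess
  cargo rises monotonically as convergence accelerates; sub-10%-excess
  models need more than a day) but not one quoted pairing: under the 10 %
  mean-error convergence criterion the sweep's fast limit on the
  reference cable is ≈300 min (set by `L²/(Dπ²)` times a log factor), and
  the model converging nearest 10³ min carries ≈25 % excess, not >90 %.
  Reproducing that pairing would require an effectively ~10× stricter
  convergence criterion (a floor near `L²/D`). The corresponding test
  assertion is left failing rather than weakened.
* Dense linear algebra bounds practical system size to a few thousand
  compartments; large reconstructions should be resampled to a coarser
  spacing first (rate rescaling makes this nearly lossless).
* `analytic_rates` requires `2p− ≥ (p+−p−)²`; strongly ballistic walks
  have no diffusive moment match.
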