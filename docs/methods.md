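# Methods

## Geometry and frames

All leaf geometry lives in a leaf-local frame with the origin at the leaf
mid-height: `x` runs along the beam-depth direction *pointing toward the
source*, `y` along leaf motion. The end curve spans `x ∈ [−lh/2, +lh/2]`
for parameter `t ∈ [0, 1]`; `t` outside the unit interval continues onto the
straight distal/proximal leaf edges, which descend in `−y`. Leaf material
fills the `−y` side, so the open field is at `+y`. A local point maps to
machine depth `X = SCD − x` (source plane `X = 0`, scoring plane `X = SAD`).
This orientation — with the circular-arc centre offset `d` applied to the
depth coordinate — is what makes the published optimal designs internally
consistent: under the opposite orientation the printed Bézier optimum
produces a strongly position-dependent sweep instead of the near-flat one
its σ implies, and the circular optimum's σ is off by a factor ~2.

Every feasible leaf end is single-valued `y(x)` (the constraint sets force
monotone `x(t)`), so the closed leaf profile is the region below the end
curve, bounded by vertical edges at `x = ±lh/2` and a back closure
`3·lh` below the curve ends — deep enough that no modelled ray exits
through it.

Curve families and their design variables:

| family | variables | fixed |
|---|---|---|
| circular arc | radius `R`, centre depth-offset `d` | endpoints on `x = ±lh/2` by construction |
| elliptical arc | semiminor axis `b` | semimajor axis `a = lh/2` |
| cubic Bézier | interior control points `P1, P2` | `P0 = (−lh/2, 0)`, `P3 = (+lh/2, 0)` |
| cubic B-spline | ordinates `y0..y7` | 9 control points, `x_i = (−1/2 + i/8)·lh`, `y8 = 0`, open-uniform knots |

Feasibility combines bound constraints, the linear arc constraints
(`−R ± d + lh/2 ≤ 0`), and discrete concavity
(`y_i + y_{i+2} − 2 y_{i+1} ≤ 0`) for the polynomial families; concave
control polygons give concave `y(x)`, i.e. convex leaf ends. The B-spline
knot vector is clamped with uniform interior knots (only the end knots are
prescribed by the parameterization; clamping makes the endpoint behaviour
match the other families).

## Source model

The focal spot is a Gaussian (or Gaussian-mixture) lateral intensity profile,
`σ = FWHM / (2√(2 ln 2))`. Quantiles are found by bracketing plus Brent
search on the CDF so mixtures need no closed-form inverse. The ray tracer
discretizes the source into `n` equally spaced subsources over
`mean ± 3σ` with midpoint-density weights renormalized to unit sum; at
`n = 100` the truncation-plus-discretization mass error is ≈0.3% (≤1%).
The discretized first moment converges to the truncated-window mean, which
for asymmetric mixtures differs from the full mean by the discarded tail
mass — a deliberate property of the fixed ±3σ window.

## Tangent–secant penumbra evaluation

For leaf position `T` (scoring-plane cm), the leaf is shifted laterally so
its tip (max-`y` point, refined by bounded scalar minimization) projects
through the source centroid onto `T`; this is closed-form. Then:

- **80% point.** `E = (0, q_{0.2})`, the 0.2-quantile of the source: the
  grazing line from `E` leaves the upper 80% of the source mass visible from
  its scoring-plane intercept. The grazing slope is the support-line maximum
  of `(y_curve − y_E)/(X_curve − X_E)`; interior tangencies are roots of the
  cross product `(P − E) × P′(t)`, bracketed on a 257-point parameter grid
  and refined by Brent to 1e−14, with the curve endpoints (edge corners)
  always among the candidates. `P80 = y_E + SAD · slope`.
- **20% point.** The secant source point sits one equivalent source size
  above the quantile point, `C = (0, y_E + e)`, on the open-field side. The
  ray slope is solved (bracketing from the grazing slope, Brent to 1e−15)
  so that the in-material chord through the closed profile equals `l`; rays
  that dip below a curve endpoint enter through the vertical edge, which is
  how the "bowl-shaped" large-radius sweeps arise. `P20 = y_C + SAD · slope`.
- `W = P80 − P20`.

The `C = E + e` anchoring is this package's resolution of an ambiguous
construction ("C is defined by the equivalent source size"): among the
candidate conventions (centroid ± e/2, centroid ± e, E + e) it is the only
one that reproduces all three published sweep means simultaneously with the
published `(e, l)`; the alternatives are off by 2–3% or produce unphysical
negative widths. The choice is absorbed into `e` on recalibration, so it is
a convention, not a free parameter.

Degenerate cases: if no chord of length `l` exists even through the full
profile the evaluation raises (never clamps); tangencies falling outside
`t ∈ (0, 1)` return the supporting corner with a flag.

## Ray-tracing reference

Straight rays from each weighted subsource to the scoring point, attenuated
by `exp(−μ_a l_t)` with `μ_a = ρ · (μ_a/ρ)`. Path lengths use a height-field
resampling of the end curve on a 1601-point uniform depth grid with linear
interpolation at the crossings (cross-checked against exact polygon
intersection to 2e−5 cm); open-field intensity is exactly 1 by weight
normalization. The 80%/20% crossings are bracketed on 100 samples of a
window `tip-projection ± 5·(geometric + transmission penumbra estimate)` —
the window is widened once and the run aborts if crossings are still not
bracketed — then refined by bracketing root-finding on the continuous
fluence function to 1e−8 cm, so the result is insensitive to the segment
count (100 vs 1000 segments and 100 vs 400 subsources each move `W` far
less than 1%).

## Calibration

`(e, l)` are identified by bounded least squares (`scipy.optimize
.least_squares`, trf) on cell-wise width residuals over a reference matrix
(≥2 curves × ≥3 positions for identifiability; equal cell weights). Default
start `e0 = FWHM`, `l0 = ln(5)/μ_a`; bounds `e ∈ (0, 5·FWHM]`,
`l ∈ (0, lh]`. Self-recovery against model-generated references is exact to
1e−6. Calibrated against the internal ray tracer over the seven-radius
verification family (R = 4…25 cm, 17 positions), the fit gives
`e ≈ 0.140 cm`, `l ≈ 1.185 cm` and tracks the tracer to 1.5% on average.
The worst cell is the extreme bowl corner (R = 25 cm, T = +20 cm) at 12.0%:
the pure-visibility tangent ignores transmission through rays cutting the
sharp curve/edge corner and pushes `P80` ≈ 1 mm outward there. This is
intrinsic model structure (the reference is converged; the fit is the
verified global least-squares minimum), and it is the same cell and
magnitude as the model's known worst case. The published
`e = 0.152 cm, l = 1.174 cm` (calibrated against Monte Carlo) are used as
canonical inputs whenever published designs are re-evaluated.

## Optimization

- Sweep: `N = 17` positions uniform over a symmetric ±20 cm stroke at the
  scoring plane; `σ` uses the sample convention `1/(N−1)`. The sweep length
  behind the published optima is not recorded anywhere, so the verification
  sweep is used for optimization as well — this is the package's assumption
  behind all reproductions.
- Local: SLSQP with finite-difference step 1e−6 (the objective is smooth to
  ~1e−9 thanks to the root-finding tolerances above), `ftol = 1e−12`,
  Table-style constraints as inequalities. The circular/elliptical mean
  objectives are convex (numeric Hessian PSD at the optimum); the mean
  surface is a very flat curved valley — 3e−4 cm over ΔR ≈ 3 cm — so
  different solvers stop at slightly different valley points; the reported
  optimum is the SLSQP terminus from the minimal-radius start.
- Global: an in-package NSGA-II (simulated binary crossover η=15, polynomial
  mutation η=20 at rate 1/n_var, binary tournament with
  feasibility-dominance, crowding-distance elitism), seeded and reproducible.
  Defaults population 80 × 150 generations suit the ≤8-variable design
  spaces; tests and examples use smaller budgets with a short sweep.
- Multistart local optimization deduplicates optima by a merge radius in
  design space. Pareto fronts are audited for mutual nondominance;
  `select_optimal` shortlists points with mean within a 5% band of the front
  minimum and returns the smallest-σ member (near-vertex rule).

## Empirical radius

The closed-form optimal-radius rule
`R_opt = ½ √(a1² + 4a1²a2² + 4a1a2²a3a4 + a4² + 4a2²a4²)` with
`a1 = ln(0.2)/μ_a`, `a2 = SAD/FS`, `a3 = √(4·SAD² + FS²)/SAD`, `a4 = lh`
is implemented verbatim. Its radicand is provably positive for all positive
inputs (as a quadratic in `a1` its discriminant is `−a4²(16a2² + 4) < 0`),
so the guard against a negative radicand is unreachable in the physical
domain; note `R_opt` *increases* with `μ_a` over the physical range (the
radicand's derivative in `a1` is positive), and increases with `lh`.

## Shape comparison

`max_lateral_deviation` compares two single-valued `y(x)` curves on a grid
with spacing ≤1e−3·lh. By default the raw maximum `|Δy|` is returned; with
`align="minimax"` the arbitrary relative lateral datum (each leaf's absolute
position is a machine calibration, not a shape property) is removed by the
shift minimizing the maximum deviation. The piecewise leaf end (central arc
of radius `R` blended C¹ into straight segments at `α_l` to the rotation
axis) blends at `x = ±R sin α_l`, which must fall inside the leaf height.

## What the synthetic conditions do and do not show

All quantitative results are for an idealized single-leaf, monoenergetic,
in-air model: a point-to-plane geometry with a Gaussian focal spot, one leaf
end, Beer–Lambert attenuation, no scatter, no opposing leaf, no
tongue-and-groove or interleaf effects, and no in-phantom dose. Passing
tests therefore demonstrate the internal consistency of the constructions,
the calibration, and the optimizers — not the clinical penumbra of a real
machine, which adds extra-focal scatter, spectral effects and phantom
scatter on top of the fluence penumbra modelled here.

## Known limitations

- Accuracy degrades to ~12% where a sharp curve/edge corner dominates
  (extreme positions of very flat tips); within-stroke cells are 1–3%.
- The optimization mean-surface flatness means reported optima are
  valley-floor points reproducible only to ~0.1–0.5 cm in `R` across solver
  settings (the objective differences involved are <1e−3 mm).
- The B-spline family is covered by property tests only; no external
  reference design is available for it.
- Asymmetric strokes and weighted position sampling have config hooks but
  are untested features.
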