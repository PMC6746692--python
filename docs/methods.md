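# Methods

## Model

The package solves selective two-phase segmentation as a convex
relaxation.  For an image `z` on a pixel grid Ω (intensities normalised
to [0,1], spacing 1, coordinates (row, col)) and a user region `P`
(polygon from ≥ 3 clicked markers, or a mask), the relaxed indicator
`u : Ω → [0,1]` minimises

    E(u) = TV_g(u) + λ̃ ∫ F u dΩ + α ∫ ν_ε₂(u) dΩ,

with `F = r/‖r‖_∞`, `r = θ D + f`.  Sup-normalising the data term makes
λ̃ and θ comparable across fitting terms; they are the only two tuning
parameters.  The binary result is the strict threshold `u > 0.5`;
convexity makes this essentially independent of the initial labelling
(asserted in tests: masks from `u⁰ = χ_P` and `u⁰ ≡ 0.5` differ on
≤ 0.5 % of pixels).

### Fitting terms

`f` is one of six per-pixel functions; negative values favour
foreground.  The proposed term (`pm`) is

    f = λ₁ (z − c₁)² − λ₂ f̃₂(z),
    f̃₂ = 1 + (z−c₁)/γ₁  on [c₁−γ₁, c₁],
         1 − (z−c₁)/γ₂  on (c₁, c₁+γ₂],
         0 otherwise,

with `c₁` the mean of `z` over `P`, held fixed for the whole run.  The
window replaces the background constant `c₂` of the Chan–Vese (`cv`)
term: it penalises background pixels *near the marked intensity*,
asymmetrically above and below `c₁`, which is exactly what a selective
problem needs when the global background mean happens to equal `c₁`.
λ₁ = λ₂ = 1 throughout; the global weight λ̃ carries the balance.

The baselines (`cv`, `rsf`, `lcv`, `hyb`, `gav`) are implemented in the
same convex frame.  Their constants refresh once per outer iteration
from the current thresholded labelling (γ = 0.5): region means for CV;
Gaussian-kernel local mean ratios for RSF (σ = 3 px default, kernel
truncated at 4σ, unit sum, replicate boundary); box-window means and
difference-image constants for LCV/HYB (k = 3, α_w = β_w = 1); power
mean ratios `Σz^β w / Σz^{β−1} w` for GAV with independent exponents
(β₁, β₂), default (4, −2), search space the eight pairs (1.5,0.5),
(2,0), (3,−1), (4,−2), (0.5,1.5), (0,2), (−1,3), (−2,4).  Intensities
are floored at 10⁻⁶ before negative-exponent powers; empty regions fall
back to global means with a warning.  The exact baseline
hyper-parameters used in the original experiments are not published;
ours are package defaults exposed in `RegionConstants`.

### Geodesic marker constraint

`D` solves `|∇D⁰| = q`, `D⁰ = 0` on `P`, with
`q = ε_D + β_G |∇z|²` (ε_D = 10⁻³, β_G = 1000), then `D = D⁰ / max D⁰`
over pixels outside `P` (all-zero if `P` is the whole domain).  The
solver is first-order upwind fast marching on the 4-neighbour stencil
with a binary heap; `q ≡ const` reduces to a scaled Euclidean distance
transform.  Cross-checks: Dijkstra on the 8-connected pixel graph with
local-metric edge weights (far-field agreement within a declared 25 %
discretisation tolerance — the oracle itself carries an ~8 %
metrication bias) and `scipy.ndimage.distance_transform_edt` for the
unit-cost case (0.05 sup-norm on normalised maps).

### Automatic (γ₁, γ₂)

The histogram of `z` (256 bins on [0,1]) is partitioned by N-class Otsu
thresholding, N = 3: one mode below, at, and above the target intensity
is the most structure a selective two-phase problem needs.  The search
is exhaustive over bin-boundary placements (vectorised prefix sums),
ties broken toward the lexicographically smallest threshold vector;
thresholds are reported at bin upper edges.  With thresholds T₁ < T₂
the half-widths follow the position of c₁: between two thresholds →
(c₁−T_{i−1}, T_i−c₁); below T₁ → (c₁, T₁−c₁); above T_{N−1} →
(c₁−T_{N−1}, 1−c₁).  Equalities resolve to the interior case; outputs
are floored at γ_min = 10⁻³ so the window never degenerates.

### Penalty and AOS scheme

`ν_ε₂(u) = H_ε₂(b(u))·b(u)` with `b(u) = √((2u−1)² + ε₂) − 1` and the
arctan-regularised Heaviside `H_ε₂`; as ε₂ → 0 this is the exact
penalty (zero on [0,1], linear growth outside).  α defaults to λ̃, which
satisfies the enforcement condition α > λ̃/2·‖F‖_∞ since ‖F‖_∞ = 1.

The gradient flow `∂u/∂t = ∇·(G∇u) − f₀`,
`G = g(|∇z|)/|∇u|_ε₁`, `f₀ = λ̃F + α ν′(u)`, is discretised
semi-implicitly.  Each step builds two 1-D diffusion operators (central
half-point conductivities, zero-flux ends), damps the explicit source by
`(I+B̃)⁻¹` where `B̃ = diag(τ α b̃)` and `b̃` equals the linear Taylor
coefficient of ν′ (computed analytically; identical at u = 0 and u = 1
by symmetry) wherever `u` lies within ζ of {0, 1}, and averages the two
tridiagonal Thomas solves.  The explicit source enters with the descent
sign (`ũ = u − τ(I+B̃)⁻¹f₀`), the convention under which the discrete
energy is non-increasing — asserted on every fixture run.

Fixed numerics: τ = 10⁻², ε₁ = 10⁻⁴, ε₂ = 10⁻¹, stopping when the mean
absolute per-pixel change ≤ 10⁻⁴ (cap 2000 iterations, unconverged runs
return the last iterate with a warning).

**Choice of ζ.**  ζ = 0.1, matching the scale of ε₂.  The steep part of
ν′ sits at `u ≈ ∓0.03` around 0 and 1 (where `b` crosses ±ε₂); a
stabilisation band narrower than that (e.g. ζ = 10⁻²) leaves the
penalty source explicit exactly where its Lipschitz constant is
largest, and for λ̃ ≳ 10 the iteration limit-cycles with mean change
~2·10⁻² instead of converging.  With ζ = 0.1 the scheme converges in
tens of iterations across λ̃, θ ∈ [1, 50].

## Synthetic scenes

The generator emulates the benchmark statistics of piecewise-constant
selective problems `z = c₁χ_F + c₂χ_B + η`:

* **equal-mean** (`make_equal_mean_fixture`): disc target at 0.50, a
  decoy disc also at 0.50, and two background panels (0.30 and a value
  ≈ 0.70 solved from the pixel counts) such that the mean over
  Ω∖target is 0.50 *exactly* — the c₁ = c₂ = 0.50 regime in which
  region-mean fitting terms vanish on the true partition (asserted);
* **contrast** (`make_contrast_fixture`): target and decoy at 0.75 over
  panels balancing the background mean to 0.49 — the easier regime
  where all baselines except RSF succeed.

Geometry (centres, radii, panel split) jitters with the seed; the
governing statistics are held to ±10⁻² and checked after rasterisation.
Noise is off by default; σ = 0.02 Gaussian noise is available for
robustness tests.  `default_markers` inscribes a deterministic triangle
at half the inradius of the target; `random_markers` draws k points
uniformly from the target interior, rejecting polygons of area < 1 px.

What these scenes do **not** emulate: intensity inhomogeneity inside
the target, partial-volume/blurred boundaries, anisotropic noise, and
the anatomical complexity of clinical CT/MRI.  Passing results
demonstrate the designed failure/success mechanism and robustness to
marker placement on piecewise-constant scenes, not clinical
performance.

## Evaluation harness

Accuracy is the Tanimoto (Jaccard) coefficient |A∩B|/|A∪B|; two empty
masks score 1, an empty prediction against a nonempty truth 0.
`parameter_sweep` evaluates a (λ̃, θ) grid with fixed markers (default
grid: integers 1–10 and every fifth value 15–50), reusing the distance
and edge maps across cells; failed solves record TC = 0 with a flag.
`randomized_marker_study` repeats the solve over seeded uniform
3-marker draws and reports the TC sample with boxplot statistics.
`scripts/acceptance.py` runs the full protocol (coarse grid tune, then
100 random-marker solves per scene) at 128×128; the problem size keeps
the whole run within a few CPU-minutes while leaving ≥ 30 pixels across
the target diameter.

## Known limitations

* RSF in this convex frame, with constants refreshed from the
  thresholded labelling and a marker-polygon initialisation, has no
  long-range growth force: far from `P` its local means adapt to
  whatever the current labelling says, so it stalls near the marker
  region on our scenes at any kernel scale.  The degenerate-limit
  identities (large-σ → region means) are verified instead.
* The Eikonal solver is first-order; distances near the source carry
  O(1) relative error on the first ring of pixels (irrelevant after
  normalisation, but visible in oracle comparisons).
* Only N = 2 or 3 Otsu classes are supported, matching the design
  argument that selective two-phase problems need at most three modes.
* Greyscale 2-D images only; no colour, volumes, or anisotropic
  spacing.
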