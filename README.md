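# selectseg

Selective two-phase segmentation of greyscale images: isolate **one**
user-indicated object among others of similar intensity, as needed for
organ contouring in CT/MRI where manual delineation is slow and generic
segmentation picks up every similar structure.

## The model

Given an image `z : Ω → [0,1]` and a few user marker points forming a
small polygon `P` inside the target, the foreground indicator
`u ∈ [0,1]` minimises the convex functional

```
min_u  TV_g(u) + λ̃ ∫ F(x) u(x) dx + α ∫ ν(u) dx
```

* `TV_g(u) = ∫ g(|∇z|) |∇u| dx` with `g(s) = 1/(1+βs²)` — contour length
  weighted to be cheap along image edges;
* `F = r/‖r‖_∞`, `r(x) = θ·D(x) + f(x)` — the data term, combining
  * the **geodesic distance penalty** `D`, the normalised solution of
    the Eikonal problem `|∇D| = ε_D + β_G |∇z|²` with `D = 0` on `P`, so
    distance from the markers accumulates slowly inside homogeneous
    regions and fast across edges, and
  * a per-pixel **fitting term** `f` whose negative values favour
    foreground;
* `ν(u)` — a regularised exact penalty enforcing `u ∈ [0,1]`, so the
  relaxed problem is unconstrained and any threshold `u > γ` (γ = 0.5)
  recovers a binary minimiser independent of initialisation.

The package's core contribution is the **asymmetric background fitting
term**: with `c₁` the mean intensity inside `P`,

```
f(x) = (z − c₁)² − f̃₂(z),     f̃₂ = piecewise-linear window peaking at
                               z = c₁, supported on [c₁−γ₁, c₁+γ₂]
```

so background structure near the *marked* intensity is penalised
regardless of whether the rest of the background is brighter or darker —
exactly the regime (foreground mean ≈ background mean) where the
Chan–Vese term `(z−c₁)² − (z−c₂)²` collapses to zero.  The half-widths
`(γ₁, γ₂)` are selected automatically from a 3-class Otsu partition of
the intensity histogram.  Baselines in the same frame: `cv`, `rsf`,
`lcv`, `hyb`, `gav`.

Minimisation uses a modified additive-operator-splitting (AOS) scheme:
two 1-D semi-implicit tridiagonal solves (Thomas algorithm, Neumann
ends) per step, with the penalty derivative stabilised near `u ∈ {0,1}`
by its Taylor linearisation.

## Worked example

```python
import numpy as np
from selectseg import SelectiveSegmentation, make_equal_mean_fixture, default_markers

# a 128x128 scene whose background mean equals the target mean (0.50),
# with a decoy object of the same intensity
z, gt, extras = make_equal_mean_fixture(seed=1)
markers = default_markers(gt, seed=0)

model = SelectiveSegmentation(z, markers=markers.markers, fitting="pm")
res = model.fit(lambda_tilde=5, theta=5, ground_truth=gt)
print(res.summary())
```

prints

```
Selective segmentation results
==============================================
fitting term            pm
image shape             (128, 128)
marker points           3
lambda~ (data weight)   5
theta (selection)       5
alpha (penalty)         5
iterations              88 (converged)
final change            9.267e-05
foreground pixels       1333
c1 / gamma1 / gamma2    0.5000 / 0.1992 / 0.0039
Tanimoto vs GT          1.0000
```

The Tanimoto (Jaccard) coefficient of 1.0000 means the thresholded
labelling reproduces the ground-truth disc exactly, while the decoy of
identical intensity is excluded by the geodesic term.  On the same scene
the Chan–Vese fitting (`fitting="cv"`) scores ≈ 0.08: with
`c₁ ≈ c₂ = 0.50` its data term vanishes and the contour never leaves the
marker polygon.

A thin CLI mirrors the library:

```bash
selectseg make-fixture --kind equal-mean --seed 1 --out-prefix scene
selectseg run --image scene.png --markers scene_markers.csv \
          --model pm --lambda 5 --theta 5 --gt scene_gt.png --out mask.png
selectseg sweep ... ; selectseg random-study ...
```

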