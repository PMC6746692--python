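"""Seeded synthetic fixtures emulating the benchmark test scenes.

Each fixture is a piecewise-constant image ``z = c1 X_F + c2 X_B (+ eta)``
with a homogeneous disc target, a decoy object of the *same* intensity
(so only the marker constraint can tell them apart), and two background
panels whose areas balance the background mean to a requested value:

* equal-mean scene: target at 0.50 with the mean over everything outside
  the target equal to 0.50 - the regime where plain region-mean fitting
  terms collapse (c1 == c2);
* contrast scene: target at 0.75 over a background of mean 0.49.

Geometry is jittered by the seed; the governing statistics (c1, c2) are
held fixed and asserted after rasterisation.  Gaussian noise is off by
default; a small sigma (e.g. 0.02) is available for robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, ImageGrid, MarkerRegion, polygon_region

__all__ = [
    "FixtureSpec",
    "make_equal_mean_fixture",
    "make_contrast_fixture",
    "default_markers",
    "random_markers",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Resolved parameters of a rendered fixture (for provenance sidecars)."""

    shape: tuple[int, int]
    foreground_value: float
    background_mean: float
    noise_sigma: float
    seed: int
    target_centre: tuple[float, float]
    target_radius: float
    decoy_centre: tuple[float, float]
    decoy_radius: float
    panel_value: float
    fill_value: float


def _disc(shape: tuple[int, int], centre: tuple[float, float],
          radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius ** 2


def _render(shape: tuple[int, int], seed: int, fg_value: float,
            bg_mean: float, noise_sigma: float):
    if shape[0] < 96 or shape[1] < 96:
        raise ValueError("fixture shape must be at least 96x96 to fit the "
                         "target and decoy")
    h, w = shape
    rng = np.random.default_rng(seed)
    scale = min(h, w)

    # two background panels split by a vertical line; the dark panel hosts
    # the target, the bright panel the same-intensity decoy.  Strong panel
    # contrast gives the scene real edges (so the geodesic metric is
    # informative) while the panel areas balance the background mean.
    ws = int((0.55 + rng.uniform(-0.02, 0.02)) * w)
    t_centre = (0.45 * h + rng.uniform(-0.04, 0.04) * h,
                0.27 * w + rng.uniform(-0.02, 0.02) * w)
    t_radius = (0.150 + rng.uniform(-0.012, 0.012)) * scale
    d_centre = (0.55 * h + rng.uniform(-0.04, 0.04) * h,
                0.80 * w + rng.uniform(-0.015, 0.015) * w)
    d_radius = (0.110 + rng.uniform(-0.010, 0.010)) * scale

    target = _disc(shape, t_centre, t_radius)
    decoy = _disc(shape, d_centre, d_radius)
    cols = np.arange(w)[None, :]
    left = np.broadcast_to(cols < ws, shape) & ~(target | decoy)
    right = np.broadcast_to(cols >= ws, shape) & ~(target | decoy)
    if (target & decoy).any() or target[:, ws:].any() or decoy[:, :ws].any():
        raise ValueError("fixture geometry error: objects overlap the "
                         "panel split")

    panel_value = 0.30
    a_d = int(decoy.sum())
    a_l = int(left.sum())
    a_r = int(right.sum())
    a_bg = a_d + a_l + a_r
    # solve the area balance so mean(z | outside target) == bg_mean exactly
    fill = (bg_mean * a_bg - fg_value * a_d - panel_value * a_l) / a_r
    if not 0.0 <= fill <= 1.0:
        raise ValueError("infeasible background area arithmetic for the "
                         f"requested mean (fill value {fill:.3f})")

    z = np.full(shape, fill)
    z[left] = panel_value
    z[decoy] = fg_value
    z[target] = fg_value
    if noise_sigma > 0:
        z = np.clip(z + rng.normal(0.0, noise_sigma, size=shape), 0.0, 1.0)

    spec = FixtureSpec(shape=shape, foreground_value=fg_value,
                       background_mean=bg_mean, noise_sigma=noise_sigma,
                       seed=seed, target_centre=t_centre,
                       target_radius=t_radius, decoy_centre=d_centre,
                       decoy_radius=d_radius, panel_value=panel_value,
                       fill_value=float(fill))
    achieved = float(z[~target].mean())
    if abs(achieved - bg_mean) > 1e-2:
        raise ValueError("rendered background mean "
                         f"{achieved:.4f} misses requested {bg_mean:.4f}")
    return ImageGrid(z), BinaryMask(target), BinaryMask(decoy), spec


def make_equal_mean_fixture(shape: tuple[int, int] = (128, 128),
                            seed: int = 1, noise_sigma: float = 0.0):
    """Target at 0.50 with the background mean also 0.50.

    Returns ``(image, gt, decoys)`` where ``decoys`` maps names to the
    masks of same-intensity distractor objects.
    """
    z, gt, decoy, spec = _render(shape, seed, fg_value=0.50, bg_mean=0.50,
                                 noise_sigma=noise_sigma)
    return z, gt, {"decoy": decoy, "spec": spec}


def make_contrast_fixture(shape: tuple[int, int] = (128, 128),
                          seed: int = 1, noise_sigma: float = 0.0):
    """Target at 0.75 over a background of mean 0.49.  Returns (image, gt)."""
    z, gt, _decoy, _spec = _render(shape, seed, fg_value=0.75, bg_mean=0.49,
                                   noise_sigma=noise_sigma)
    return z, gt


def default_markers(gt: BinaryMask, seed: int = 0) -> MarkerRegion:
    """Deterministic 3-marker triangle strictly inside the target.

    Vertices sit at half the inradius around the deepest interior point
    (angles rotated slightly by the seed).
    """
    edt = ndimage.distance_transform_edt(gt.values)
    inradius = float(edt.max())
    if inradius < 3.0:
        raise ValueError("target too thin to inscribe a marker triangle")
    centre = np.unravel_index(int(edt.argmax()), edt.shape)
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi / 3.0)
    r = 0.5 * inradius
    pts = []
    for k in range(3):
        ang = phi0 + 2.0 * np.pi * k / 3.0
        pts.append((centre[0] + r * np.sin(ang), centre[1] + r * np.cos(ang)))
    region = polygon_region(np.array(pts), gt.shape)
    if not gt.values[region.region_mask.values].all():
        raise ValueError("marker triangle escapes the target mask")
    return region


def random_markers(gt: BinaryMask, rng: np.random.Generator,
                   k_markers: int = 3, max_tries: int = 50) -> MarkerRegion:
    """Draw k marker points uniformly from the target interior.

    Draws are rejected when the polygon is degenerate (area below one
    pixel, i.e. near-collinear points) or self-intersecting; after
    ``max_tries`` rejections an error is raised.
    """
    interior = ndimage.binary_erosion(gt.values)
    rows, cols = np.nonzero(interior if interior.any() else gt.values)
    if rows.size < k_markers:
        raise ValueError("target interior too small for the marker draw")
    for _ in range(max_tries):
        idx = rng.choice(rows.size, size=k_markers, replace=False)
        pts = np.column_stack([rows[idx], cols[idx]]).astype(float)
        # triangle area guard (shoelace) before rasterising
        if k_markers == 3:
            area = 0.5 * abs(
                (pts[1, 0] - pts[0, 0]) * (pts[2, 1] - pts[0, 1])
                - (pts[2, 0] - pts[0, 0]) * (pts[1, 1] - pts[0, 1]))
            if area < 1.0:
                continue
        try:
            return polygon_region(pts, gt.shape)
        except ValueError:
            continue
    raise ValueError(f"failed to draw a valid marker polygon in "
                     f"{max_tries} tries")
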