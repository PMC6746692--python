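"""Per-pixel fitting functions f(x) for the convex selective functional.

Every model is minimised in the same frame

    min_{u in [0,1]}  TV_g(u) + lambda~ * int F(x) u dx  (+ penalty)

where ``F = r / ||r||_inf`` and ``r(x) = theta * D(x) + f(x)``.  Negative
``f`` favours foreground labelling, positive favours background.  This
module provides

* the proposed asymmetric background term (PM): ``f = lambda1 (z-c1)^2
  - lambda2 * f2~`` with the piecewise-linear window ``f2~`` supported on
  ``[c1-gamma1, c1+gamma2]``;
* the Chan-Vese (CV), region-scalable (RSF), local Chan-Vese (LCV),
  hybrid (HYB) and generalised-averages (GAV) baselines with their
  iterative constant updates.

Per the parameterisation used throughout, ``lambda1 = lambda2 = 1``
inside each f; the single global weight ``lambda~`` (solver) carries the
data-vs-regulariser balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geodesic import DistanceMap
from .grid import ImageGrid, MarkerRegion

__all__ = [
    "PMParams",
    "RegionConstants",
    "FittingField",
    "GAV_BETA_PAIRS",
    "c1_from_region",
    "pm_background",
    "pm_fitting",
    "cv_fitting",
    "rsf_fitting",
    "lcv_fitting",
    "hyb_fitting",
    "gav_constants",
    "assemble_field",
]

#: exponent pairs searched for the generalised-averages baseline
GAV_BETA_PAIRS: tuple[tuple[float, float], ...] = (
    (1.5, 0.5), (2.0, 0.0), (3.0, -1.0), (4.0, -2.0),
    (0.5, 1.5), (0.0, 2.0), (-1.0, 3.0), (-2.0, 4.0),
)

#: intensity floor applied before negative-exponent powers (GAV)
EPS_Z = 1e-6


@dataclass(frozen=True)
class PMParams:
    """Parameters of the proposed fitting term."""

    c1: float
    gamma1: float
    gamma2: float
    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("gamma1 and gamma2 must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("term weights must be non-negative")
        if self.c1 - self.gamma1 < -1 or self.c1 + self.gamma2 > 2:
            raise ValueError("penalty window strays far outside [0, 1]; "
                             "check c1/gamma values")


@dataclass
class RegionConstants:
    """Constants/functions shared by the baseline fitting terms."""

    c1: float = 0.5
    c2: float = 0.5
    d1: float = 0.0           # LCV/HYB difference-image constants
    d2: float = 0.0
    beta1: float = 4.0        # GAV exponents; (4, -2) suits equal-mean scenes
    beta2: float = -2.0
    sigma: float = 3.0        # RSF kernel scale (pixels)
    window_k: int = 3         # LCV/HYB averaging window
    alpha_w: float = 1.0      # LCV/HYB intensity-term weight
    beta_w: float = 1.0       # LCV/HYB difference-term weight
    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.window_k < 1 or self.window_k % 2 == 0:
            raise ValueError("window_k must be odd and >= 1")
        if self.alpha_w < 0 or self.beta_w < 0:
            raise ValueError("alpha_w/beta_w must be non-negative")


@dataclass(frozen=True)
class FittingField:
    """Signed fitting function, the combined field r and its rescale F."""

    f_values: np.ndarray = field(repr=False)
    r_values: np.ndarray = field(repr=False)
    F_values: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.F_values.shape


def c1_from_region(z: ImageGrid, P: MarkerRegion) -> float:
    """Mean image intensity over the marker polygon P (fixes c1 for PM)."""
    m = P.region_mask.values
    if m.shape != z.shape:
        raise ValueError("marker region shape does not match the image")
    if not m.any():
        raise ValueError("empty marker region")
    return float(z.values[m].mean())


def pm_background(z: ImageGrid | np.ndarray, p: PMParams) -> np.ndarray:
    """Asymmetric piecewise-linear background penalty f2~ in [0, 1].

    Peaks at 1 where ``z == c1``, falls linearly to 0 at ``c1 - gamma1``
    and ``c1 + gamma2``, and is 0 outside that window; so background
    structures near the marked intensity are penalised regardless of
    whether the rest of the background is brighter or darker.
    """
    v = z.values if isinstance(z, ImageGrid) else np.asarray(z, dtype=float)
    below = 1.0 + (v - p.c1) / p.gamma1
    above = 1.0 - (v - p.c1) / p.gamma2
    out = np.where(v <= p.c1, below, above)
    lo, hi = p.c1 - p.gamma1, p.c1 + p.gamma2
    out = np.where((v < lo) | (v > hi), 0.0, out)
    return np.clip(out, 0.0, 1.0)


def pm_fitting(z: ImageGrid, p: PMParams) -> np.ndarray:
    """Proposed fitting term ``f = lambda1 (z-c1)^2 - lambda2 f2~``."""
    v = z.values
    return p.lambda1 * (v - p.c1) ** 2 - p.lambda2 * pm_background(v, p)


def cv_fitting(z: ImageGrid, c1: float, c2: float,
               lambda1: float = 1.0, lambda2: float = 1.0) -> np.ndarray:
    """Chan-Vese fitting ``f = lambda1 (z-c1)^2 - lambda2 (z-c2)^2``."""
    v = z.values
    return lambda1 * (v - c1) ** 2 - lambda2 * (v - c2) ** 2


def _region_means(v: np.ndarray, fg: np.ndarray) -> tuple[float, float]:
    """Foreground/background means with global-mean fallback."""
    gmean = float(v.mean())
    c1 = float(v[fg].mean()) if fg.any() else gmean
    bg = ~fg
    c2 = float(v[bg].mean()) if bg.any() else gmean
    if not fg.any() or not bg.any():
        warnings.warn("empty region in constant update; falling back to "
                      "the global mean", stacklevel=3)
    return c1, c2


def rsf_fitting(z: ImageGrid, u_prev: np.ndarray,
                rc: RegionConstants) -> np.ndarray:
    """Region-scalable fitting with kernel-ratio function updates.

    ``h1, h2`` are the Gaussian-weighted local means of z inside/outside
    the current (thresholded) labelling; ``f_i`` are the kernel-smoothed
    squared residuals.  The Gaussian kernel has unit sum, scale
    ``sigma`` and is truncated at radius 4 sigma (replicate boundary).
    """
    v = z.values
    ug = (np.asarray(u_prev, dtype=float) > 0.5).astype(float)

    def smooth(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, rc.sigma, mode="nearest",
                                       truncate=4.0)

    num1, den1 = smooth(ug * v), smooth(ug)
    num2, den2 = smooth((1.0 - ug) * v), smooth(1.0 - ug)
    cm1, cm2 = _region_means(v, ug > 0.5)
    tiny = 1e-12
    bad1, bad2 = den1 <= tiny, den2 <= tiny
    if bad1.any() or bad2.any():
        warnings.warn("locally empty region in RSF update; substituting the "
                      "global region mean there", stacklevel=2)
    h1 = np.where(bad1, cm1, num1 / np.where(bad1, 1.0, den1))
    h2 = np.where(bad2, cm2, num2 / np.where(bad2, 1.0, den2))

    # f_i(x) = int K(x-y) (z(y) - h_i(x))^2 dy, expanded so K is applied to
    # z and z^2 only (h_i is frozen at x)
    kz = smooth(v)
    kz2 = smooth(v * v)
    f1 = kz2 - 2.0 * h1 * kz + h1 * h1
    f2 = kz2 - 2.0 * h2 * kz + h2 * h2
    return rc.lambda1 * f1 - rc.lambda2 * f2


def _box(a: np.ndarray, k: int) -> np.ndarray:
    return ndimage.uniform_filter(a, size=k, mode="nearest")


def _lcv_like(v: np.ndarray, u_prev: np.ndarray,
              rc: RegionConstants) -> np.ndarray:
    """Shared LCV/HYB structure on an arbitrary base image v."""
    ug = (np.asarray(u_prev, dtype=float) > 0.5)
    c1, c2 = _region_means(v, ug)
    diff = _box(v, rc.window_k) - v
    d1 = float(diff[ug].mean()) if ug.any() else 0.0
    d2 = float(diff[~ug].mean()) if (~ug).any() else 0.0
    f1 = rc.alpha_w * (v - c1) ** 2 + rc.beta_w * (diff - d1) ** 2
    f2 = rc.alpha_w * (v - c2) ** 2 + rc.beta_w * (diff - d2) ** 2
    return f1 - f2


def lcv_fitting(z: ImageGrid, u_prev: np.ndarray,
                rc: RegionConstants) -> np.ndarray:
    """Local Chan-Vese fitting on z and the difference image z* - z."""
    return _lcv_like(z.values, u_prev, rc)


def hyb_fitting(z: ImageGrid, u_prev: np.ndarray,
                rc: RegionConstants) -> np.ndarray:
    """Hybrid fitting: LCV structure on the product image w = z* z."""
    v = z.values
    w = _box(v, rc.window_k) * v
    return _lcv_like(w, u_prev, rc)


def gav_constants(z: ImageGrid, u_prev: np.ndarray, beta1: float,
                  beta2: float) -> tuple[float, float]:
    """Generalised-averages constants.

    ``c_i = sum(z^beta_i w) / sum(z^(beta_i - 1) w)`` with w = u (fore)
    or 1-u (back); ``beta = 1`` recovers the plain region means.
    Intensities are floored at a small epsilon before negative-exponent
    powers; a vanishing denominator falls back to the region mean.
    """
    v = z.values
    ug = (np.asarray(u_prev, dtype=float) > 0.5).astype(float)

    def gav_mean(w: np.ndarray, beta: float) -> float:
        vb = np.maximum(v, EPS_Z) if beta < 1 else v
        den = float((vb ** (beta - 1.0) * w).sum())
        if abs(den) < 1e-12:
            warnings.warn("zero denominator in GAV constant update; "
                          "falling back to the region mean", stacklevel=3)
            sel = w > 0.5
            return float(v[sel].mean()) if sel.any() else float(v.mean())
        return float((vb ** beta * w).sum()) / den

    c1 = gav_mean(ug, beta1)
    c2 = gav_mean(1.0 - ug, beta2)
    return c1, c2


def assemble_field(f: np.ndarray, D: DistanceMap | np.ndarray,
                   theta: float) -> FittingField:
    """Combine fitting and distance terms and rescale to sup-norm 1.

    ``r = theta D + f``; ``F = r / ||r||_inf`` (identically zero if r
    is).  The rescale makes parameter choices comparable across models.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    dvals = D.values if isinstance(D, DistanceMap) else np.asarray(D, float)
    f = np.asarray(f, dtype=float)
    if f.shape != dvals.shape:
        raise ValueError(f"shape mismatch: f {f.shape} vs D {dvals.shape}")
    r = theta * dvals + f
    m = float(np.abs(r).max())
    F = r / m if m > 0 else np.zeros_like(r)
    return FittingField(f, r, F)
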