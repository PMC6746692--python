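"""Grid-level data model: images, masks, marker polygons and edge maps.

Conventions shared by every other module:

* coordinates are ``(row, col)``, 0-based, pixel-centred;
* grid spacing is fixed at 1 pixel;
* image intensities live in ``[0, 1]`` after :func:`normalize_image`;
* gradients use central differences in the interior and one-sided
  differences at the borders (``numpy.gradient``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

__all__ = [
    "ImageGrid",
    "BinaryMask",
    "MarkerRegion",
    "EdgeMap",
    "normalize_image",
    "gradient_magnitude",
    "edge_map",
    "polygon_region",
]


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D greyscale image ``z`` on a regular pixel grid.

    Parameters
    ----------
    values : ndarray of float, shape (height, width)
        Intensities in ``[0, 1]``.
    spacing : float
        Grid step; fixed at 1.0 per pixel.
    """

    values: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {v.shape}")
        if v.shape[0] < 3 or v.shape[1] < 3:
            raise ValueError(
                "image must be at least 3x3 (finite-difference stencils "
                f"need interior pixels), got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("image intensities must lie in [0, 1]; "
                             "use normalize_image() first")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """A pixel membership flag field paired with an image grid shape."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {v.shape}")
        if v.dtype != bool:
            uniq = np.unique(v)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("mask values must be two-valued (0/1)")
            v = v.astype(bool)
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area(self) -> int:
        return int(self.values.sum())

    def check_shape(self, other) -> None:
        if self.shape != getattr(other, "shape", other):
            raise ValueError(f"shape mismatch: {self.shape} vs "
                             f"{getattr(other, 'shape', other)}")


@dataclass(frozen=True)
class MarkerRegion:
    """User-marked foreground region P, with the marker points if known.

    The region interior is assumed to lie inside the target object; its
    mean intensity fixes the foreground constant ``c1``.  ``markers`` is
    ``None`` when P was supplied directly as a mask rather than as a
    clicked polygon.
    """

    markers: np.ndarray | None  # (k, 2) float, (row, col) order
    region_mask: BinaryMask = field(repr=False)

    def __post_init__(self) -> None:
        if self.markers is not None:
            m = np.asarray(self.markers, dtype=float)
            if m.ndim != 2 or m.shape[1] != 2 or m.shape[0] < 3:
                raise ValueError("markers must be an ordered list of >= 3 "
                                 "(row, col) points")
            object.__setattr__(self, "markers", m)
        if self.region_mask.area == 0:
            raise ValueError("marker region is empty")


@dataclass(frozen=True)
class EdgeMap:
    """Per-pixel edge-stopping weight ``g(|grad z|) = 1/(1 + beta s^2)``."""

    values: np.ndarray
    beta_edge: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.min() <= 0 or v.max() > 1 + 1e-12:
            raise ValueError("edge map values must lie in (0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def normalize_image(raw: np.ndarray) -> ImageGrid:
    """Affinely rescale a raw intensity field to ``[0, 1]``.

    The minimum maps to 0 and the maximum to 1.  A constant image is
    rejected as degenerate (the rescale is undefined and every fitting
    term would be identically zero).
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw image contains non-finite values")
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        raise ValueError("degenerate image: max intensity equals min")
    return ImageGrid((raw - lo) / (hi - lo))


def gradient_magnitude(z: ImageGrid | np.ndarray) -> np.ndarray:
    """Euclidean norm of the two first-difference image gradient components."""
    v = z.values if isinstance(z, ImageGrid) else np.asarray(z, dtype=float)
    gr, gc = np.gradient(v)
    return np.hypot(gr, gc)


def edge_map(z: ImageGrid, beta_edge: float = 1000.0) -> EdgeMap:
    """Edge-stopping function ``g(s) = 1 / (1 + beta s^2)`` on ``|grad z|``.

    ``beta_edge = 0`` gives a map identically 1, reducing the weighted
    total variation to plain TV.
    """
    if beta_edge < 0:
        raise ValueError(f"beta_edge must be non-negative, got {beta_edge}")
    s = gradient_magnitude(z)
    return EdgeMap(1.0 / (1.0 + beta_edge * s * s), float(beta_edge))


def polygon_region(markers, shape: tuple[int, int]) -> MarkerRegion:
    """Rasterise an ordered marker polygon P to a binary mask.

    A pixel belongs to P when its centre is inside or on the polygon
    boundary (``shapely.covers``).  Collinear, out-of-bounds and
    self-intersecting marker sets are rejected.
    """
    pts = np.asarray(markers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an ordered list of >= 3 (row, col) marker points")
    h, w = shape
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > h - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > w - 1):
        raise ValueError("marker points fall outside the image grid")
    poly = shapely.Polygon(pts)
    if poly.is_valid:
        if poly.area <= 0:
            raise ValueError("marker points are collinear (zero-area polygon)")
    elif shapely.make_valid(poly).area <= 0:
        raise ValueError("marker points are collinear (zero-area polygon)")
    else:
        raise ValueError("marker polygon is self-intersecting")

    r0 = int(np.floor(pts[:, 0].min()))
    r1 = int(np.ceil(pts[:, 0].max()))
    c0 = int(np.floor(pts[:, 1].min()))
    c1 = int(np.ceil(pts[:, 1].max()))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                         indexing="ij")
    centres = shapely.points(np.column_stack([rr.ravel(), cc.ravel()]))
    shapely.prepare(poly)
    inside = shapely.covers(poly, centres).reshape(rr.shape)
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    return MarkerRegion(pts, BinaryMask(mask))
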