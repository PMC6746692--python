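"""Automatic (gamma1, gamma2) selection by multi-level Otsu thresholding.

The asymmetric background penalty is supported on the intensity window
``[c1 - gamma1, c1 + gamma2]``.  The half-widths are chosen from the
N-class Otsu partition of the image histogram: the window spans the
histogram class that contains ``c1``, so the penalty covers exactly the
intensity mode the user marked and stops at the neighbouring modes.
``N = 3`` by default; a selective two-phase problem rarely needs more
phases than "darker than the target / the target / brighter".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ImageGrid

__all__ = ["OtsuThresholds", "multi_otsu", "gamma_from_thresholds"]

#: half-width floor: a zero-width window would disable the penalty
GAMMA_MIN = 1e-3


@dataclass(frozen=True)
class OtsuThresholds:
    """Strictly increasing thresholds T_1 < ... < T_{N-1} in (0, 1)."""

    thresholds: tuple[float, ...]
    n_classes: int
    n_bins: int

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if len(t) != self.n_classes - 1:
            raise ValueError("need exactly n_classes - 1 thresholds")
        if any(not (0.0 < x < 1.0) for x in t):
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", t)


def multi_otsu(z: ImageGrid | np.ndarray, n_classes: int = 3,
               n_bins: int = 256) -> OtsuThresholds:
    """Otsu thresholds maximising between-class variance on ``[0, 1]``.

    The histogram uses ``n_bins`` equal bins on [0, 1]; thresholds are
    reported at bin upper edges.  The search is exhaustive over all
    boundary placements (all single boundaries for N=2, all boundary
    pairs for N=3) and ties are broken toward the lexicographically
    smallest threshold vector.
    """
    vals = z.values if isinstance(z, ImageGrid) else np.asarray(z, dtype=float)
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if n_classes > 3:
        raise ValueError("only N = 2 or 3 classes are supported; a selective "
                         "two-phase problem does not need a finer partition")
    hist, edges = np.histogram(vals.ravel(), bins=n_bins, range=(0.0, 1.0))
    if int((hist > 0).sum()) < n_classes:
        raise ValueError(
            f"image has fewer than {n_classes} occupied intensity bins; "
            "lower n_classes")

    p = hist / hist.sum()
    mids = 0.5 * (edges[:-1] + edges[1:])
    # cumulative mass and first moment; class (i, j] statistics in O(1)
    W = np.concatenate([[0.0], np.cumsum(p)])
    M = np.concatenate([[0.0], np.cumsum(p * mids)])

    def class_term(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """w * mean^2 for classes spanning bins (i, j]; 0 for empty classes."""
        w = W[j] - W[i]
        m = M[j] - M[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(w > 0, m * m / np.where(w > 0, w, 1.0), 0.0)
        return t

    if n_classes == 2:
        k = np.arange(1, n_bins)  # boundary after bin k-1
        obj = class_term(np.zeros_like(k), k) + class_term(k, np.full_like(k, n_bins))
        best = int(np.argmax(obj))  # first max = smallest threshold
        cuts = (int(k[best]),)
    else:
        i = np.arange(1, n_bins - 1)[:, None]
        j = np.arange(2, n_bins)[None, :]
        valid = j > i
        obj = (class_term(np.zeros_like(i + j), i + 0 * j)
               + class_term(i + 0 * j, np.where(valid, j, i + 1))
               + class_term(np.where(valid, j, i + 1), np.full_like(i + j, n_bins)))
        obj = np.where(valid, obj, -np.inf)
        flat = int(np.argmax(obj))  # row-major first max = lexicographic smallest
        bi, bj = np.unravel_index(flat, obj.shape)
        cuts = (int(i[bi, 0]), int(j[0, bj]))

    thresholds = tuple(float(edges[c]) for c in cuts)
    return OtsuThresholds(thresholds, n_classes, n_bins)


def gamma_from_thresholds(c1: float, T: OtsuThresholds,
                          gamma_min: float = GAMMA_MIN) -> tuple[float, float]:
    """Half-widths (gamma1, gamma2) of the background penalty window.

    Cases on the position of ``c1`` among the thresholds:

    (i)   ``T_{i-1} <= c1 <= T_i``   -> ``(c1 - T_{i-1}, T_i - c1)``
    (ii)  ``c1 <= T_1``              -> ``(c1, T_1 - c1)``
    (iii) ``c1 >= T_{N-1}``          -> ``(c1 - T_{N-1}, 1 - c1)``

    Boundary equalities resolve toward case (i) when available; any zero
    output is replaced by ``gamma_min``.
    """
    if not 0.0 <= c1 <= 1.0:
        raise ValueError("c1 must lie in [0, 1]")
    t = T.thresholds
    if len(t) >= 2:
        for lo, hi in zip(t, t[1:]):
            if lo <= c1 <= hi:  # case (i)
                g1, g2 = c1 - lo, hi - c1
                break
        else:
            if c1 <= t[0]:  # case (ii)
                g1, g2 = c1, t[0] - c1
            else:  # case (iii)
                g1, g2 = c1 - t[-1], 1.0 - c1
    else:
        if c1 <= t[0]:
            g1, g2 = c1, t[0] - c1
        else:
            g1, g2 = c1 - t[0], 1.0 - c1
    return max(g1, gamma_min), max(g2, gamma_min)
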