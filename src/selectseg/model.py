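"""Model/Results interface for selective segmentation.

:class:`SelectiveSegmentation` is built from an image plus user markers
and a choice of fitting term; :meth:`~SelectiveSegmentation.fit` runs
the convex AOS minimisation and returns a
:class:`SegmentationResults` carrying the relaxed labelling, the binary
mask, the iterate trace and a ``summary()`` table.  Simulation-style
diagnostics (parameter sweeps, random-marker studies) hang off the
model object.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import evaluate as _ev
from .fitting import PMParams, RegionConstants
from .geodesic import DistanceMap, geodesic_distance
from .grid import (BinaryMask, EdgeMap, ImageGrid, MarkerRegion, edge_map,
                   normalize_image, polygon_region)
from .solver import MODELS, SegmentationRun, SolverConfig, solve

__all__ = ["SelectiveSegmentation", "SegmentationResults"]


class SelectiveSegmentation:
    """Selective two-phase segmentation of one greyscale image.

    Parameters
    ----------
    image : ImageGrid or ndarray
        Greyscale image; raw arrays are affinely normalised to [0, 1].
    markers : array-like of (row, col), optional
        Ordered user marker points (>= 3) forming the polygon P inside
        the target.  Exactly one of ``markers`` / ``marker_mask``.
    marker_mask : BinaryMask or bool ndarray, optional
        A foreground region P given directly as a mask.
    fitting : str
        One of ``pm`` (proposed asymmetric background term), ``cv``,
        ``rsf``, ``lcv``, ``hyb``, ``gav``.
    config : SolverConfig, optional
        Numerical defaults; individual fields can be overridden in
        :meth:`fit`.
    """

    def __init__(self, image, markers=None, marker_mask=None,
                 fitting: str = "pm", config: SolverConfig | None = None):
        if isinstance(image, ImageGrid):
            self.image = image
        else:
            arr = np.asarray(image, dtype=float)
            if arr.min() >= 0 and arr.max() <= 1 and arr.max() > arr.min():
                self.image = ImageGrid(arr)
            else:
                self.image = normalize_image(arr)
        if (markers is None) == (marker_mask is None):
            raise ValueError("provide exactly one of markers / marker_mask")
        if markers is not None:
            self.region = polygon_region(markers, self.image.shape)
        else:
            mask = (marker_mask if isinstance(marker_mask, BinaryMask)
                    else BinaryMask(np.asarray(marker_mask)))
            self.region = MarkerRegion(None, mask)
        if fitting not in MODELS:
            raise ValueError(f"unknown fitting {fitting!r}; one of {MODELS}")
        self.fitting = fitting
        self.config = config or SolverConfig()
        self._distance: DistanceMap | None = None
        self._edges: EdgeMap | None = None

    # cached geometry-dependent fields -------------------------------------
    @property
    def distance_map(self) -> DistanceMap:
        """Normalised geodesic distance penalty from P (cached)."""
        if self._distance is None:
            self._distance = geodesic_distance(
                self.image, self.region, self.config.eps_d, self.config.beta_g)
        return self._distance

    @property
    def edge_weights(self) -> EdgeMap:
        if self._edges is None:
            self._edges = edge_map(self.image, self.config.beta_edge)
        return self._edges

    # fitting ---------------------------------------------------------------
    def fit(self, lambda_tilde: float | None = None,
            theta: float | None = None, *,
            pm_params: PMParams | None = None,
            constants: RegionConstants | None = None,
            u0: np.ndarray | None = None,
            ground_truth: BinaryMask | np.ndarray | None = None,
            **config_overrides) -> "SegmentationResults":
        """Minimise the selective functional; returns the results object."""
        overrides = dict(config_overrides)
        if lambda_tilde is not None:
            overrides["lambda_tilde"] = lambda_tilde
        if theta is not None:
            overrides["theta"] = theta
        cfg = dataclasses.replace(self.config, **overrides) if overrides \
            else self.config
        run = solve(self.image, self.region, self.fitting, cfg,
                    D=self.distance_map, g=self.edge_weights,
                    pm_params=pm_params, constants=constants, u0=u0)
        if ground_truth is not None:
            run.tc = _ev.tanimoto(run.mask, ground_truth)
        return SegmentationResults(self, run)

    # simulation-style diagnostics ------------------------------------------
    def parameter_sweep(self, ground_truth, lambda_grid=_ev.DEFAULT_SWEEP_GRID,
                        theta_grid=_ev.DEFAULT_SWEEP_GRID):
        """TC over a (lambda~, theta) grid with these fixed markers."""
        gt = (ground_truth if isinstance(ground_truth, BinaryMask)
              else BinaryMask(np.asarray(ground_truth)))
        return _ev.parameter_sweep(self.image, self.region, gt, self.fitting,
                                   lambda_grid, theta_grid, self.config)

    def randomized_marker_study(self, ground_truth, n_trials: int = 100,
                                seed: int = 1, **kwargs):
        """Robustness of this model to random 3-marker user input."""
        gt = (ground_truth if isinstance(ground_truth, BinaryMask)
              else BinaryMask(np.asarray(ground_truth)))
        return _ev.randomized_marker_study(self.image, gt, self.fitting,
                                           n_trials=n_trials, seed=seed,
                                           cfg=self.config, **kwargs)


class SegmentationResults:
    """Fitted labelling with diagnostics.

    Attributes
    ----------
    u : ndarray
        Relaxed labelling in ~[0, 1].
    mask : BinaryMask
        Thresholded foreground (strict ``u > gamma``, gamma = 0.5).
    trace : SolverTrace
        Per-iteration change norms, energies and penalty activations.
    """

    def __init__(self, model: SelectiveSegmentation, run: SegmentationRun):
        self.model = model
        self.run = run

    # convenient views ------------------------------------------------------
    @property
    def u(self) -> np.ndarray:
        return self.run.u

    @property
    def mask(self) -> BinaryMask:
        return self.run.mask

    @property
    def converged(self) -> bool:
        return self.run.trace.converged

    @property
    def iterations(self) -> int:
        return self.run.trace.iterations

    @property
    def trace(self):
        return self.run.trace

    @property
    def params(self) -> SolverConfig:
        return self.run.config

    def tanimoto(self, ground_truth) -> float:
        return _ev.tanimoto(self.mask, ground_truth)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cfg = self.run.config
        tr = self.run.trace
        lines = [
            "Selective segmentation results",
            "=" * 46,
            f"{'fitting term':<24}{self.run.model}",
            f"{'image shape':<24}{self.model.image.shape}",
            f"{'marker points':<24}"
            f"{len(self.model.region.markers) if self.model.region.markers is not None else 'mask input'}",
            f"{'lambda~ (data weight)':<24}{cfg.lambda_tilde:g}",
            f"{'theta (selection)':<24}{cfg.theta:g}",
            f"{'alpha (penalty)':<24}{cfg.alpha_eff:g}",
            f"{'iterations':<24}{tr.iterations}"
            f"{' (converged)' if tr.converged else ' (max_iter hit)'}",
            f"{'final change':<24}"
            f"{tr.change[-1]:.3e}" if tr.change else "",
            f"{'foreground pixels':<24}{self.mask.area}",
        ]
        if self.run.pm_params is not None:
            p = self.run.pm_params
            lines.append(f"{'c1 / gamma1 / gamma2':<24}"
                         f"{p.c1:.4f} / {p.gamma1:.4f} / {p.gamma2:.4f}")
        if self.run.tc is not None:
            lines.append(f"{'Tanimoto vs GT':<24}{self.run.tc:.4f}")
        return "\n".join(x for x in lines if x)

    def plot(self, ax=None, ground_truth=None):
        """Overlay the segmentation contour on the image (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.model.image.values, cmap="gray", vmin=0, vmax=1)
        ax.contour(self.mask.values.astype(float), levels=[0.5], colors="r")
        if ground_truth is not None:
            gv = (ground_truth.values if isinstance(ground_truth, BinaryMask)
                  else np.asarray(ground_truth, bool))
            ax.contour(gv.astype(float), levels=[0.5], colors="g",
                       linestyles="--")
        m = self.model.region.markers
        if m is not None:
            ax.plot(m[:, 1], m[:, 0], "y^", markersize=5)
        ax.set_axis_off()
        return ax
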