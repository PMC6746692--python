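"""Segmentation accuracy, parameter sweeps and marker-robustness studies."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodesic import geodesic_distance
from .grid import BinaryMask, ImageGrid, MarkerRegion, edge_map
from .solver import SolverConfig, solve
from .synth import random_markers

__all__ = [
    "tanimoto",
    "SweepResult",
    "parameter_sweep",
    "tune_parameters",
    "MarkerStudyResult",
    "randomized_marker_study",
    "DEFAULT_SWEEP_GRID",
]

#: the published sweep grid: every integer 1..10, then every fifth to 50
DEFAULT_SWEEP_GRID: tuple[float, ...] = tuple(range(1, 11)) + tuple(range(15, 55, 5))


def tanimoto(pred: BinaryMask | np.ndarray, gt: BinaryMask | np.ndarray) -> float:
    """Tanimoto/Jaccard coefficient ``|pred & gt| / |pred | gt|``.

    Two empty masks agree perfectly (TC = 1); an empty prediction
    against a nonempty truth scores 0.
    """
    p = pred.values if isinstance(pred, BinaryMask) else np.asarray(pred, bool)
    g = gt.values if isinstance(gt, BinaryMask) else np.asarray(gt, bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


@dataclass
class SweepResult:
    """TC over a (lambda~, theta) grid for one model on one scene."""

    lambda_grid: tuple[float, ...]
    theta_grid: tuple[float, ...]
    tc_matrix: np.ndarray  # shape (len(lambda_grid), len(theta_grid))
    model: str
    fixture: str = ""
    failures: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-form records (model, fixture, lambda, theta, tc)."""
        rows = [
            {"model": self.model, "fixture": self.fixture,
             "lambda": lam, "theta": th,
             "tc": float(self.tc_matrix[i, j])}
            for i, lam in enumerate(self.lambda_grid)
            for j, th in enumerate(self.theta_grid)
        ]
        return pd.DataFrame(rows)

    def best(self) -> tuple[float, float, float]:
        """(lambda~, theta, tc) of the best cell (first max, row-major)."""
        i, j = np.unravel_index(int(np.argmax(self.tc_matrix)),
                                self.tc_matrix.shape)
        return (self.lambda_grid[i], self.theta_grid[j],
                float(self.tc_matrix[i, j]))


def parameter_sweep(z: ImageGrid, P: MarkerRegion, gt: BinaryMask,
                    model: str = "pm",
                    lambda_grid=DEFAULT_SWEEP_GRID,
                    theta_grid=DEFAULT_SWEEP_GRID,
                    cfg: SolverConfig | None = None,
                    fixture: str = "") -> SweepResult:
    """Solve at every (lambda~, theta) pair with fixed markers, record TC.

    The geodesic distance and edge maps depend only on the image and
    markers, so they are computed once and shared by all grid cells.  A
    failed solve is recorded as TC = 0 with a failure flag and the sweep
    continues.
    """
    lambda_grid = tuple(float(x) for x in lambda_grid)
    theta_grid = tuple(float(x) for x in theta_grid)
    if not lambda_grid or not theta_grid:
        raise ValueError("parameter grids must be nonempty")
    cfg = cfg or SolverConfig()
    D = geodesic_distance(z, P, cfg.eps_d, cfg.beta_g)
    g = edge_map(z, cfg.beta_edge)
    tc = np.zeros((len(lambda_grid), len(theta_grid)))
    failed = np.zeros_like(tc, dtype=bool)
    for i, lam in enumerate(lambda_grid):
        for j, th in enumerate(theta_grid):
            cell = dataclasses.replace(cfg, lambda_tilde=lam, theta=th)
            try:
                run = solve(z, P, model, cell, D=D, g=g, track_energy=False)
                tc[i, j] = tanimoto(run.mask, gt)
            except (FloatingPointError, ValueError):
                failed[i, j] = True
    return SweepResult(lambda_grid, theta_grid, tc, model, fixture, failed)


def tune_parameters(z: ImageGrid, P: MarkerRegion, gt: BinaryMask,
                    model: str = "pm",
                    lambda_grid=(2.0, 5.0, 10.0, 20.0),
                    theta_grid=(2.0, 5.0, 10.0),
                    cfg: SolverConfig | None = None) -> tuple[float, float, float]:
    """Coarse grid search; returns the best (lambda~, theta, tc)."""
    sweep = parameter_sweep(z, P, gt, model, lambda_grid, theta_grid, cfg)
    return sweep.best()


@dataclass
class MarkerStudyResult:
    """TC sample from randomised 3-marker user input."""

    tc_values: np.ndarray
    model: str
    lambda_tilde: float
    theta: float
    skipped: int = 0

    @property
    def mean(self) -> float:
        return float(self.tc_values.mean())

    def summary(self) -> dict:
        q1, med, q3 = np.percentile(self.tc_values, [25, 50, 75])
        iqr = q3 - q1
        return {
            "n": int(self.tc_values.size),
            "mean": self.mean,
            "min": float(self.tc_values.min()),
            "q1": float(q1), "median": float(med), "q3": float(q3),
            "iqr": float(iqr),
            "lower_fence": float(q1 - 1.5 * iqr),
            "upper_fence": float(q3 + 1.5 * iqr),
            "max": float(self.tc_values.max()),
            "skipped": self.skipped,
        }


def randomized_marker_study(z: ImageGrid, gt: BinaryMask, model: str = "pm",
                            n_trials: int = 100, k_markers: int = 3,
                            seed: int = 1,
                            cfg: SolverConfig | None = None,
                            rng_streams=None) -> MarkerStudyResult:
    """Robustness to user input: solve over random marker triangles.

    Each trial draws ``k_markers`` non-collinear points uniformly from
    the target interior, solves with fixed (lambda~, theta) and records
    TC.  ``rng_streams`` may supply one seeded generator per trial (for
    externally controlled seeding); otherwise trial t uses
    ``default_rng([seed, t])``.
    """
    cfg = cfg or SolverConfig()
    g = edge_map(z, cfg.beta_edge)
    tcs = []
    skipped = 0
    for t in range(n_trials):
        rng = (rng_streams[t] if rng_streams is not None
               else np.random.default_rng([seed, t]))
        try:
            P = random_markers(gt, rng, k_markers)
        except ValueError:
            skipped += 1
            continue
        run = solve(z, P, model, cfg, g=g, track_energy=False)
        tcs.append(tanimoto(run.mask, gt))
    if not tcs:
        raise ValueError("every marker draw failed; target too small?")
    return MarkerStudyResult(np.asarray(tcs), model,
                             cfg.lambda_tilde, cfg.theta, skipped)
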