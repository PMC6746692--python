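"""Modified additive-operator-splitting (AOS) solver.

The relaxed labelling u minimises the unconstrained functional

    TV_g(u) + lambda~ int F u dx + alpha int nu(u) dx,

where ``nu`` is the regularised exact penalty keeping u near [0, 1].
The gradient flow

    du/dt = div( g(|grad z|) grad u / |grad u|_eps1 ) - f0,
    f0 = lambda~ F + alpha nu'(u),

is discretised semi-implicitly: the 2-D diffusion splits into two 1-D
tridiagonal solves (Thomas algorithm, Neumann ends) that are averaged,
and the penalty derivative is stabilised near u in {0, 1} by the
diagonal update B~ built from the linear Taylor coefficient of nu'.
Iteration stops when the mean absolute per-pixel change drops below
``tol``; the binary segmentation is the strict threshold u > gamma.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fitting import (PMParams, RegionConstants, assemble_field, c1_from_region,
                      cv_fitting, gav_constants, hyb_fitting, lcv_fitting,
                      pm_fitting, rsf_fitting)
from .geodesic import DistanceMap, geodesic_distance
from .grid import BinaryMask, EdgeMap, ImageGrid, MarkerRegion, edge_map
from .otsu import gamma_from_thresholds, multi_otsu

__all__ = [
    "SolverConfig",
    "Labeling",
    "SolverTrace",
    "SegmentationRun",
    "penalty_value_and_derivative",
    "taylor_b_coefficient",
    "b_tilde_mask",
    "aos_iterate",
    "discrete_energy",
    "threshold_labeling",
    "solve",
    "MODELS",
]

MODELS = ("pm", "cv", "rsf", "lcv", "hyb", "gav")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the AOS scheme.

    ``lambda_tilde`` and ``theta`` are the two tuning parameters of the
    method (data weight and selection weight); everything else is fixed
    across experiments: ``tau = 1e-2``, ``eps1 = 1e-4`` (TV floor),
    ``eps2 = 1e-1`` (penalty smoothing), ``tol = 1e-4``.  ``alpha``
    defaults to ``lambda_tilde``, which satisfies the enforcement
    condition ``alpha > lambda~/2 * ||F||_inf`` since ``||F||_inf = 1``.
    """

    lambda_tilde: float = 5.0
    theta: float = 4.0
    tau: float = 1e-2
    eps1: float = 1e-4
    eps2: float = 1e-1
    alpha: float | None = None
    zeta: float = 1e-1
    tol: float = 1e-4
    max_iter: int = 2000
    beta_edge: float = 1000.0
    eps_d: float = 1e-3
    beta_g: float = 1000.0
    threshold_gamma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau", "eps1", "eps2", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lambda_tilde < 0 or self.theta < 0:
            raise ValueError("lambda_tilde and theta must be non-negative")
        if not 0.0 < self.threshold_gamma < 1.0:
            raise ValueError("threshold_gamma must lie in (0, 1)")

    @property
    def alpha_eff(self) -> float:
        """Penalty weight; must exceed lambda~/2 * ||F||_inf (= lambda~/2)."""
        if self.alpha is not None:
            return self.alpha
        return self.lambda_tilde if self.lambda_tilde > 0 else 1.0


@dataclass(frozen=True)
class Labeling:
    """Relaxed or thresholded label function."""

    u: np.ndarray = field(repr=False)
    stage: str = "relaxed"  # or "thresholded"
    threshold_gamma: float = 0.5


@dataclass
class SolverTrace:
    """Per-iteration diagnostics of a solve."""

    change: list[float] = field(default_factory=list)
    energy: list[float] = field(default_factory=list)
    penalty_active: list[int] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


@dataclass
class SegmentationRun:
    """Everything produced by one solve."""

    u: np.ndarray
    mask: BinaryMask
    trace: SolverTrace
    config: SolverConfig
    model: str
    pm_params: PMParams | None = None
    constants: RegionConstants | None = None
    tc: float | None = None


# ---------------------------------------------------------------------------
# penalty function
# ---------------------------------------------------------------------------

def penalty_value_and_derivative(u, eps2: float):
    """Regularised exact penalty ``nu(u) = H(b(u)) b(u)`` and its derivative.

    ``b(u) = sqrt((2u-1)^2 + eps2) - 1`` is ~0 at u in {0, 1}, negative
    inside (0, 1) and grows linearly outside; H is the arctan-smoothed
    Heaviside with width eps2.  As eps2 -> 0 this tends to the exact
    penalty: zero on [0, 1], linear growth outside.
    """
    if eps2 <= 0:
        raise ValueError("eps2 must be positive")
    u = np.asarray(u, dtype=float)
    s = 2.0 * u - 1.0
    root = np.sqrt(s * s + eps2)
    b = root - 1.0
    H = 0.5 * (1.0 + (2.0 / math.pi) * np.arctan(b / eps2))
    Hp = 1.0 / (math.pi * eps2 * (1.0 + (b / eps2) ** 2))
    bp = 2.0 * s / root
    nu = H * b
    nup = bp * (H + b * Hp)
    return nu, nup


def taylor_b_coefficient(eps2: float) -> float:
    """Linear Taylor coefficient of ``nu'`` about u = 0 (equal at u = 1).

    This is ``nu''(0)``, computed by the chain rule; the penalty is even
    about u = 1/2 so the expansions at 0 and 1 share the coefficient.
    """
    if eps2 <= 0:
        raise ValueError("eps2 must be positive")
    s = -1.0  # u = 0
    root = math.sqrt(s * s + eps2)
    b = root - 1.0
    bp = 2.0 * s / root
    bpp = 4.0 * eps2 / root ** 3
    H = 0.5 * (1.0 + (2.0 / math.pi) * math.atan(b / eps2))
    Hp = 1.0 / (math.pi * eps2 * (1.0 + (b / eps2) ** 2))
    Hpp = -2.0 * b / (math.pi * eps2 ** 3 * (1.0 + (b / eps2) ** 2) ** 2)
    return bpp * (H + b * Hp) + bp * bp * (2.0 * Hp + b * Hpp)


def b_tilde_mask(u: np.ndarray, zeta: float, b_coeff: float) -> np.ndarray:
    """Penalty-stabilisation field: ``b_coeff`` where u is within zeta of
    0 or 1 (the interval ``[-zeta, zeta] U [1-zeta, 1+zeta]``), else 0."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    u = np.asarray(u, dtype=float)
    active = (np.abs(u) <= zeta) | (np.abs(u - 1.0) <= zeta)
    return np.where(active, b_coeff, 0.0)


# ---------------------------------------------------------------------------
# one AOS step
# ---------------------------------------------------------------------------

def _tridiag_solve(lower: np.ndarray, diag: np.ndarray, upper: np.ndarray,
                   rhs: np.ndarray) -> np.ndarray:
    """Thomas algorithm for a batch of tridiagonal systems.

    All arrays have shape (n_systems, n); ``lower[:, 0]`` and
    ``upper[:, -1]`` are ignored.
    """
    m, n = diag.shape
    cp = np.empty((m, n))
    dp = np.empty((m, n))
    cp[:, 0] = upper[:, 0] / diag[:, 0]
    dp[:, 0] = rhs[:, 0] / diag[:, 0]
    for i in range(1, n):
        denom = diag[:, i] - lower[:, i] * cp[:, i - 1]
        cp[:, i] = upper[:, i] / denom
        dp[:, i] = (rhs[:, i] - lower[:, i] * dp[:, i - 1]) / denom
    x = np.empty((m, n))
    x[:, -1] = dp[:, -1]
    for i in range(n - 2, -1, -1):
        x[:, i] = dp[:, i] - cp[:, i] * x[:, i + 1]
    return x


def _diffuse_1d(u_t: np.ndarray, G: np.ndarray, w: np.ndarray,
                tau: float, axis: int) -> np.ndarray:
    """Solve ``(I - 2 tau W A_axis) x = u_t`` line by line (Neumann ends).

    A is the 1-D diffusion operator with half-point conductivities
    ``G_{i+1/2} = (G_i + G_{i+1})/2``; W = diag(w) is the inverse of
    ``I + B~``.
    """
    if axis == 0:
        u_t, G, w = u_t.T, G.T, w.T
    Gf = 0.5 * (G[:, 1:] + G[:, :-1])          # interface i+1/2
    m, n = u_t.shape
    Gp = np.zeros((m, n))
    Gm = np.zeros((m, n))
    Gp[:, :-1] = Gf
    Gm[:, 1:] = Gf
    k = 2.0 * tau * w
    lower = -k * Gm
    upper = -k * Gp
    diag = 1.0 + k * (Gm + Gp)
    x = _tridiag_solve(lower, diag, upper, u_t)
    return x.T if axis == 0 else x


def aos_iterate(u: np.ndarray, F: np.ndarray, g: np.ndarray,
                cfg: SolverConfig, b_coeff: float | None = None) -> np.ndarray:
    """One semi-implicit AOS step of the gradient flow.

    Builds the diffusivity ``G = g / sqrt(|grad u|^2 + eps1^2)``, the
    explicit source ``f0 = lambda~ F + alpha nu'(u)`` damped by
    ``(I + B~)^{-1}`` near u in {0, 1}, then averages the two 1-D
    semi-implicit diffusion solves.
    """
    u = np.asarray(u, dtype=float)
    if b_coeff is None:
        b_coeff = taylor_b_coefficient(cfg.eps2)
    alpha = cfg.alpha_eff
    gr, gc = np.gradient(u)
    G = g / np.sqrt(gr * gr + gc * gc + cfg.eps1 ** 2)

    _, nup = penalty_value_and_derivative(u, cfg.eps2)
    f0 = cfg.lambda_tilde * F + alpha * nup
    btil = b_tilde_mask(u, cfg.zeta, b_coeff)
    w = 1.0 / (1.0 + cfg.tau * alpha * btil)   # (I + B~)^{-1}

    u_t = u - cfg.tau * w * f0                 # explicit source, descent sign
    x1 = _diffuse_1d(u_t, G, w, cfg.tau, axis=0)
    x2 = _diffuse_1d(u_t, G, w, cfg.tau, axis=1)
    out = 0.5 * (x1 + x2)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            "non-finite iterate in AOS step; try a smaller time step tau")
    return out


def discrete_energy(u: np.ndarray, F: np.ndarray, g: np.ndarray,
                    cfg: SolverConfig) -> float:
    """Discrete value of the unconstrained functional (same stencils)."""
    gr, gc = np.gradient(np.asarray(u, dtype=float))
    tv = float((g * np.sqrt(gr * gr + gc * gc + cfg.eps1 ** 2)).sum())
    data = cfg.lambda_tilde * float((F * u).sum())
    nu, _ = penalty_value_and_derivative(u, cfg.eps2)
    return tv + data + cfg.alpha_eff * float(nu.sum())


def threshold_labeling(u: np.ndarray | Labeling, gamma: float = 0.5) -> BinaryMask:
    """Binary foreground ``{x : u(x) > gamma}`` (strict inequality)."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie strictly inside (0, 1)")
    vals = u.u if isinstance(u, Labeling) else np.asarray(u, dtype=float)
    return BinaryMask(vals > gamma)


# ---------------------------------------------------------------------------
# the outer iteration
# ---------------------------------------------------------------------------

def _fitting_refresh(model: str, z: ImageGrid, u: np.ndarray,
                     pm: PMParams | None, rc: RegionConstants) -> np.ndarray:
    """Fitting function for the current iterate (baselines refresh their
    constants from the gamma=0.5 thresholded labelling; PM is fixed)."""
    ug = u > 0.5
    if model == "cv":
        c1 = float(z.values[ug].mean()) if ug.any() else rc.c1
        c2 = float(z.values[~ug].mean()) if (~ug).any() else rc.c2
        rc.c1, rc.c2 = c1, c2
        return cv_fitting(z, c1, c2, rc.lambda1, rc.lambda2)
    if model == "rsf":
        return rsf_fitting(z, u, rc)
    if model == "lcv":
        return lcv_fitting(z, u, rc)
    if model == "hyb":
        return hyb_fitting(z, u, rc)
    if model == "gav":
        rc.c1, rc.c2 = gav_constants(z, u, rc.beta1, rc.beta2)
        return cv_fitting(z, rc.c1, rc.c2, rc.lambda1, rc.lambda2)
    raise ValueError(f"unknown model {model!r}; choose one of {MODELS}")


def solve(z: ImageGrid, P: MarkerRegion, model: str = "pm",
          cfg: SolverConfig | None = None, *,
          D: DistanceMap | None = None,
          g: EdgeMap | None = None,
          pm_params: PMParams | None = None,
          constants: RegionConstants | None = None,
          u0: np.ndarray | None = None,
          track_energy: bool = True) -> SegmentationRun:
    """Run the full selective segmentation for one fitting model.

    The geodesic distance map and edge map can be passed in (e.g. reused
    across a parameter sweep with fixed markers); PM's (gamma1, gamma2)
    are resolved via multi-Otsu unless given in ``pm_params``.
    """
    cfg = cfg or SolverConfig()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose one of {MODELS}")
    if g is None:
        g = edge_map(z, cfg.beta_edge)
    if D is None:
        D = geodesic_distance(z, P, cfg.eps_d, cfg.beta_g)

    rc = constants or RegionConstants()
    c1 = c1_from_region(z, P)
    if model == "pm":
        if pm_params is None:
            g1, g2 = gamma_from_thresholds(c1, multi_otsu(z))
            pm_params = PMParams(c1=c1, gamma1=g1, gamma2=g2)
        f_fixed = pm_fitting(z, pm_params)
    else:
        rc.c1 = c1
        f_fixed = None

    if u0 is None:
        u = P.region_mask.values.astype(float)
    else:
        u = np.asarray(u0, dtype=float).copy()
        if u.shape != z.shape:
            raise ValueError("u0 shape does not match the image")

    b_coeff = taylor_b_coefficient(cfg.eps2)
    gv = g.values
    trace = SolverTrace()
    if model == "pm":
        F = assemble_field(f_fixed, D, cfg.theta).F_values

    for it in range(cfg.max_iter):
        if model != "pm":
            f = _fitting_refresh(model, z, u, pm_params, rc)
            F = assemble_field(f, D, cfg.theta).F_values
        u_new = aos_iterate(u, F, gv, cfg, b_coeff)
        change = float(np.abs(u_new - u).mean())
        trace.change.append(change)
        if track_energy:
            trace.energy.append(discrete_energy(u_new, F, gv, cfg))
        trace.penalty_active.append(
            int((b_tilde_mask(u_new, cfg.zeta, 1.0) > 0).sum()))
        u = u_new
        if change <= cfg.tol:
            trace.converged = True
            trace.iterations = it + 1
            break
    else:
        trace.iterations = cfg.max_iter
        warnings.warn("solver reached max_iter without meeting the "
                      "stopping tolerance; returning the last iterate",
                      stacklevel=2)

    mask = threshold_labeling(u, cfg.threshold_gamma)
    return SegmentationRun(u=u, mask=mask, trace=trace, config=cfg,
                           model=model, pm_params=pm_params, constants=rc)
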