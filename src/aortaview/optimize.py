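"""Search for the optimal projection plane under MCL / MEA / mSAR.

Three search modes mirror the escalation from primary-plane projection to
full 3D rotation:

* ``ppp`` — enumerate the three primary planes (XOY, XOZ, YOZ) expressed
  as fixed rotations onto the reference plane.
* ``single_axis_{x,y,z}`` — 1D grid + Nelder-Mead refinement of one Euler
  angle, the others held at zero.
* ``rotation_3d`` — 2D grid over (beta, gamma) with alpha fixed at 0,
  then Nelder-Mead restarts from the best grid cells.  Alpha is fixed
  because a rotation about X leaves the rotated x coordinate of every
  point unchanged and moves (y, z) rigidly in-plane, so CL, EA and SAR of
  the YOZ projection are alpha-invariant: searching (beta, gamma) only is
  lossless.

Criteria: ``mcl`` maximises projected contour length, ``mea`` maximises
enclosed area, ``msar`` minimises the sum of absolute residuals.  mSAR is
the recommended criterion: it directly scores coplanarity of the rotated
curve with the projection plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .centerline import Centerline3D, RotationAngles
from .exceptions import DegenerateInputError, UndefinedObjectiveError, ValidationError
from .geometry import plane_normal
from .metrics import PlaneMetrics, evaluate_plane

__all__ = [
    "CRITERIA",
    "PRIMARY_PLANE_ANGLES",
    "OptimizationResult",
    "evaluate_primary_planes",
    "best_primary_plane",
    "optimize_ppp",
    "optimize_single_axis",
    "optimize_3d",
    "compare_criteria",
]

CRITERIA = ("mcl", "mea", "msar")

#: fixed rotations carrying each primary plane onto the reference (YOZ)
#: plane.  gamma = pi/2 maps world x onto the rotated y axis, so the
#: projection shows (x, z) = XOZ; beta = pi/2 likewise exposes XOY.
PRIMARY_PLANE_ANGLES = {
    "YOZ": RotationAngles(0.0, 0.0, 0.0),
    "XOZ": RotationAngles(0.0, 0.0, np.pi / 2),
    "XOY": RotationAngles(0.0, np.pi / 2, 0.0),
}

_DEFAULT_GRID_DEG = 2.0
_NM_OPTIONS = dict(xatol=1e-12, fatol=1e-13, maxiter=20000, maxfev=20000)


@dataclass(frozen=True)
class OptimizationResult:
    """Best plane found under one criterion and search mode.

    ``trace`` holds every evaluated candidate as rows
    ``(alpha, beta, gamma, objective)`` where the objective is the raw
    criterion value (CL, EA or SAR, not sign-flipped).
    """

    criterion: str
    mode: str
    best_angles: RotationAngles
    best_metrics: PlaneMetrics
    trace: np.ndarray = field(repr=False)
    grid_resolution: float | None = None

    @property
    def objective_value(self) -> float:
        return _criterion_value(self.best_metrics, self.criterion)

    @property
    def canonical_angles(self) -> RotationAngles:
        return self.best_angles.canonical()

    @property
    def plane_normal(self) -> np.ndarray:
        """Unsigned unit normal of the optimal plane, world frame."""
        return plane_normal(self.best_angles)


def _criterion_value(m: PlaneMetrics, criterion: str) -> float:
    if criterion == "mcl":
        return m.cl_2d
    if criterion == "mea":
        if m.ea is None:
            raise UndefinedObjectiveError(
                "enclosed area (mea) is undefined: projection is collinear"
            )
        return m.ea
    if criterion == "msar":
        return m.sar
    raise ValidationError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")


def is_better(criterion: str, a: float, b: float) -> bool:
    """True if objective value ``a`` beats ``b`` under ``criterion``."""
    return a < b if criterion == "msar" else a > b


# ---------------------------------------------------------------------------
# vectorised objective evaluation on (beta, gamma) batches, alpha = 0
# ---------------------------------------------------------------------------


def _batch_objective(
    P: np.ndarray, beta: np.ndarray, gamma: np.ndarray, criterion: str
) -> np.ndarray:
    """Raw criterion values for batches of (beta, gamma) angles.

    ``P`` is the (3, n) point matrix.  Rows of R with alpha = 0:
    row0 = (cb*cg, -sg, sb*cg), row1 = (cb*sg, cg, sb*sg),
    row2 = (-sb, 0, cb); the projection keeps rows 1-2, SAR uses row 0.
    For ``mea`` the fan-of-absolute-triangles area is computed without a
    collinearity check (a collinear projection simply scores ~0 and can
    never win; the final re-evaluation applies the strict check).
    """
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    if criterion == "msar":
        rows = np.stack([cb * cg, -sg, sb * cg], axis=-1)  # (m, 3)
        x = rows @ P  # (m, n)
        return np.abs(x - x.mean(axis=1, keepdims=True)).sum(axis=1)
    rows1 = np.stack([cb * sg, cg, sb * sg], axis=-1)
    rows2 = np.stack([-sb, np.zeros_like(sb), cb], axis=-1)
    y = rows1 @ P
    z = rows2 @ P
    if criterion == "mcl":
        return np.sqrt(np.diff(y, axis=1) ** 2 + np.diff(z, axis=1) ** 2).sum(axis=1)
    if criterion == "mea":
        qy = y - y[:, :1]
        qz = z - z[:, :1]
        cross = qy[:, 1:-1] * qz[:, 2:] - qy[:, 2:] * qz[:, 1:-1]
        return 0.5 * np.abs(cross).sum(axis=1)
    raise ValidationError(f"unknown criterion {criterion!r}")


def _check_criterion_feasible(c: Centerline3D, criterion: str) -> None:
    if criterion not in CRITERIA:
        raise ValidationError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    if criterion == "mea" and len(c) < 3:
        raise DegenerateInputError("mea requires at least 3 points")


# ---------------------------------------------------------------------------
# primary plane enumeration
# ---------------------------------------------------------------------------


def evaluate_primary_planes(
    c: Centerline3D, ea_mode: str = "fan_abs"
) -> dict[str, PlaneMetrics]:
    """Metrics of the three primary projection planes XOY, XOZ, YOZ."""
    return {
        name: evaluate_plane(c, angles, ea_mode)
        for name, angles in PRIMARY_PLANE_ANGLES.items()
    }


def best_primary_plane(metrics: dict[str, PlaneMetrics]) -> str:
    """Recommended primary plane: minimal D (equivalently maximal CL)."""
    return min(metrics, key=lambda k: metrics[k].d)


def optimize_ppp(
    c: Centerline3D, criterion: str = "msar", ea_mode: str = "fan_abs"
) -> OptimizationResult:
    """Pick the best of the three primary planes under ``criterion``."""
    _check_criterion_feasible(c, criterion)
    per_plane = evaluate_primary_planes(c, ea_mode)
    trace, best_name, best_val = [], None, None
    for name, m in per_plane.items():
        try:
            val = _criterion_value(m, criterion)
        except UndefinedObjectiveError:
            continue
        trace.append([*PRIMARY_PLANE_ANGLES[name], val])
        if best_val is None or is_better(criterion, val, best_val):
            best_name, best_val = name, val
    if best_name is None:
        raise UndefinedObjectiveError(
            f"criterion {criterion!r} undefined on all primary planes "
            "(collinear projections)"
        )
    return OptimizationResult(
        criterion=criterion,
        mode="ppp",
        best_angles=PRIMARY_PLANE_ANGLES[best_name],
        best_metrics=per_plane[best_name],
        trace=np.asarray(trace, dtype=float),
    )


# ---------------------------------------------------------------------------
# grid + Nelder-Mead searches
# ---------------------------------------------------------------------------


def _scalar_objective(c: Centerline3D, criterion: str, ea_mode: str):
    """Signed scalar objective (to minimise) at (beta, gamma), alpha = 0.

    Uses the criterion-only batch kernel: the refinement loop never needs
    the full metric triple, and for mea the collinearity check is
    deferred to the final strict re-evaluation.
    """
    sign = 1.0 if criterion == "msar" else -1.0
    P = c.points.T

    def f(v) -> float:
        b = np.array([float(v[0])])
        g = np.array([float(v[1])])
        return sign * float(_batch_objective(P, b, g, criterion)[0])

    return f


def _refine(f, x0: np.ndarray) -> tuple[np.ndarray, float]:
    res = minimize(f, x0, method="Nelder-Mead", options=_NM_OPTIONS)
    return res.x, res.fun


def optimize_single_axis(
    c: Centerline3D,
    axis: str,
    criterion: str = "msar",
    grid_deg: float = _DEFAULT_GRID_DEG,
    ea_mode: str = "fan_abs",
    refine: bool = True,
) -> OptimizationResult:
    """1D search of the rotation angle about one world axis.

    The X-axis search is flat by construction (the projection is
    X-rotation invariant) and simply returns the primary YOZ plane
    objective at every grid point.
    """
    axis = axis.lower()
    if axis not in ("x", "y", "z"):
        raise ValidationError(f"axis must be 'x', 'y' or 'z', got {axis!r}")
    _check_criterion_feasible(c, criterion)
    if not (grid_deg > 0):
        raise ValidationError("grid resolution must be positive")
    step = np.deg2rad(grid_deg)
    theta = np.arange(0.0, 2 * np.pi, step)
    P = c.points.T

    if axis == "x":
        beta = np.zeros_like(theta)
        gamma = np.zeros_like(theta)
    elif axis == "y":
        beta, gamma = theta, np.zeros_like(theta)
    else:
        beta, gamma = np.zeros_like(theta), theta
    vals = _batch_objective(P, beta, gamma, criterion)

    sign = 1.0 if criterion == "msar" else -1.0
    alphas = theta if axis == "x" else np.zeros_like(theta)
    trace = np.column_stack([alphas, beta, gamma, vals])

    def angles_of(t: float) -> RotationAngles:
        return RotationAngles(
            t if axis == "x" else 0.0,
            t if axis == "y" else 0.0,
            t if axis == "z" else 0.0,
        )

    k = int(np.argmin(sign * vals))
    best_t = float(theta[k])
    f_fast = _scalar_objective(c, criterion, ea_mode)
    if refine and axis != "x":
        if axis == "y":
            f1 = lambda v: f_fast((float(v[0]), 0.0))  # noqa: E731
        else:
            f1 = lambda v: f_fast((0.0, float(v[0])))  # noqa: E731
        xb, fb = _refine(f1, np.array([best_t]))
        if np.isfinite(fb) and fb <= sign * vals[k]:
            best_t = float(xb[0])
    best_angles = angles_of(best_t)
    best_metrics = evaluate_plane(c, best_angles, ea_mode)
    # final strict evaluation (collinearity-aware) must still be defined
    _criterion_value(best_metrics, criterion)
    return OptimizationResult(
        criterion=criterion,
        mode=f"single_axis_{axis}",
        best_angles=best_angles,
        best_metrics=best_metrics,
        trace=trace,
        grid_resolution=step,
    )


def optimize_3d(
    c: Centerline3D,
    criterion: str = "msar",
    grid_deg: float = _DEFAULT_GRID_DEG,
    ea_mode: str = "fan_abs",
    n_restarts: int = 5,
    refine: bool = True,
    ensure_dominance: bool = True,
) -> OptimizationResult:
    """Full two-angle (beta, gamma) search with alpha fixed at 0.

    Coarse grid over beta in [0, pi) x gamma in [0, 2*pi), then
    Nelder-Mead restarts from the ``n_restarts`` best grid cells.  With
    ``ensure_dominance`` the three single-axis optima are also used as
    restart seeds, so the 3D result can never fall below the best
    single-axis result for the same criterion.
    """
    _check_criterion_feasible(c, criterion)
    if not (grid_deg > 0):
        raise ValidationError("grid resolution must be positive")
    step = np.deg2rad(grid_deg)
    betas = np.arange(0.0, np.pi, step)
    gammas = np.arange(0.0, 2 * np.pi, step)
    B, G = np.meshgrid(betas, gammas, indexing="ij")
    bb, gg = B.ravel(), G.ravel()
    P = c.points.T

    # chunk the batch evaluation to bound peak memory on long centerlines
    vals = np.empty(bb.shape[0])
    chunk = max(1, int(4e6 / max(len(c), 1)))
    for i in range(0, bb.shape[0], chunk):
        sl = slice(i, i + chunk)
        vals[sl] = _batch_objective(P, bb[sl], gg[sl], criterion)
    trace = np.column_stack([np.zeros_like(bb), bb, gg, vals])

    sign = 1.0 if criterion == "msar" else -1.0
    signed = sign * vals
    if criterion == "mea" and not np.any(vals > len(c) * COLLINEAR_AREA_FLOOR):
        raise UndefinedObjectiveError(
            "enclosed area (mea) is undefined for this centerline: "
            "every candidate projection is (near-)collinear"
        )
    order = np.argsort(signed)
    seeds = [np.array([bb[k], gg[k]]) for k in order[: max(1, n_restarts)]]

    f2 = _scalar_objective(c, criterion, ea_mode)

    if ensure_dominance:
        for axis in ("y", "z"):
            sax = optimize_single_axis(
                c, axis, criterion, grid_deg, ea_mode, refine=refine
            )
            seeds.append(np.array([sax.best_angles.beta, sax.best_angles.gamma]))
        seeds.append(np.zeros(2))  # the X-axis / primary YOZ plane

    best_x = seeds[0]
    best_f = f2(best_x)
    if refine:
        for x0 in seeds:
            xr, fr = _refine(f2, x0)
            if fr < best_f:
                best_x, best_f = xr, fr
    else:
        for x0 in seeds[1:]:
            f0 = f2(x0)
            if f0 < best_f:
                best_x, best_f = x0, f0

    best_angles = RotationAngles(0.0, float(best_x[0]), float(best_x[1]))
    best_metrics = evaluate_plane(c, best_angles, ea_mode)
    _criterion_value(best_metrics, criterion)
    return OptimizationResult(
        criterion=criterion,
        mode="rotation_3d",
        best_angles=best_angles,
        best_metrics=best_metrics,
        trace=trace,
        grid_resolution=step,
    )


#: fan areas below n * this floor (mm^2) are treated as "no polygon ever
#: closes" when deciding that the mea objective is globally undefined
COLLINEAR_AREA_FLOOR = 1e-9


def compare_criteria(
    c: Centerline3D,
    grid_deg: float = _DEFAULT_GRID_DEG,
    ea_mode: str = "fan_abs",
) -> dict[str, OptimizationResult]:
    """Run the 3D search under each criterion and report side by side.

    By construction the mSAR optimum has the smallest SAR of the three
    and the MCL optimum the largest CL.
    """
    if len(c) < 3:
        raise DegenerateInputError("compare_criteria requires at least 3 points")
    return {
        crit: optimize_3d(c, crit, grid_deg=grid_deg, ea_mode=ea_mode)
        for crit in CRITERIA
    }
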