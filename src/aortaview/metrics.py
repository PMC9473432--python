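"""Plane-quality metrics for a candidate projection plane.

Three scalars grade how well a rotated centerline unfolds on the
reference projection plane (YOZ):

* **CL** — contour length of the projected polyline (mm).  Projection can
  only shorten a polyline, so ``cl_2d <= cl_3d`` always, with equality
  iff the rotated curve lies in a plane of constant x.
* **EA** — enclosed area (mm^2) of the implicitly closed projected curve,
  by fan triangulation from the first vertex with absolute triangle
  areas.  Undefined (None) for collinear projections: a straight segment
  closes no polygon.  The fan-of-absolute-triangles construction
  overestimates the area of non-convex polygons; since every candidate
  plane is graded the same way, the comparison is unaffected.  A signed
  shoelace mode is kept for cross-checking.
* **SAR** — sum of absolute residuals ``sum |x_k - mean(x)|`` (mm) of the
  rotated points: the total L1 deviation of the curve from the plane
  x = mean(x) parallel to the RPP.  Zero iff the rotated curve is
  exactly coplanar with constant x.

``D = cl_3d - cl_2d`` measures how much of the true length a primary
plane projection loses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .centerline import Centerline3D, Projection2D, RotationAngles
from .exceptions import DegenerateInputError, ValidationError
from .geometry import project_to_rpp, rotate_points

__all__ = [
    "PlaneMetrics",
    "contour_length_2d",
    "contour_length_3d",
    "enclosed_area",
    "sar",
    "ppp_difference",
    "evaluate_plane",
    "COLLINEARITY_TOL",
]

#: max point-to-best-fit-line distance (mm) below which a projection is
#: treated as collinear and EA is undefined
COLLINEARITY_TOL = 1e-6


@dataclass(frozen=True)
class PlaneMetrics:
    """The (CL, EA, SAR) triple plus D, grading one candidate plane."""

    cl_2d: float
    cl_3d: float
    ea: float | None
    sar: float

    @property
    def d(self) -> float:
        """Length lost by projection, ``cl_3d - cl_2d`` (mm)."""
        return self.cl_3d - self.cl_2d

    def to_dict(self, angles: RotationAngles | None = None) -> dict:
        out = {}
        if angles is not None:
            out["angles_rad"] = [float(a) for a in angles]
        out.update(
            cl_3d_mm=float(self.cl_3d),
            cl_2d_mm=float(self.cl_2d),
            ea_mm2=None if self.ea is None else float(self.ea),
            sar_mm=float(self.sar),
            d_mm=float(self.d),
        )
        return out


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def contour_length_2d(p: Projection2D) -> float:
    """Projected contour length: sum of consecutive point distances (mm)."""
    if len(p) < 2:
        raise DegenerateInputError("contour length requires at least 2 points")
    return _polyline_length(p.points)


def contour_length_3d(c: Centerline3D) -> float:
    """True 3D contour length of the centerline (mm); rotation invariant."""
    if len(c) < 2:
        raise DegenerateInputError("contour length requires at least 2 points")
    return _polyline_length(c.points)


def is_collinear(p: Projection2D, tol: float = COLLINEARITY_TOL) -> bool:
    """True if every projected point is within ``tol`` mm of one 2D line."""
    q = p.points - p.points.mean(axis=0)
    # direction of best-fit (total least squares) line from the SVD
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    dist = np.abs(q @ vt[-1])
    return bool(dist.max() <= tol)


def enclosed_area(
    p: Projection2D, mode: str = "fan_abs", tol: float = COLLINEARITY_TOL
) -> float | None:
    """Enclosed area (mm^2) of the implicitly closed projected curve.

    Parameters
    ----------
    p : Projection2D
    mode : {"fan_abs", "signed_shoelace"}
        ``fan_abs`` (default): translate so the first vertex is the
        origin, fan-triangulate, and sum *absolute* triangle areas.
        ``signed_shoelace``: absolute value of the signed shoelace sum of
        the closed polygon.  The two agree on convex simple polygons;
        fan_abs dominates otherwise.

    Returns
    -------
    float or None
        None (undefined) when the projected points are collinear within
        ``tol`` — a straight projection encloses nothing.
    """
    if len(p) < 3:
        raise DegenerateInputError("enclosed area requires at least 3 points")
    if is_collinear(p, tol):
        return None
    pts = p.points
    if mode == "fan_abs":
        q = pts - pts[0]
        cross = q[1:-1, 0] * q[2:, 1] - q[2:, 0] * q[1:-1, 1]
        return float(0.5 * np.abs(cross).sum())
    if mode == "signed_shoelace":
        u, v = pts[:, 0], pts[:, 1]
        un, vn = np.roll(u, -1), np.roll(v, -1)
        return float(0.5 * abs(np.sum(u * vn - un * v)))
    raise ValidationError(f"unknown enclosed-area mode {mode!r}")


def sar(c: Centerline3D, center: str = "mean") -> float:
    """Sum of absolute residuals ``sum |x_k - x_center|`` (mm).

    ``center="mean"`` (default) follows the definition with the
    arithmetic mean; ``center="median"`` is available as the L1-optimal
    alternative but is not the default.
    """
    if len(c) < 1:
        raise DegenerateInputError("SAR requires at least 1 point")
    x = c.x
    if center == "mean":
        c0 = x.mean()
    elif center == "median":
        c0 = np.median(x)
    else:
        raise ValidationError(f"unknown SAR center {center!r}")
    return float(np.abs(x - c0).sum())


def ppp_difference(cl_3d: float, cl_2d: float) -> float:
    """D = cl_3d - cl_2d (mm): length lost by a primary plane projection."""
    if cl_3d < 0 or cl_2d < 0:
        raise ValidationError("contour lengths must be non-negative")
    if cl_2d > cl_3d:
        if cl_2d - cl_3d <= 1e-6:
            warnings.warn(
                "cl_2d exceeds cl_3d by rounding-level amount; D is negative",
                stacklevel=2,
            )
        else:
            raise ValidationError(
                f"cl_2d ({cl_2d}) exceeds cl_3d ({cl_3d}) beyond rounding"
            )
    return cl_3d - cl_2d


def evaluate_plane(
    c: Centerline3D,
    angles: RotationAngles = RotationAngles(),
    ea_mode: str = "fan_abs",
) -> PlaneMetrics:
    """Rotate, project onto the RPP, and compute the full metric triple."""
    if len(c) < 2:
        raise DegenerateInputError("plane evaluation requires at least 2 points")
    rotated = rotate_points(c, angles)
    proj = project_to_rpp(rotated)
    ea = enclosed_area(proj, ea_mode) if len(c) >= 3 else None
    return PlaneMetrics(
        cl_2d=contour_length_2d(proj),
        cl_3d=contour_length_3d(c),
        ea=ea,
        sar=sar(rotated),
    )
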