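"""Core containers: ordered 3D centerlines, rotation angles, 2D projections.

A centerline is an ordered polyline through the vessel lumen, in
millimetres, proximal to distal.  Order matters anatomically, but every
metric in :mod:`aortaview.metrics` is invariant under order reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "Centerline3D",
    "RotationAngles",
    "Projection2D",
    "resample_arclength",
    "slice_zone",
]

TWO_PI = 2.0 * np.pi


class RotationAngles(NamedTuple):
    """Euler angles (radians) about the world X, Y, Z axes.

    The rotation is applied in the fixed order X, then Y, then Z
    (see :func:`aortaview.geometry.rotation_matrix`).  Angles are stored
    without range reduction; :meth:`canonical` returns the equivalent
    triple reduced to [0, 2*pi).
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def canonical(self) -> "RotationAngles":
        return RotationAngles(*(float(np.mod(a, TWO_PI)) for a in self))

    def validate(self) -> "RotationAngles":
        if not all(np.isfinite(a) for a in self):
            raise ValidationError(f"rotation angles must be finite, got {self}")
        return self


@dataclass(frozen=True)
class Centerline3D:
    """Ordered 3D point sequence in mm, with optional SVS zone index ranges.

    Parameters
    ----------
    points : (n, 3) array_like
        Ordered coordinates in mm, proximal to distal.
    label : str
        Free-text identifier.
    zone_bounds : mapping, optional
        SVS zone name -> half-open, 0-based ``(start, stop)`` index range.
    """

    points: np.ndarray
    label: str = ""
    zone_bounds: Mapping[str, tuple[int, int]] | None = field(default=None)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(
                f"centerline points must have shape (n, 3), got {pts.shape}"
            )
        if pts.shape[0] < 1:
            raise DegenerateInputError("centerline must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("centerline coordinates must be finite (no NaN/Inf)")
        pts = np.ascontiguousarray(pts)
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        if self.zone_bounds is not None:
            n = pts.shape[0]
            for name, (i0, i1) in dict(self.zone_bounds).items():
                if not (0 <= i0 < i1 <= n):
                    raise ValidationError(
                        f"zone {name!r} range [{i0}, {i1}) invalid for n={n}"
                    )

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length (mm) at each vertex, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def with_points(self, pts: np.ndarray, label: str | None = None) -> "Centerline3D":
        return Centerline3D(
            pts, self.label if label is None else label, self.zone_bounds
        )


@dataclass(frozen=True)
class Projection2D:
    """Ordered 2D projection (u, v) = (y, z) of a rotated centerline, in mm."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(
                f"projection points must have shape (n, 2), got {pts.shape}"
            )
        pts = np.ascontiguousarray(pts)
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def u(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def v(self) -> np.ndarray:
        return self.points[:, 1]


def resample_arclength(c: Centerline3D, spacing: float) -> Centerline3D:
    """Resample a centerline at uniform arc-length spacing (mm).

    Linear interpolation along the polyline; both endpoints are kept
    exactly.  Idempotent (to 1e-9) on polylines already uniform at
    ``spacing``.
    """
    if not (spacing > 0):
        raise ValidationError(f"spacing must be positive, got {spacing}")
    s = c.arc_lengths()
    total = s[-1]
    if total < spacing:
        raise ValidationError(
            f"total length {total:.6g} mm shorter than spacing {spacing:.6g} mm"
        )
    targets = np.arange(0.0, total, spacing)
    # keep the distal endpoint exactly
    if total - targets[-1] < 1e-12 * max(total, 1.0):
        targets[-1] = total
    else:
        targets = np.concatenate([targets, [total]])
    out = np.column_stack([np.interp(targets, s, c.points[:, k]) for k in range(3)])
    out[0] = c.points[0]
    out[-1] = c.points[-1]
    return Centerline3D(out, c.label)


def slice_zone(c: Centerline3D, zone: str) -> Centerline3D:
    """Return the sub-centerline over a stored half-open zone index range."""
    if not c.zone_bounds or zone not in c.zone_bounds:
        raise KeyError(f"zone {zone!r} not present in zone_bounds")
    i0, i1 = c.zone_bounds[zone]
    return Centerline3D(c.points[i0:i1], f"{c.label}[{zone}]" if c.label else zone)
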