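"""Ordered Euler rotations and projection onto the reference plane (YOZ).

The rotated coordinate frame is obtained from the world frame by rotating
about X by alpha, then about Y by beta, then about Z by gamma, composed by
left multiplication: ``R = RotZ(gamma) @ RotY(beta) @ RotX(alpha)``.  Sign
conventions: counterclockwise about X and Z, clockwise about Y are
positive.  The reference projection plane (RPP) is the YOZ plane of the
rotated frame: projecting discards the rotated x coordinate, so a rotation
about X never changes the projection's metrics (x is unchanged and (y, z)
move rigidly in-plane).
"""

from __future__ import annotations

import numpy as np

from .centerline import Centerline3D, Projection2D, RotationAngles

__all__ = [
    "rot_x",
    "rot_y",
    "rot_z",
    "rotation_matrix",
    "rotate_points",
    "project_to_rpp",
    "plane_normal",
]


def rot_x(alpha: float) -> np.ndarray:
    """Rotation about the X axis, counterclockwise positive."""
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(beta: float) -> np.ndarray:
    """Rotation about the Y axis, clockwise positive."""
    c, s = np.cos(beta), np.sin(beta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(gamma: float) -> np.ndarray:
    """Rotation about the Z axis, counterclockwise positive."""
    c, s = np.cos(gamma), np.sin(gamma)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_matrix(angles: RotationAngles) -> np.ndarray:
    """Composed rotation ``RotZ(gamma) @ RotY(beta) @ RotX(alpha)``.

    Orthonormal with determinant +1 (to machine precision).
    """
    a = RotationAngles(*angles).validate()
    return rot_z(a.gamma) @ rot_y(a.beta) @ rot_x(a.alpha)


def rotate_points(c: Centerline3D, angles: RotationAngles) -> Centerline3D:
    """Apply the composed rotation to every point of a centerline.

    Rigid: pairwise distances and total length are preserved.
    """
    R = rotation_matrix(angles)
    return c.with_points(c.points @ R.T)


def project_to_rpp(c: Centerline3D) -> Projection2D:
    """Project onto the reference projection plane: keep (y, z), drop x."""
    return Projection2D(c.points[:, 1:3])


def plane_normal(angles: RotationAngles) -> np.ndarray:
    """Unit normal (world frame) of the projection plane selected by ``angles``.

    The rotated x coordinate of a world point p is ``R[0] @ p``, so the
    first row of R is the viewing direction.  The plane is unoriented:
    the sign is canonicalised so the first component of largest magnitude
    is positive, making antipodal solutions compare equal.
    """
    n = rotation_matrix(angles)[0]
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return n
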