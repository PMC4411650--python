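"""Shared 3D geometry primitives: Euler rotations, planes, ray casting.

Conventions used across the package: right-handed camera frame with +z along
the optical axis into the scene, +x to the right, +y downward (so image
coordinates u/v grow right/down); millimetres for 3D lengths; degrees at
every public interface, radians only inside trigonometric calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Plane",
    "rot_x",
    "rot_y",
    "rot_z",
    "euler_zyx",
    "rigid_about_point",
    "intersect_rays_plane",
]


def rot_x(angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the x axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the y axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the z axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def euler_zyx(theta_deg) -> np.ndarray:
    """Compose Rz(θz)·Ry(θy)·Rx(θx) from a (θx, θy, θz) triple in degrees.

    This is the rotation order used for viewpoint alternation: the x
    rotation is applied to the scene first, then y, then z.
    """
    tx, ty, tz = np.asarray(theta_deg, dtype=float)
    return rot_z(tz) @ rot_y(ty) @ rot_x(tx)


def rigid_about_point(rotation: np.ndarray, center) -> np.ndarray:
    """4×4 homogeneous transform rotating about a fixed 3D point.

    Equivalent to T(center) · R · T(−center): ``center`` is a fixed point of
    the returned map.
    """
    c = np.asarray(center, dtype=float).reshape(3)
    out = np.eye(4)
    out[:3, :3] = rotation
    out[:3, 3] = c - rotation @ c
    return out


@dataclass(frozen=True)
class Plane:
    """An oriented plane with an in-plane coordinate frame.

    ``origin`` is a 3D point on the plane (mm); ``b1`` and ``b2`` are unit,
    mutually orthogonal in-plane basis vectors, so a surface coordinate
    (s, t) maps to the 3D point origin + s·b1 + t·b2.
    """

    origin: np.ndarray
    b1: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        b1 = np.asarray(self.b1, dtype=float).reshape(3)
        b2 = np.asarray(self.b2, dtype=float).reshape(3)
        if not (np.isclose(np.linalg.norm(b1), 1.0) and np.isclose(np.linalg.norm(b2), 1.0)):
            raise ValueError("plane basis vectors must be unit length")
        if not np.isclose(b1 @ b2, 0.0, atol=1e-12):
            raise ValueError("plane basis vectors must be orthogonal")
        object.__setattr__(self, "b1", b1)
        object.__setattr__(self, "b2", b2)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.b1, self.b2)

    def point_at(self, surface_coords) -> np.ndarray:
        """3D points for surface coordinates (..., 2) in mm."""
        st = np.asarray(surface_coords, dtype=float)
        return self.origin + st[..., :1] * self.b1 + st[..., 1:2] * self.b2

    def surface_coords(self, points) -> np.ndarray:
        """Project 3D points (..., 3) onto the in-plane (s, t) frame."""
        d = np.asarray(points, dtype=float) - self.origin
        return np.stack([d @ self.b1, d @ self.b2], axis=-1)

    def transformed(self, matrix: np.ndarray) -> "Plane":
        """Apply a 4×4 rigid transform to the plane and its frame."""
        r, t = matrix[:3, :3], matrix[:3, 3]
        return Plane(r @ self.origin + t, r @ self.b1, r @ self.b2)


def intersect_rays_plane(directions, plane: Plane, origin=None, eps: float = 1e-12):
    """Intersect rays from ``origin`` (default camera center) with a plane.

    Parameters
    ----------
    directions : array (..., 3)
        Ray direction vectors (need not be normalized).
    plane : Plane
    origin : array (3,), optional
        Common ray origin; defaults to the coordinate origin.

    Returns
    -------
    points : array (..., 3)
        Intersection points (NaN where invalid).
    valid : bool array (...)
        True where the ray meets the plane at a positive parameter.
    """
    d = np.asarray(directions, dtype=float)
    o = np.zeros(3) if origin is None else np.asarray(origin, dtype=float).reshape(3)
    n = plane.normal
    denom = d @ n
    numer = (plane.origin - o) @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(np.abs(denom) > eps, numer / denom, np.nan)
    valid = np.isfinite(lam) & (lam > 0)
    pts = o + lam[..., None] * d
    pts = np.where(valid[..., None], pts, np.nan)
    return pts, valid
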