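"""Core viewpoint-alternation pipeline.

Given a frame, a sparse set of pixel ↔ 3D-point correspondences and a
commanded rotation θ = (θx, θy, θz) about a pivot in the scene, the
pipeline synthesizes the frame a virtual camera at the rotated viewpoint
would see:

1. rigidly rotate the 3D points about the pivot (Rz·Ry·Rx order),
2. reproject them through the pinhole model,
3. Delaunay-triangulate the reprojected pixels,
4. for every output pixel inside the mesh, barycentrically interpolate
   the three vertices' *source* pixel positions and copy the source
   color sampled there.

Because only positions are interpolated — never colors across depth
discontinuities — the method degrades gracefully with sparse depth: any
fraction of pixels with a valid 3D point suffices to build the mesh.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay, QhullError

from .camera_model import CameraIntrinsics, project_point, undistort_image
from .geometry import euler_zyx

__all__ = [
    "PivotPose",
    "DepthPointSet",
    "Mesh",
    "WarpResult",
    "transform_points",
    "reproject",
    "build_mesh",
    "render",
    "warp_frame",
]

#: transformed points closer to the camera plane than this are discarded
Z_EPS = 1e-6


@dataclass(frozen=True)
class PivotPose:
    """Rigid transform H from the camera frame to the rotation-center frame.

    A commanded rotation R acts on scene points as H⁻¹·R·H. The common
    case is a pure pivot point c in the camera frame, for which H = T(−c)
    and the composite map is T(c)·R·T(−c), leaving c fixed.
    """

    transform: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.transform, dtype=float)
        if h.shape != (4, 4):
            raise ValueError("pivot transform must be 4x4")
        r = h[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-9
        ):
            raise ValueError("pivot rotation block must be orthonormal with det +1")
        if not np.allclose(h[3], [0, 0, 0, 1]):
            raise ValueError("last row of pivot transform must be (0, 0, 0, 1)")
        object.__setattr__(self, "transform", h)

    @classmethod
    def from_point(cls, center) -> "PivotPose":
        c = np.asarray(center, dtype=float).reshape(3)
        h = np.eye(4)
        h[:3, 3] = -c
        return cls(h)

    def rotation_about(self, theta_deg) -> np.ndarray:
        """4×4 scene transform H⁻¹·Rz(θz)Ry(θy)Rx(θx)·H."""
        r4 = np.eye(4)
        r4[:3, :3] = euler_zyx(theta_deg)
        return np.linalg.inv(self.transform) @ r4 @ self.transform


@dataclass(frozen=True)
class DepthPointSet:
    """Ordered pixel ↔ 3D-point correspondences in the camera frame.

    ``pixels`` are continuous (u, v) positions in the *undistorted* source
    image; ``points`` are the associated 3D positions in mm with z > 0.
    """

    pixels: np.ndarray
    points: np.ndarray
    image_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        px = np.atleast_2d(np.asarray(self.pixels, dtype=float))
        pt = np.atleast_2d(np.asarray(self.points, dtype=float))
        if px.shape[1] != 2 or pt.shape[1] != 3 or px.shape[0] != pt.shape[0]:
            raise ValueError("pixels must be (N, 2) and points (N, 3) with equal N")
        w, h = self.image_size
        if np.any(px[:, 0] < 0) or np.any(px[:, 0] > w - 1) or np.any(
            px[:, 1] < 0
        ) or np.any(px[:, 1] > h - 1):
            raise ValueError("pixels must lie within the source image bounds")
        if np.any(pt[:, 2] <= 0):
            raise ValueError("all 3D points must have z > 0")
        if len(np.unique(px, axis=0)) != len(px):
            raise ValueError("duplicate pixels in depth point set")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "points", pt)
        object.__setattr__(self, "image_size", (int(w), int(h)))

    def __len__(self) -> int:
        return len(self.pixels)

    @classmethod
    def from_csv(cls, path, image_size) -> "DepthPointSet":
        """Read correspondences from a CSV with header u,v,x,y,z."""
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [c.strip().lower() for c in header[:5]] != ["u", "v", "x", "y", "z"]:
                raise ValueError(f"{path}: expected header 'u,v,x,y,z' (line 1)")
            rows = []
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                try:
                    rows.append([float(c) for c in row[:5]])
                except ValueError as exc:
                    raise ValueError(f"{path}: malformed number on line {lineno}") from exc
        if not rows:
            raise ValueError(f"{path}: no data rows")
        arr = np.asarray(rows)
        return cls(pixels=arr[:, :2], points=arr[:, 2:5], image_size=image_size)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["u", "v", "x", "y", "z"])
            for px, pt in zip(self.pixels, self.points):
                writer.writerow([repr(float(c)) for c in (*px, *pt)])


@dataclass(frozen=True)
class Mesh:
    """Delaunay triangulation over a 2D point set.

    Points are lexicographically sorted by (u, v) before triangulation so
    the result is independent of input ordering; ``simplices`` index the
    points as originally supplied.
    """

    points: np.ndarray
    simplices: np.ndarray
    _dt: Delaunay = field(repr=False)
    _order: np.ndarray = field(repr=False)

    def locate(self, query):
        """Find containing triangles and barycentric coordinates.

        Returns (simplex index into ``simplices`` or −1, barycentric
        weights (..., 3) matching each simplex's vertex order).
        """
        q = np.asarray(query, dtype=float)
        idx = self._dt.find_simplex(q)
        inside = idx >= 0
        safe = np.where(inside, idx, 0)
        t = self._dt.transform[safe]
        b = np.einsum("...ij,...j->...i", t[..., :2, :], q - t[..., 2, :])
        bary = np.concatenate([b, 1.0 - b.sum(axis=-1, keepdims=True)], axis=-1)
        return np.where(inside, idx, -1), bary


def transform_points(pts: DepthPointSet, theta_deg, pivot: PivotPose) -> DepthPointSet:
    """Rigidly rotate the 3D points about the pivot; keep pixel associations.

    Points whose transformed depth falls to z ≤ ``Z_EPS`` (at or behind the
    virtual camera) are dropped. Raises if no point survives.
    """
    if len(pts) == 0:
        raise ValueError("empty depth point set")
    m = pivot.rotation_about(theta_deg)
    moved = pts.points @ m[:3, :3].T + m[:3, 3]
    keep = moved[:, 2] > Z_EPS
    if not np.any(keep):
        raise ValueError("all points fell behind the virtual camera")
    return DepthPointSet(
        pixels=pts.pixels[keep], points=moved[keep], image_size=pts.image_size
    )


def reproject(pts: DepthPointSet, cam: CameraIntrinsics):
    """Project transformed 3D points back to the image plane.

    Returns ``(source_pixels, projected_pixels)`` — both continuous (N, 2)
    arrays; the i-th source pixel is associated with the i-th projection.
    """
    return pts.pixels.copy(), project_point(pts.points, cam)


def build_mesh(projected) -> Mesh:
    """Delaunay-triangulate projected pixel positions.

    Delaunay triangulation maximizes minimum angles, giving the
    near-equilateral triangles that barycentric interpolation favors.
    Raises ``ValueError`` for fewer than 3 points or degenerate (collinear)
    geometry.
    """
    pts = np.atleast_2d(np.asarray(projected, dtype=float))
    if len(pts) < 3:
        raise ValueError("need at least 3 points to triangulate")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    try:
        dt = Delaunay(pts[order])
    except QhullError as exc:
        raise ValueError("degenerate point geometry (collinear or coincident)") from exc
    return Mesh(points=pts, simplices=order[dt.simplices], _dt=dt, _order=order)


def _sample_image(image: np.ndarray, pos_uv: np.ndarray, sampling: str) -> np.ndarray:
    order = {"bilinear": 1, "nearest": 0}[sampling]
    coords = [pos_uv[..., 1], pos_uv[..., 0]]
    if image.ndim == 2:
        return map_coordinates(image.astype(float), coords, order=order, mode="nearest")
    return np.stack(
        [map_coordinates(image[..., c].astype(float), coords, order=order, mode="nearest")
         for c in range(image.shape[2])],
        axis=-1,
    )


@dataclass(frozen=True)
class WarpResult:
    """Output of the mesh warp.

    ``source_map`` holds, per output pixel, the interpolated continuous
    source position (u, v), NaN where invalid; ``validity_mask`` is True
    exactly where the pixel fell inside the mesh. ``source_pixels`` are
    the per-vertex source positions, indexed like ``mesh.points``.
    """

    image: np.ndarray
    mesh: Mesh
    source_map: np.ndarray
    validity_mask: np.ndarray
    source_pixels: np.ndarray


def render(
    source_image,
    source_pixels,
    projected_pixels,
    mesh: Mesh,
    out_size: tuple[int, int] | None = None,
    fill=0,
    sampling: str = "bilinear",
) -> WarpResult:
    """Rasterize the virtual view by barycentric interpolation.

    Every output pixel inside a mesh triangle receives the color of the
    source image sampled at the barycentric combination of the triangle
    vertices' source positions; pixels outside the convex hull get the
    fill color and are marked invalid.
    """
    if sampling not in ("bilinear", "nearest"):
        raise ValueError("sampling must be 'bilinear' or 'nearest'")
    img = np.asarray(source_image)
    src = np.asarray(source_pixels, dtype=float)
    w_out, h_out = out_size if out_size is not None else (img.shape[1], img.shape[0])

    uu, vv = np.meshgrid(np.arange(w_out, dtype=float), np.arange(h_out, dtype=float))
    grid = np.stack([uu, vv], axis=-1)
    simplex, bary = mesh.locate(grid.reshape(-1, 2))
    valid = simplex >= 0
    verts = mesh._dt.simplices[np.where(valid, simplex, 0)]  # indices into sorted pts
    src_sorted = src[mesh._order]
    pos = np.einsum("nk,nkj->nj", bary, src_sorted[verts])
    # interpolated source positions stay within the source convex hull but can
    # drift a ULP outside the raster; clamp for sampling
    pos[:, 0] = np.clip(pos[:, 0], 0, img.shape[1] - 1)
    pos[:, 1] = np.clip(pos[:, 1], 0, img.shape[0] - 1)

    values = _sample_image(img, pos, sampling)
    if img.ndim == 2:
        out = np.full((h_out * w_out,), float(np.asarray(fill).ravel()[0]))
        out[valid] = values[valid]
        out = out.reshape(h_out, w_out)
    else:
        nch = img.shape[2]
        fill_vec = np.broadcast_to(np.asarray(fill, dtype=float).ravel(), (nch,)) \
            if np.asarray(fill).size in (1, nch) else np.zeros(nch)
        out = np.tile(fill_vec, (h_out * w_out, 1))
        out[valid] = values[valid]
        out = out.reshape(h_out, w_out, nch)

    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(img.dtype)

    source_map = np.full((h_out * w_out, 2), np.nan)
    source_map[valid] = pos[valid]
    return WarpResult(
        image=out,
        mesh=mesh,
        source_map=source_map.reshape(h_out, w_out, 2),
        validity_mask=valid.reshape(h_out, w_out),
        source_pixels=src,
    )


def _dedup_projected(src, dst, z, z_buffer: bool):
    """Collapse projected positions that coincide; keep the nearer point."""
    key = np.round(dst / 1e-9).astype(np.int64)
    _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    if len(first) == len(dst):
        return np.arange(len(dst))
    keep = []
    for group in range(len(first)):
        members = np.nonzero(inv == group)[0]
        if len(members) == 1 or not z_buffer:
            keep.append(members[0])
        else:
            keep.append(members[np.argmin(z[members])])
    return np.sort(np.asarray(keep))


def warp_frame(
    image,
    pts: DepthPointSet,
    theta_deg,
    pivot: PivotPose,
    cam: CameraIntrinsics,
    *,
    z_buffer: bool = True,
    sampling: str = "bilinear",
    fill=0,
    out_size: tuple[int, int] | None = None,
) -> WarpResult:
    """Full pipeline: undistort → rotate about pivot → reproject → mesh → render.

    Deterministic for fixed inputs. Raises on dimension mismatch, empty
    transformed sets and degenerate mesh geometry.
    """
    img = np.asarray(image)
    if img.shape[0] != cam.height or img.shape[1] != cam.width:
        raise ValueError("image dimensions do not match calibration")
    if len(pts) < 3:
        raise ValueError("need at least 3 depth points to warp")
    src_img = undistort_image(img, cam) if cam.has_distortion else img
    moved = transform_points(pts, theta_deg, pivot)
    src_px, dst_px = reproject(moved, cam)
    keep = _dedup_projected(src_px, dst_px, moved.points[:, 2], z_buffer)
    mesh = build_mesh(dst_px[keep])
    return render(
        src_img, src_px[keep], dst_px[keep], mesh,
        out_size=out_size, fill=fill, sampling=sampling,
    )
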