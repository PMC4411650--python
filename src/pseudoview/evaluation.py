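"""Rendering-fidelity evaluation against the closed-form planar oracle.

For a planar scene the whole pipeline — back-projection onto the plane,
rigid pivot rotation, reprojection — composes to an exact 3×3 homography
between the source and virtual images. That map needs no meshing or
interpolation, so it serves as an independent ground truth for the mesh
warp. Rendering error is reported two ways:

* image-based: intensity-weighted centroid of each dot landmark in the
  warped raster, compared with the homography-mapped position, converted
  to mm of displacement on the phantom surface. This is the system
  figure of merit.
* geometric: the warp's mesh-induced piecewise-affine map evaluated at
  the landmark, compared with the homography. This isolates the
  interpolation error of the sparse mesh from rasterization and
  localization noise, and is the quantity expected to shrink
  monotonically as the depth grid is refined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera_model import CameraIntrinsics, project_point
from .geometry import Plane, euler_zyx, intersect_rays_plane, rigid_about_point
from .synthetic_scene import SceneSetup, dot_landmarks, render_phantom_view, sample_depth_grid, sheet_plane
from .warp_engine import PivotPose, WarpResult, warp_frame

__all__ = [
    "PlanarMap",
    "ErrorReport",
    "homography_oracle",
    "virtual_plane",
    "backproject_to_plane",
    "locate_landmark",
    "mesh_forward_map",
    "map_error_field",
    "rendering_error",
    "sweep_angles",
]


@dataclass(frozen=True)
class PlanarMap:
    """Homography mapping source pixels to virtual-view pixels."""

    matrix: np.ndarray  # 3x3

    def __call__(self, pixels) -> np.ndarray:
        px = np.asarray(pixels, dtype=float)
        h = np.concatenate([px, np.ones(px.shape[:-1] + (1,))], axis=-1)
        out = h @ self.matrix.T
        return out[..., :2] / out[..., 2:3]


def homography_oracle(plane: Plane, cam: CameraIntrinsics, theta_deg, pivot: PivotPose) -> PlanarMap:
    """Exact source-pixel → virtual-pixel map for a planar scene.

    Composes K·[b1 b2 M] for the source view with the pivot-rotated frame
    for the virtual view. Raises if the plane passes through the camera
    center (the source homography would be singular).
    """
    k = cam.matrix
    h1 = k @ np.column_stack([plane.b1, plane.b2, plane.origin])
    if abs(np.linalg.det(h1)) < 1e-9 * abs(np.linalg.det(k)):
        raise ValueError("degenerate plane: passes through the camera center")
    m = pivot.rotation_about(theta_deg)
    vp = plane.transformed(m)
    h2 = k @ np.column_stack([vp.b1, vp.b2, vp.origin])
    return PlanarMap(matrix=h2 @ np.linalg.inv(h1))


def virtual_plane(plane: Plane, theta_deg, pivot: PivotPose) -> Plane:
    """The scene plane after the pivot rotation (as seen by the camera)."""
    return plane.transformed(pivot.rotation_about(theta_deg))


def backproject_to_plane(pixels, plane: Plane, cam: CameraIntrinsics) -> np.ndarray:
    """Cast pixel rays onto a plane; returns 3D points (..., 3), mm."""
    px = np.asarray(pixels, dtype=float)
    dirs = np.stack(
        [(px[..., 0] - cam.u0) / cam.fx, (px[..., 1] - cam.v0) / cam.fy, np.ones(px.shape[:-1])],
        axis=-1,
    )
    pts, valid = intersect_rays_plane(dirs, plane)
    if not np.all(valid):
        raise ValueError("pixel ray does not meet the plane in front of the camera")
    return pts


def locate_landmark(image, approx_px, half_window, background: float, foreground: float):
    """Intensity-weighted centroid of a dark landmark near a predicted spot.

    ``half_window`` is the (u, v) half-extent in px of the search window.
    Every pixel is weighted by its darkness relative to the background,
    including the antialiased rim, which carries most of the sub-pixel
    information for small foreshortened dots; the weighting is symmetric
    for centrally symmetric spots, so the centroid is unbiased.

    Returns (centroid (2,), ok flag).
    """
    img = np.asarray(image, dtype=float)
    hu, hv = (int(np.ceil(h)) for h in half_window)
    cu, cv = (int(round(c)) for c in np.asarray(approx_px, dtype=float))
    u0, u1 = cu - hu, cu + hu + 1
    v0, v1 = cv - hv, cv + hv + 1
    if u0 < 0 or v0 < 0 or u1 > img.shape[1] or v1 > img.shape[0]:
        return np.full(2, np.nan), False
    patch = img[v0:v1, u0:u1]
    w = np.clip((background - patch) / (background - foreground), 0.0, 1.0)
    mass = w.sum()
    if mass <= 1e-9:
        return np.full(2, np.nan), False
    uu, vv = np.meshgrid(np.arange(u0, u1, dtype=float), np.arange(v0, v1, dtype=float))
    return np.array([(w * uu).sum() / mass, (w * vv).sum() / mass]), True


def mesh_forward_map(warp: WarpResult, query_src_px) -> np.ndarray:
    """Evaluate the warp's piecewise-affine source→virtual map at query points.

    The mesh triangles live in virtual-view coordinates; the same vertex
    triples, taken at their source positions, triangulate the source
    image. Each query is located in that source triangulation by
    barycentric coordinates and pushed through to the virtual view.
    Returns NaN for queries outside every triangle.
    """
    src = np.asarray(warp.source_pixels, dtype=float)
    q = np.atleast_2d(np.asarray(query_src_px, dtype=float))
    tris = warp.mesh.simplices
    a, b, c = (src[tris[:, i]] for i in range(3))  # (m, 2) each
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    ok_tri = np.abs(det) > 1e-12
    out = np.full((len(q), 2), np.nan)
    dst = warp.mesh.points
    for j, p in enumerate(q):
        pa_u, pa_v = p[0] - a[:, 0], p[1] - a[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            w1 = ((c[:, 1] - a[:, 1]) * pa_u - (c[:, 0] - a[:, 0]) * pa_v) / det
            w2 = (-(b[:, 1] - a[:, 1]) * pa_u + (b[:, 0] - a[:, 0]) * pa_v) / det
        w0 = 1.0 - w1 - w2
        inside = ok_tri & (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        hits = np.nonzero(inside)[0]
        if len(hits) == 0:
            continue
        k = hits[0]  # deterministic: lowest triangle index wins boundary ties
        out[j] = w0[k] * dst[tris[k, 0]] + w1[k] * dst[tris[k, 1]] + w2[k] * dst[tris[k, 2]]
    return out


def map_error_field(warp: WarpResult, oracle_map: PlanarMap) -> np.ndarray:
    """Dense per-output-pixel geometric error of the warp map, in px.

    For every valid output pixel p the warp recorded the interpolated
    source position s(p); if the warp were exact, the homography would
    map s(p) back onto p. The returned field is |oracle(s(p)) − p|, NaN
    outside the valid region. Its maximum is the natural convergence
    measure as the depth grid is refined.
    """
    h, w = warp.validity_mask.shape
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    out = np.full((h, w), np.nan)
    m = warp.validity_mask & np.isfinite(warp.source_map[..., 0])
    mapped = oracle_map(warp.source_map[m])
    out[m] = np.hypot(mapped[:, 0] - uu[m], mapped[:, 1] - vv[m])
    return out


@dataclass(frozen=True)
class ErrorReport:
    """Per-landmark rendering errors at one viewpoint angle.

    ``error_mm`` is the on-surface displacement between the measured
    landmark position in the warped image and the ground-truth reference
    position (``reference_px``); ``error_px`` the same in image pixels;
    ``geom_error_px`` the mesh-map-vs-homography geometric error. Landmarks that could not be
    measured (outside the valid warp region) carry NaN and are excluded
    from summaries but flagged in ``valid``.
    """

    theta: np.ndarray
    landmarks_px: np.ndarray
    oracle_px: np.ndarray
    reference_px: np.ndarray
    measured_px: np.ndarray
    mesh_px: np.ndarray
    error_px: np.ndarray
    error_mm: np.ndarray
    geom_error_px: np.ndarray
    valid: np.ndarray

    def _summary(self, values: np.ndarray):
        v = values[self.valid]
        if len(v) == 0:
            return float("nan"), float("nan"), float("nan")
        return float(np.max(v)), float(np.mean(v)), float(np.median(v))

    @property
    def max_mm(self) -> float:
        return self._summary(self.error_mm)[0]

    @property
    def mean_mm(self) -> float:
        return self._summary(self.error_mm)[1]

    @property
    def median_mm(self) -> float:
        return self._summary(self.error_mm)[2]

    @property
    def max_px(self) -> float:
        return self._summary(self.error_px)[0]

    @property
    def geom_max_px(self) -> float:
        return self._summary(self.geom_error_px)[0]

    def to_dict(self) -> dict:
        return {
            "theta": list(map(float, self.theta)),
            "n_landmarks": int(len(self.landmarks_px)),
            "n_valid": int(self.valid.sum()),
            "max_mm": self.max_mm,
            "mean_mm": self.mean_mm,
            "median_mm": self.median_mm,
            "max_px": self.max_px,
            "geom_max_px": self.geom_max_px,
        }


def _landmark_windows(setup: SceneSetup, theta_deg, margin_px: float = 2.0):
    """Per-landmark (u, v) search half-extents from the projected dot size."""
    cam, pose, phantom = setup
    plane = sheet_plane(pose)
    m = rigid_about_point(euler_zyx(theta_deg), pose.pivot)
    vp = plane.transformed(m)
    r = phantom.dot_radius
    centers = phantom.dot_xy
    offsets = np.array([[r, 0.0], [-r, 0.0], [0.0, r], [0.0, -r]])
    rim = centers[:, None, :] + offsets[None, :, :]  # (n, 4, 2)
    rim_px = project_point(vp.point_at(rim), cam)
    ctr_px = project_point(vp.point_at(centers), cam)
    half = 1.3 * np.max(np.abs(rim_px - ctr_px[:, None, :]), axis=1) + margin_px
    return ctr_px, half


def rendering_error(
    warp: WarpResult,
    oracle_map: PlanarMap,
    setup: SceneSetup,
    theta_deg,
    reference_image=None,
) -> ErrorReport:
    """Measure landmark rendering error of one warped frame.

    Each dot landmark is localized in the warped image by its
    intensity-weighted centroid inside an adaptive window seeded at the
    homography-predicted position. The reference position is, by default,
    the same centroid measured in ``reference_image`` — the analytic
    ground-truth render from the virtual viewpoint — so the perspective
    offset between a foreshortened dot's centroid and its projected
    center, common to both images, cancels and the metric isolates the
    warp's own error. Without a reference image the homography-predicted
    center itself is used. The displacement is reported in px and, via
    back-projection onto the rotated phantom plane, in mm on the surface.
    Landmarks outside the valid warp region are flagged, not silently
    dropped.
    """
    cam, pose, phantom = setup
    theta = np.asarray(theta_deg, dtype=float).reshape(3)
    _, src_px = dot_landmarks(setup)
    oracle_px = oracle_map(src_px)
    ctr_px, half = _landmark_windows(setup, theta)

    n = len(src_px)
    measured = np.full((n, 2), np.nan)
    reference = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        u, v = int(round(oracle_px[i, 0])), int(round(oracle_px[i, 1]))
        inside = (
            0 <= u < warp.validity_mask.shape[1]
            and 0 <= v < warp.validity_mask.shape[0]
            and warp.validity_mask[v, u]
        )
        if not inside:
            continue
        measured[i], ok_m = locate_landmark(
            warp.image, oracle_px[i], half[i], phantom.background, phantom.foreground
        )
        if reference_image is not None:
            reference[i], ok_r = locate_landmark(
                reference_image, oracle_px[i], half[i], phantom.background, phantom.foreground
            )
        else:
            reference[i], ok_r = oracle_px[i], True
        valid[i] = ok_m and ok_r

    error_px = np.linalg.norm(measured - reference, axis=1)
    vp = virtual_plane(sheet_plane(pose), theta, pose.pivot_pose)
    error_mm = np.full(n, np.nan)
    if np.any(valid):
        p_meas = backproject_to_plane(measured[valid], vp, cam)
        p_ref = backproject_to_plane(reference[valid], vp, cam)
        error_mm[valid] = np.linalg.norm(p_meas - p_ref, axis=1)

    mesh_px = mesh_forward_map(warp, src_px)
    geom_error_px = np.linalg.norm(mesh_px - oracle_px, axis=1)

    return ErrorReport(
        theta=theta,
        landmarks_px=src_px,
        oracle_px=oracle_px,
        reference_px=reference,
        measured_px=measured,
        mesh_px=mesh_px,
        error_px=error_px,
        error_mm=error_mm,
        geom_error_px=np.where(np.isfinite(geom_error_px), geom_error_px, np.nan),
        valid=valid,
    )


def sweep_angles(setup: SceneSetup, pitch: float, theta_list, **warp_kwargs) -> list[ErrorReport]:
    """Warp the base view over a list of angles and report errors per angle.

    ``theta_list`` entries may be scalars (interpreted as θx) or full
    (θx, θy, θz) triples. Deterministic for fixed inputs.
    """
    cam, pose, _ = setup
    base = render_phantom_view(setup, (0.0, 0.0, 0.0))
    grid = sample_depth_grid(setup, pitch)
    plane = sheet_plane(pose)
    reports = []
    for th in theta_list:
        theta = np.asarray(th, dtype=float)
        if theta.ndim == 0:
            theta = np.array([float(theta), 0.0, 0.0])
        warp = warp_frame(base, grid, theta, pose.pivot_pose, cam, **warp_kwargs)
        omap = homography_oracle(plane, cam, theta, pose.pivot_pose)
        reference = render_phantom_view(setup, theta)
        reports.append(rendering_error(warp, omap, setup, theta, reference_image=reference))
    return reports
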