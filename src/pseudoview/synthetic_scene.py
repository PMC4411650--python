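"""Synthetic planar-phantom fixtures with known ground truth.

Emulates the bench configuration used to exercise viewpoint alternation:
a flat rubber training sheet printed with a cut line and aiming dots,
imaged by a camera whose optical axis meets the sheet at a grazing 20°
elevation from 117 mm away — the horizontal view typical of suturing deep
in the abdominal cavity. The rotation pivot sits at the sheet center,
120 mm along the optical axis.

Because the scene is a known plane, every quantity the warp produces has
a closed-form reference: the ground-truth renderer draws the phantom
analytically (ray–plane intersection, supersampled), with no meshing or
interpolation anywhere, and the depth grid carries exact pixel ↔ 3D
correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .camera_model import CameraIntrinsics, project_point
from .geometry import Plane, intersect_rays_plane, rigid_about_point, euler_zyx
from .warp_engine import DepthPointSet, PivotPose

__all__ = [
    "PhantomSpec",
    "ScenePose",
    "SceneSetup",
    "default_phantom",
    "make_default_setup",
    "sheet_plane",
    "render_phantom_view",
    "sample_depth_grid",
    "dot_landmarks",
    "make_input_trace",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Printed pattern on the flat training sheet (all lengths in mm).

    Surface coordinates: s along the sheet width (lateral), t along the
    sheet height (toward/away from the camera), origin at the center.
    """

    width: float = 80.0
    height: float = 60.0
    dot_xy: np.ndarray = field(default_factory=lambda: _default_dots())
    dot_radius: float = 1.5
    segments: np.ndarray = field(default_factory=lambda: np.array([[[-15.0, 0.0], [15.0, 0.0]]]))
    line_halfwidth: float = 0.5
    background: int = 255
    foreground: int = 0

    def __post_init__(self) -> None:
        dots = np.atleast_2d(np.asarray(self.dot_xy, dtype=float))
        if self.dot_radius <= 0:
            raise ValueError("dot radius must be positive")
        if np.any(np.abs(dots[:, 0]) > self.width / 2) or np.any(np.abs(dots[:, 1]) > self.height / 2):
            raise ValueError("dots must lie on the sheet")
        object.__setattr__(self, "dot_xy", dots)
        object.__setattr__(self, "segments", np.asarray(self.segments, dtype=float))


def _default_dots(pitch: float = 5.0, n_pairs: int = 6, offset: float = 5.0) -> np.ndarray:
    """Six aiming-dot pairs flanking the central cut line at 5 mm pitch."""
    s = (np.arange(n_pairs) - (n_pairs - 1) / 2) * pitch
    upper = np.stack([s, np.full(n_pairs, -offset)], axis=1)
    lower = np.stack([s, np.full(n_pairs, offset)], axis=1)
    return np.concatenate([upper, lower])


def default_phantom() -> PhantomSpec:
    return PhantomSpec()


@dataclass(frozen=True)
class ScenePose:
    """Camera-to-sheet geometry.

    elevation_deg is the angle between the optical axis and the sheet
    surface (20° ≈ near-horizontal view); standoff is the distance from
    the camera center to the sheet center along the optical axis; the
    pivot is the rotation center for viewpoint alternation.
    """

    elevation_deg: float = 20.0
    standoff: float = 117.0
    pivot: tuple[float, float, float] = (0.0, 0.0, 120.0)

    def __post_init__(self) -> None:
        if not (0 < self.elevation_deg < 90):
            raise ValueError("elevation must be in (0, 90) degrees")
        if self.standoff <= 0:
            raise ValueError("standoff must be positive")

    @property
    def pivot_pose(self) -> PivotPose:
        return PivotPose.from_point(self.pivot)


class SceneSetup(NamedTuple):
    cam: CameraIntrinsics
    pose: ScenePose
    phantom: PhantomSpec


def make_default_setup() -> SceneSetup:
    """The default bench configuration: 20° elevation, 117 mm standoff,
    pivot at (0, 0, 120) mm, 640×480 distortion-free camera with
    fx = fy = 800 px."""
    cam = CameraIntrinsics(fx=800.0, fy=800.0, u0=320.0, v0=240.0, width=640, height=480)
    return SceneSetup(cam=cam, pose=ScenePose(), phantom=default_phantom())


def sheet_plane(pose: ScenePose) -> Plane:
    """The sheet plane in the camera frame.

    The sheet center lies on the optical axis at the standoff distance;
    the in-plane t axis recedes from the camera, tilted so the optical
    axis meets the surface at the configured elevation. The receding
    direction points toward −y (upward in the image), matching a camera
    looking slightly down onto the sheet.
    """
    e = np.deg2rad(pose.elevation_deg)
    origin = np.array([0.0, 0.0, pose.standoff])
    b1 = np.array([1.0, 0.0, 0.0])
    b2 = np.array([0.0, -np.sin(e), np.cos(e)])
    return Plane(origin, b1, b2)


def _phantom_mask(phantom: PhantomSpec, st: np.ndarray) -> np.ndarray:
    """Boolean foreground mask for surface coordinates (..., 2)."""
    s, t = st[..., 0], st[..., 1]
    on_sheet = (np.abs(s) <= phantom.width / 2) & (np.abs(t) <= phantom.height / 2)
    fg = np.zeros(st.shape[:-1], dtype=bool)
    for cx, cy in phantom.dot_xy:
        fg |= (s - cx) ** 2 + (t - cy) ** 2 <= phantom.dot_radius**2
    for (a, b) in phantom.segments:
        ab = b - a
        ln2 = ab @ ab
        ap_s, ap_t = s - a[0], t - a[1]
        lam = np.clip((ap_s * ab[0] + ap_t * ab[1]) / ln2, 0.0, 1.0)
        d2 = (ap_s - lam * ab[0]) ** 2 + (ap_t - lam * ab[1]) ** 2
        fg |= d2 <= phantom.line_halfwidth**2
    return fg & on_sheet


def render_phantom_view(setup: SceneSetup, theta_deg=(0.0, 0.0, 0.0), supersample: int = 2) -> np.ndarray:
    """Ground-truth render of the phantom from the rotated viewpoint.

    Exact pinhole render via per-pixel ray–plane intersection against the
    pivot-rotated sheet plane — no meshing, no interpolation. Each pixel
    averages ``supersample``² sub-samples (default 2×2 = 4 samples) so dot
    centroids are recoverable to better than 0.1 px. Deterministic.

    Raises if the rotated sheet reaches or passes the camera center, or
    sits edge-on to it.
    """
    cam, pose, phantom = setup
    plane = sheet_plane(pose)
    m = rigid_about_point(euler_zyx(theta_deg), pose.pivot)
    vplane = plane.transformed(m)

    # camera must stay on the front (+normal) side of the sheet; the signed
    # distance hits zero when the view turns edge-on and flips beyond it
    if vplane.normal @ (np.zeros(3) - vplane.origin) < 1e-6 * pose.standoff:
        raise ValueError("camera is on or behind the phantom plane (edge-on view)")
    corners = vplane.point_at(
        np.array([[-phantom.width / 2, -phantom.height / 2], [phantom.width / 2, -phantom.height / 2],
                  [-phantom.width / 2, phantom.height / 2], [phantom.width / 2, phantom.height / 2]])
    )
    if np.any(corners[:, 2] <= 0):
        raise ValueError("phantom sheet reaches behind the camera at this angle")

    n = int(supersample)
    offs = (np.arange(n) + 0.5) / n - 0.5
    ou, ov = np.meshgrid(offs, offs)
    sub = np.stack([ou.ravel(), ov.ravel()], axis=1)  # (n*n, 2)

    uu, vv = np.meshgrid(np.arange(cam.width, dtype=float), np.arange(cam.height, dtype=float))
    acc = np.zeros((cam.height, cam.width))
    for du, dv in sub:
        dirs = np.stack(
            [(uu + du - cam.u0) / cam.fx, (vv + dv - cam.v0) / cam.fy, np.ones_like(uu)],
            axis=-1,
        )
        pts, valid = intersect_rays_plane(dirs, vplane)
        st = vplane.surface_coords(np.where(valid[..., None], pts, 0.0))
        fg = _phantom_mask(phantom, st) & valid
        acc += np.where(fg, phantom.foreground, phantom.background)
    img = acc / len(sub)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def sample_depth_grid(setup: SceneSetup, pitch: float = 5.0) -> DepthPointSet:
    """Uniform grid of exact pixel ↔ 3D correspondences on the sheet.

    Grid points are spaced ``pitch`` mm apart in sheet coordinates,
    spanning the full sheet inclusive of both edges, and filtered to the
    camera's field of view at θ = 0. This stands in for 3D shape
    acquisition with a known-perfect depth source.
    """
    cam, pose, phantom = setup
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    plane = sheet_plane(pose)
    s = np.arange(-phantom.width / 2, phantom.width / 2 + pitch / 2, pitch)
    t = np.arange(-phantom.height / 2, phantom.height / 2 + pitch / 2, pitch)
    ss, tt = np.meshgrid(s, t)
    st = np.stack([ss.ravel(), tt.ravel()], axis=1)
    pts3 = plane.point_at(st)
    infront = pts3[:, 2] > 0
    pts3 = pts3[infront]
    px = project_point(pts3, cam)
    visible = (
        (px[:, 0] >= 0) & (px[:, 0] <= cam.width - 1) & (px[:, 1] >= 0) & (px[:, 1] <= cam.height - 1)
    )
    if not np.any(visible):
        raise ValueError("no grid point falls inside the camera field of view")
    return DepthPointSet(pixels=px[visible], points=pts3[visible], image_size=(cam.width, cam.height))


def dot_landmarks(setup: SceneSetup):
    """Exact 3D dot centers and their θ = 0 source-pixel projections."""
    cam, pose, phantom = setup
    plane = sheet_plane(pose)
    centers3 = plane.point_at(phantom.dot_xy)
    return centers3, project_point(centers3, cam)


_PROFILES = ("neutral", "hold", "pulse", "continuous")


def make_input_trace(
    profile: str,
    duration: float = 10.0,
    update_rate: float = 16.0,
    seed: int = 0,
    n_neutral: int = 10,
) -> np.ndarray:
    """Synthesize a deterministic 2-axis input trace.

    Returns an array (n, 3) with columns (t, q1, q2). Every profile
    starts with ``n_neutral`` frames at rest for neutral calibration.

    Profiles: ``neutral`` stays at rest; ``hold`` deflects fully, then
    releases and holds the reached angle; ``pulse`` deflects, holds,
    deflects in reverse for the same time (returning θ to zero), then
    rests; ``continuous`` wanders smoothly (seeded noise).
    """
    if duration <= 0 or update_rate <= 0:
        raise ValueError("duration and update_rate must be positive")
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {_PROFILES}")
    n = max(int(round(duration * update_rate)), n_neutral + 1)
    t = np.arange(n) / update_rate
    q = np.zeros((n, 2))
    body = n - n_neutral
    if profile == "hold":
        q[n_neutral : n_neutral + max(body // 4, 1), 0] = 1.0
    elif profile == "pulse":
        k = max(body // 6, 1)
        q[n_neutral : n_neutral + k, 0] = 1.0
        q[n_neutral + 2 * k : n_neutral + 3 * k, 0] = -1.0
    elif profile == "continuous":
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal((body, 2))
        smooth = np.empty_like(raw)
        acc = np.zeros(2)
        for i in range(body):  # first-order low-pass for joystick-like motion
            acc = 0.92 * acc + 0.25 * raw[i]
            smooth[i] = acc
        q[n_neutral:] = np.clip(smooth, -1.0, 1.0)
    return np.column_stack([t, q])
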