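"""Pivot rotation, reprojection, Delaunay meshing and barycentric rendering."""

import numpy as np
import pytest

from pseudoview.camera_model import CameraIntrinsics, project_point
from pseudoview.geometry import euler_zyx
from pseudoview.warp_engine import (
    DepthPointSet,
    PivotPose,
    build_mesh,
    render,
    reproject,
    transform_points,
    warp_frame,
)

CAM = CameraIntrinsics(fx=800.0, fy=800.0, u0=320.0, v0=240.0)
PIVOT = PivotPose.from_point((0.0, 0.0, 120.0))


def random_point_set(rng, n=40):
    pts = rng.uniform([-30, -25, 100], [30, 25, 160], size=(n, 3))
    return DepthPointSet(pixels=project_point(pts, CAM), points=pts, image_size=(640, 480))


def brute_force_circumcircle_ok(points, simplices, tol=1e-9):
    """Empty-circumcircle predicate via the incircle determinant."""
    for tri in simplices:
        a, b, c = points[tri]
        ab, ac = b - a, c - a
        if ab[0] * ac[1] - ab[1] * ac[0] < 0:  # orient counter-clockwise
            b, c = c, b
        others = np.delete(np.arange(len(points)), tri)
        for idx in others:
            d = points[idx]
            m = np.array([
                [a[0] - d[0], a[1] - d[1], (a[0] - d[0]) ** 2 + (a[1] - d[1]) ** 2],
                [b[0] - d[0], b[1] - d[1], (b[0] - d[0]) ** 2 + (b[1] - d[1]) ** 2],
                [c[0] - d[0], c[1] - d[1], (c[0] - d[0]) ** 2 + (c[1] - d[1]) ** 2],
            ])
            scale = max(np.abs(m[:, :2]).max() ** 4, 1.0)
            if np.linalg.det(m) > tol * scale:  # strictly inside
                return False
    return True


class TestDepthPointSet:
    def test_validation(self):
        with pytest.raises(ValueError):
            DepthPointSet(pixels=[[0, 0], [0, 0]], points=[[0, 0, 10], [1, 1, 10]],
                          image_size=(640, 480))
        with pytest.raises(ValueError):
            DepthPointSet(pixels=[[700, 0]], points=[[0, 0, 10]], image_size=(640, 480))
        with pytest.raises(ValueError):
            DepthPointSet(pixels=[[10, 10]], points=[[0, 0, -1]], image_size=(640, 480))

    def test_csv_round_trip(self, tmp_path, rng):
        pts = random_point_set(rng, 25)
        pts.to_csv(tmp_path / "pts.csv")
        back = DepthPointSet.from_csv(tmp_path / "pts.csv", image_size=(640, 480))
        np.testing.assert_array_equal(back.pixels, pts.pixels)
        np.testing.assert_array_equal(back.points, pts.points)

    def test_malformed_csv_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("u,v,x,y,z\n1,2,3,4,5\n1,2,three,4,5\n")
        with pytest.raises(ValueError, match="line 3"):
            DepthPointSet.from_csv(path, image_size=(640, 480))


class TestTransformPoints:
    def test_zero_rotation_is_identity(self, rng):
        pts = random_point_set(rng)
        out = transform_points(pts, (0.0, 0.0, 0.0), PIVOT)
        np.testing.assert_array_equal(out.points, pts.points)
        np.testing.assert_array_equal(out.pixels, pts.pixels)

    @pytest.mark.parametrize("theta", [(90, 0, 0), (0, 45, 0), (10, 20, 30)])
    def test_pivot_is_fixed_point(self, theta):
        pts = DepthPointSet(pixels=[[320, 240], [100, 100], [500, 400]],
                            points=[[0, 0, 120], [-10, -15, 110], [20, 18, 130]],
                            image_size=(640, 480))
        out = transform_points(pts, theta, PIVOT)
        i = np.argmin(np.linalg.norm(out.pixels - [320, 240], axis=1))
        np.testing.assert_allclose(out.points[i], [0, 0, 120], atol=1e-9)

    def test_hand_computed_x_rotation(self):
        pts = DepthPointSet(pixels=[[320, 240], [0, 0]],
                            points=[[0, 0, 110], [-40, -30, 100]], image_size=(640, 480))
        out = transform_points(pts, (90.0, 0.0, 0.0), PIVOT)
        # Rx(90°) about (0,0,120): (0,0,110) has offset (0,0,-10) -> (0,10,0)
        np.testing.assert_allclose(out.points[0], [0.0, 10.0, 120.0], atol=1e-9)

    def test_rigidity_and_inverse_composition(self, rng):
        pts = random_point_set(rng, 60)
        theta = (17.0, -8.0, 25.0)
        moved = transform_points(pts, theta, PIVOT)
        d0 = np.linalg.norm(pts.points[:, None] - pts.points[None], axis=-1)
        d1 = np.linalg.norm(moved.points[:, None] - moved.points[None], axis=-1)
        assert np.max(np.abs(d0 - d1)) < 1e-9
        # undo with the inverse rotation applied through a pivot whose
        # composite transform is the matrix inverse
        r_inv = np.linalg.inv(PIVOT.rotation_about(theta))
        back = moved.points @ r_inv[:3, :3].T + r_inv[:3, 3]
        assert np.max(np.abs(back - pts.points)) < 1e-9

    def test_points_behind_camera_dropped_and_empty_raises(self):
        pts = DepthPointSet(pixels=[[320, 240]], points=[[0, 0, 240]], image_size=(640, 480))
        # Rx(180°) about z=120 sends z=240 to z=0 -> dropped -> empty set
        with pytest.raises(ValueError):
            transform_points(pts, (180.0, 0.0, 0.0), PIVOT)


class TestReproject:
    def test_identity_round_trip(self, rng):
        pts = random_point_set(rng)
        src, dst = reproject(transform_points(pts, (0, 0, 0), PIVOT), CAM)
        np.testing.assert_allclose(dst, src, atol=1e-6)

    def test_on_axis_point_hits_principal_point(self):
        pts = DepthPointSet(pixels=[[320, 240], [10, 10], [600, 400]],
                            points=[[0, 0, 100], [-38.75, -28.75, 100], [35, 20, 100]],
                            image_size=(640, 480))
        _, dst = reproject(pts, CAM)
        np.testing.assert_allclose(dst[0], [320.0, 240.0], atol=1e-12)


class TestBuildMesh:
    def test_three_points_single_triangle(self):
        mesh = build_mesh([[0, 0], [10, 0], [0, 10]])
        assert mesh.simplices.shape == (1, 3)

    def test_unit_square_two_triangles_with_empty_circumcircles(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        mesh = build_mesh(pts)
        assert mesh.simplices.shape == (2, 3)
        shared = set(mesh.simplices[0]) & set(mesh.simplices[1])
        assert len(shared) == 2  # one shared diagonal
        assert brute_force_circumcircle_ok(pts, mesh.simplices)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_mesh([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            build_mesh([[i, 2.0 * i] for i in range(5)])

    def test_ordering_invariance(self, rng):
        pts = rng.uniform(0, 100, size=(30, 2))
        perm = rng.permutation(30)
        m1 = build_mesh(pts)
        m2 = build_mesh(pts[perm])
        tri1 = {frozenset(t) for t in m1.simplices}
        tri2 = {frozenset(perm[t]) for t in m2.simplices}
        assert tri1 == tri2


class TestRender:
    def test_identity_warp_reproduces_source(self, rng):
        img = rng.integers(0, 256, size=(60, 80), dtype=np.uint8)
        uu, vv = np.meshgrid(np.arange(0, 80, 4, dtype=float), np.arange(0, 60, 4, dtype=float))
        px = np.stack([uu.ravel(), vv.ravel()], axis=1)
        mesh = build_mesh(px)
        out = render(img, px, px, mesh, out_size=(80, 60))
        diff = np.abs(out.image.astype(int) - img.astype(int))[out.validity_mask]
        assert diff.max() <= 1
        assert (diff == 0).mean() > 0.999

    def test_affine_field_reproduced_exactly(self):
        """Barycentric interpolation of positions + bilinear sampling is exact
        for an affine intensity field (both are affine-preserving)."""
        a, b, c = 0.37, -0.21, 40.0
        uu, vv = np.meshgrid(np.arange(80, dtype=float), np.arange(60, dtype=float))
        img = a * uu + b * vv + c
        gu, gv = np.meshgrid(np.arange(0, 80, 7, dtype=float), np.arange(0, 60, 7, dtype=float))
        px = np.stack([gu.ravel(), gv.ravel()], axis=1)
        mesh = build_mesh(px)
        out = render(img, px, px, mesh, out_size=(80, 60))
        expect = a * uu + b * vv + c
        m = out.validity_mask
        np.testing.assert_allclose(out.image[m], expect[m], rtol=0, atol=1e-9)

    def test_outside_hull_gets_fill_and_invalid(self):
        img = np.full((60, 80), 200, dtype=np.uint8)
        px = np.array([[20.0, 20.0], [60.0, 20.0], [40.0, 50.0]])
        mesh = build_mesh(px)
        out = render(img, px, px, mesh, out_size=(80, 60), fill=7)
        assert not out.validity_mask[0, 0]
        assert out.image[0, 0] == 7
        assert np.all(np.isnan(out.source_map[0, 0]))

    def test_source_map_positions_inside_source_bounds(self, rng):
        img = rng.integers(0, 256, size=(60, 80), dtype=np.uint8)
        px_src = rng.uniform([0, 0], [79, 59], size=(40, 2))
        px_dst = px_src + rng.uniform(-3, 3, size=(40, 2))
        mesh = build_mesh(px_dst)
        out = render(img, px_src, px_dst, mesh, out_size=(80, 60))
        sm = out.source_map[out.validity_mask]
        assert np.all(sm[:, 0] >= 0) and np.all(sm[:, 0] <= 79)
        assert np.all(sm[:, 1] >= 0) and np.all(sm[:, 1] <= 59)


class TestWarpFrame:
    def test_identity_theta_matches_input_on_hull(self, setup, base_view, grid5):
        out = warp_frame(base_view, grid5, (0, 0, 0), setup.pose.pivot_pose, setup.cam)
        diff = np.abs(out.image.astype(int) - base_view.astype(int))[out.validity_mask]
        assert (diff <= 1).mean() >= 0.999

    def test_deterministic(self, setup, base_view, grid5):
        a = warp_frame(base_view, grid5, (25, 0, 0), setup.pose.pivot_pose, setup.cam)
        b = warp_frame(base_view, grid5, (25, 0, 0), setup.pose.pivot_pose, setup.cam)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mesh.simplices, b.mesh.simplices)

    def test_too_few_points_rejected(self, setup, base_view):
        pts = DepthPointSet(pixels=[[320, 240], [10, 10]],
                            points=[[0, 0, 117], [-45, -34, 117]], image_size=(640, 480))
        with pytest.raises(ValueError):
            warp_frame(base_view, pts, (0, 0, 0), setup.pose.pivot_pose, setup.cam)

    def test_dimension_mismatch_rejected(self, setup, grid5):
        with pytest.raises(ValueError):
            warp_frame(np.zeros((10, 10), dtype=np.uint8), grid5, (0, 0, 0),
                       setup.pose.pivot_pose, setup.cam)

    def test_color_image_supported(self, setup, grid5, base_view):
        rgb = np.stack([base_view] * 3, axis=-1)
        out = warp_frame(rgb, grid5, (15, 0, 0), setup.pose.pivot_pose, setup.cam)
        assert out.image.shape == rgb.shape
        gray = warp_frame(base_view, grid5, (15, 0, 0), setup.pose.pivot_pose, setup.cam)
        np.testing.assert_array_equal(out.image[..., 0], gray.image)


class TestPivotPose:
    def test_invalid_rotation_block_rejected(self):
        h = np.eye(4)
        h[0, 0] = 2.0
        with pytest.raises(ValueError):
            PivotPose(h)

    def test_rotation_about_matches_euler_composition(self):
        theta = (10.0, 20.0, 30.0)
        m = PivotPose.from_point((0, 0, 0)).rotation_about(theta)
        np.testing.assert_allclose(m[:3, :3], euler_zyx(theta), atol=1e-12)
        np.testing.assert_allclose(m[:3, 3], 0.0, atol=1e-12)
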