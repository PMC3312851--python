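import numpy as np
import pytest
from hypothesis import given, strategies as stnum
from scipy.spatial import cKDTree

import aortapwv as ap
from aortapwv.errors import DegenerateGeometryError, GeometryError


def rectangle_contour(length=100.0, width=20.0):
    return ap.LumenContour(
        0, 0, np.array([[0, 0], [length, 0], [length, width], [0, width]], float)
    )


def half_ring_contour(r_in=30.0, r_out=50.0, n=200):
    th = np.linspace(0, np.pi, n)
    outer = np.column_stack([r_out * np.cos(th), r_out * np.sin(th)])
    inner = np.column_stack([r_in * np.cos(th[::-1]), r_in * np.sin(th[::-1])])
    return ap.LumenContour(0, 0, np.vstack([outer, inner]))


class TestCenterline:
    def test_rectangle_midline_within_half_mm_hausdorff(self):
        cl = ap.centerline_from_contour(rectangle_contour(), [(0, 10), (100, 10)])
        mid = np.column_stack([np.linspace(0, 100, 1001), np.full(1001, 10.0)])
        d1 = cKDTree(mid).query(cl.points)[0].max()
        d2 = cKDTree(cl.points).query(mid)[0].max()
        assert max(d1, d2) <= 0.5

    def test_half_ring_medial_arc_within_one_mm(self):
        cl = ap.centerline_from_contour(half_ring_contour(), [(40, 0), (-40, 0)])
        radii = np.linalg.norm(cl.points, axis=1)
        assert np.abs(radii - 40.0).max() <= 1.0

    def test_too_few_points_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            ap.LumenContour(0, 0, np.array([[0, 0], [1, 1]], float))

    def test_self_intersecting_polygon_is_degenerate(self):
        bowtie = ap.LumenContour(
            0, 0, np.array([[0, 0], [10, 10], [10, 0], [0, 10]], float)
        )
        with pytest.raises(DegenerateGeometryError):
            ap.centerline_from_contour(bowtie, [(0, 5), (10, 5)])

    def test_tangents_are_unit_and_arc_strictly_increasing(self):
        cl = ap.centerline_from_contour(half_ring_contour(), [(40, 0), (-40, 0)])
        assert np.allclose(np.linalg.norm(cl.tangents, axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(cl.arc_length_m) > 0)


class TestChords:
    def test_rectangle_five_chords_at_quarter_fractions(self):
        rect = rectangle_contour()
        cl = ap.centerline_from_contour(rect, [(0, 10), (100, 10)])
        chords = ap.sample_chords(cl, rect, n=5)
        fracs = [c.s_m / cl.length_m for c in chords]
        assert fracs == pytest.approx([0, 0.25, 0.5, 0.75, 1.0], abs=1e-9)
        for c in chords:
            assert c.length_mm == pytest.approx(20.0, abs=0.5)
            # perpendicular to the local tangent
            chord_vec = c.endpoints[1] - c.endpoints[0]
            chord_vec = chord_vec / np.linalg.norm(chord_vec)
            assert abs(np.dot(chord_vec, c.direction)) < 1e-6

    def test_single_chord_sits_at_trajectory_start(self):
        rect = rectangle_contour()
        cl = ap.centerline_from_contour(rect, [(0, 10), (100, 10)])
        (chord,) = ap.sample_chords(cl, rect, n=1)
        assert chord.s_m == 0.0

    def test_half_ring_chords_span_constant_annulus_width(self):
        ring = half_ring_contour()
        cl = ap.centerline_from_contour(ring, [(40, 0), (-40, 0)])
        chords = ap.sample_chords(cl, ring, n=50)
        for c in chords:
            assert c.length_mm == pytest.approx(20.0, abs=0.5)

    def test_chord_arc_spacing_is_uniform(self):
        ring = half_ring_contour()
        cl = ap.centerline_from_contour(ring, [(40, 0), (-40, 0)])
        chords = ap.sample_chords(cl, ring, n=40)
        gaps = np.diff([c.s_m for c in chords])
        expected = cl.length_m / 39
        assert np.all(np.abs(gaps - expected) <= 0.01 * expected)


class TestProjection:
    def test_aligned_orthogonal_and_hand_example(self):
        assert ap.project_velocity(0.0, 1.0, (0.0, 1.0)) == pytest.approx(1.0)
        assert ap.project_velocity(1.0, 0.0, (0.0, 1.0)) == pytest.approx(0.0)
        assert ap.project_velocity(0.6, 0.8, (0.6, 0.8)) == pytest.approx(1.0)

    def test_non_unit_direction_is_an_error(self):
        with pytest.raises(GeometryError):
            ap.project_velocity(1.0, 0.0, (0.5, 0.5))

    @given(
        alpha=stnum.floats(-5, 5),
        vap=stnum.floats(-2, 2),
        vfh=stnum.floats(-2, 2),
        theta=stnum.floats(0, 6.28),
    )
    def test_projection_is_linear(self, alpha, vap, vfh, theta):
        d = (np.cos(theta), np.sin(theta))
        lhs = ap.project_velocity(alpha * vap, alpha * vfh, d)
        rhs = alpha * ap.project_velocity(vap, vfh, d)
        assert lhs == pytest.approx(rhs, abs=1e-9)


def _uniform_maps(n_phase=5, shape=(44, 204), value_fh=1.0, value_ap=0.0, venc=1.5):
    t = np.arange(n_phase) * 0.02
    fh = np.full((n_phase,) + shape, value_fh)
    aps = np.full((n_phase,) + shape, value_ap)
    return (
        ap.VelocityMapSeries("AP", aps, (0.5, 0.5), t, venc),
        ap.VelocityMapSeries("FH", fh, (0.5, 0.5), t, venc),
    )


@pytest.fixture(scope="module")
def rect_geometry():
    rect = rectangle_contour()
    cl = ap.centerline_from_contour(rect, [(0, 10), (100, 10)])
    return rect, cl, ap.sample_chords(cl, rect, n=9)


class TestChordCurves:
    def test_uniform_axial_flow_gives_constant_curves(self, rect_geometry):
        _, _, chords = rect_geometry
        maps_ap, maps_fh = _uniform_maps()
        curves = ap.chord_velocity_curves(maps_ap, maps_fh, chords, rr_s=1.0)
        for c in curves:
            assert np.allclose(c.values, 1.0, atol=1e-6)

    def test_parabolic_cross_profile_maximum_is_centerline_peak(self, rect_geometry):
        _, _, chords = rect_geometry
        n_phase, shape = 3, (44, 204)
        rows = np.arange(shape[0]) * 0.5
        profile = np.clip(1.0 - ((rows - 10.0) / 10.0) ** 2, 0, None)
        fh = np.broadcast_to(
            profile[None, :, None], (n_phase,) + shape
        ).copy()
        maps_ap = ap.VelocityMapSeries(
            "AP", np.zeros((n_phase,) + shape), (0.5, 0.5), np.arange(3) * 0.02, 1.5
        )
        maps_fh = ap.VelocityMapSeries("FH", fh, (0.5, 0.5), np.arange(3) * 0.02, 1.5)
        curves = ap.chord_velocity_curves(maps_ap, maps_fh, chords, rr_s=1.0)
        for c in curves[1:-1]:
            assert c.values[0] == pytest.approx(1.0, abs=0.02)

    def test_chord_outside_extent_is_an_error(self, rect_geometry):
        _, _, chords = rect_geometry
        maps_ap, maps_fh = _uniform_maps(shape=(10, 10))
        with pytest.raises(GeometryError):
            ap.chord_velocity_curves(maps_ap, maps_fh, chords, rr_s=1.0)

    def test_rigid_rotation_leaves_projected_curves_unchanged(self):
        """90-degree rotation of contour + components is a no-op."""
        rect = rectangle_contour()
        cl = ap.centerline_from_contour(rect, [(0, 10), (100, 10)])
        chords = ap.sample_chords(cl, rect, n=7)
        n_phase, shape = 3, (44, 204)
        rng = np.random.default_rng(0)
        rows = np.arange(shape[0]) * 0.5
        profile = np.clip(1.0 - ((rows - 10.0) / 10.0) ** 2, 0, None)
        amps = rng.uniform(0.5, 1.0, n_phase)
        fh = amps[:, None, None] * profile[None, :, None] * np.ones((1,) + shape)
        zero = np.zeros((n_phase,) + shape)
        t = np.arange(n_phase) * 0.02
        curves = ap.chord_velocity_curves(
            ap.VelocityMapSeries("AP", zero, (0.5, 0.5), t, 1.5),
            ap.VelocityMapSeries("FH", fh, (0.5, 0.5), t, 1.5),
            chords,
            rr_s=1.0,
        )
        # rotate by +90 deg: (x, y) -> (y_max - y, x); velocity (vx, vy) -> (-vy, vx)
        ymax = 21.5
        rot_poly = np.column_stack(
            [ymax - rect.polygon[:, 1], rect.polygon[:, 0]]
        )
        rect_r = ap.LumenContour(0, 0, rot_poly)
        cl_r = ap.centerline_from_contour(rect_r, [(11.5, 0), (11.5, 100)])
        chords_r = ap.sample_chords(cl_r, rect_r, n=7)
        # rotated frames: B[r', c'] = A[r=(c'), c=...] built by sampling the
        # original field at the pre-image of each new pixel
        shape_r = (204, 44)
        rr_idx, cc_idx = np.meshgrid(
            np.arange(shape_r[0]), np.arange(shape_r[1]), indexing="ij"
        )
        x_new = cc_idx * 0.5
        y_new = rr_idx * 0.5
        x_old = y_new
        y_old = ymax - x_new
        r_old = np.clip(np.round(y_old / 0.5).astype(int), 0, shape[0] - 1)
        c_old = np.clip(np.round(x_old / 0.5).astype(int), 0, shape[1] - 1)
        fh_r = np.empty((n_phase,) + shape_r)
        ap_r = np.empty((n_phase,) + shape_r)
        for k in range(n_phase):
            vx_old = fh[k][r_old, c_old]
            vy_old = zero[k][r_old, c_old]
            fh_r[k] = -vy_old  # new vx
            ap_r[k] = vx_old  # new vy
        curves_r = ap.chord_velocity_curves(
            ap.VelocityMapSeries("AP", ap_r, (0.5, 0.5), t, 1.5),
            ap.VelocityMapSeries("FH", fh_r, (0.5, 0.5), t, 1.5),
            chords_r,
            rr_s=1.0,
        )
        orig = np.array([c.values for c in curves])
        rot = np.array([c.values for c in curves_r])
        assert np.allclose(orig, rot, atol=1e-6)


class TestRoiAndArea:
    def test_uniform_roi_curve(self):
        poly = ap.LumenContour(
            0, 0, np.array([[2, 2], [20, 2], [20, 18], [2, 18]], float)
        )
        frames = np.ones((4, 30, 30))
        maps = ap.VelocityMapSeries(
            "through_plane", frames, (1.0, 1.0), np.arange(4) * 0.02, 1.5
        )
        curve = ap.roi_max_velocity_curve(maps, poly, rr_s=1.0)
        assert np.allclose(curve.values, 1.0)

    def test_all_zero_frames_then_no_upslope_downstream(self):
        poly = ap.LumenContour(
            0, 0, np.array([[2, 2], [20, 2], [20, 18], [2, 18]], float)
        )
        maps = ap.VelocityMapSeries(
            "through_plane", np.zeros((6, 30, 30)), (1.0, 1.0), np.arange(6) * 0.02, 1.5
        )
        curve = ap.roi_max_velocity_curve(maps, poly, rr_s=1.0)
        assert np.all(curve.values == 0.0)
        with pytest.raises(ap.errors.NoUpslopeError):
            ap.detect_onset_velocity(curve)

    def test_empty_roi_is_an_error(self):
        poly = ap.LumenContour(
            0, 0, np.array([[100, 100], [110, 100], [110, 110], [100, 110]], float)
        )
        maps = ap.VelocityMapSeries(
            "through_plane", np.zeros((2, 30, 30)), (1.0, 1.0), np.arange(2) * 0.02, 1.5
        )
        with pytest.raises(GeometryError):
            ap.roi_max_velocity_curve(maps, poly, rr_s=1.0)

    @staticmethod
    def _circle(r, n=256):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([50 + r * np.cos(th), 50 + r * np.sin(th)])

    def test_circle_area_matches_pi_r_squared(self):
        c = ap.LumenContour(0, 0, self._circle(10.0, n=64))
        assert c.area_mm2 == pytest.approx(np.pi * 100, rel=0.005)

    def test_identical_contours_have_zero_distension(self):
        c = ap.LumenContour(0, 0, self._circle(10.0))
        _, dA, _ = ap.lumen_area_series([c, c, c], [0.0, 0.03, 0.06], rr_s=1.0)
        assert dA == 0.0

    def test_oscillating_radii_distension(self):
        radii = [11.28, 11.97, 11.28, 11.97]
        contours = [
            ap.LumenContour(0, i, self._circle(r)) for i, r in enumerate(radii)
        ]
        _, dA, a_min = ap.lumen_area_series(
            contours, np.arange(4) * 0.03, rr_s=1.0
        )
        assert a_min == pytest.approx(np.pi * 11.28**2, rel=0.005)  # ~399.7
        assert dA == pytest.approx(np.pi * (11.97**2 - 11.28**2), rel=0.01)  # ~50.4

    def test_self_intersecting_phase_contour_is_degenerate(self):
        bowtie = ap.LumenContour(
            0, 0, np.array([[0, 0], [10, 10], [10, 0], [0, 10]], float)
        )
        ok = ap.LumenContour(0, 1, self._circle(10.0))
        with pytest.raises(DegenerateGeometryError):
            ap.lumen_area_series([bowtie, ok], [0.0, 0.03], rr_s=1.0)
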