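"""Slice geometry: contour smoothing, resampling, segmentation, OD."""

import numpy as np
import pytest

from topviewmap.errors import GeometryError, ValidationError
from topviewmap.slices import (
    Line,
    SliceDelineation,
    SliceMetadata,
    assign_segments,
    profile_slice,
    project_center,
    resample_arc,
    segment_mean_od,
    smooth_contour,
    validate_monotonic_x,
)
from topviewmap.synth import RibbonGeometry, generate_phantom_slice

from oracles import arc_resample_oracle, orthogonal_residual_ss


class TestSmoothContour:
    def test_collinear_points_are_fixed(self):
        pts = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0) + 1.0])
        out = smooth_contour(pts, window=3)
        assert np.allclose(out, pts, atol=1e-9)

    def test_short_polyline_unchanged(self):
        pts = np.array([[0.0, 0.0], [1.0, 3.0]])
        assert np.array_equal(smooth_contour(pts, window=5), pts)

    def test_noise_reduced_against_local_tls_oracle(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 4 * np.pi, 200)
        clean = np.column_stack([x, np.sin(x)])
        noisy = clean + rng.normal(0, 0.05, clean.shape)
        smoothed = smooth_contour(noisy, window=7)
        ss_before = orthogonal_residual_ss(noisy, noisy, half=3)
        ss_after = orthogonal_residual_ss(smoothed, noisy, half=3)
        assert ss_after < ss_before

    def test_rejects_non_finite(self):
        with pytest.raises(GeometryError):
            smooth_contour(np.array([[0.0, np.nan], [1.0, 1.0], [2.0, 2.0]]))


class TestResampleArc:
    def test_uniform_straight_line(self):
        out = resample_arc(np.array([[0.0, 0.0], [10.0, 0.0]]), 5)
        assert np.allclose(out[:, 0], [0, 2.5, 5, 7.5, 10])
        assert np.allclose(out[:, 1], 0)

    def test_k2_returns_endpoints(self):
        poly = np.array([[0.0, 0.0], [1.0, 2.0], [4.0, 0.5]])
        out = resample_arc(poly, 2)
        assert np.allclose(out, poly[[0, -1]])

    def test_quarter_circle_spacings(self):
        th = np.linspace(0, np.pi / 2, 2000)
        arc = np.column_stack([np.cos(th), np.sin(th)])
        out = resample_arc(arc, 4)
        expected = arc_resample_oracle(arc, 4)
        assert np.allclose(out, expected, atol=1e-9)
        spac = [
            np.abs(np.diff(np.arctan2(out[:, 1], out[:, 0])))[i] for i in range(3)
        ]
        assert np.allclose(spac, np.pi / 6, rtol=1e-3)

    def test_spacing_ratio_bound_on_smooth_curve(self):
        th = np.linspace(0, np.pi, 5000)
        arc = np.column_stack([np.cos(th), np.sin(th)])  # constant curvature:
        out = resample_arc(arc, 30)  # equal arcs <=> equal chords
        d = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert d.max() / d.min() <= 1.001

    def test_zero_length_errors(self):
        with pytest.raises(GeometryError):
            resample_arc(np.array([[1.0, 1.0], [1.0, 1.0]]), 3)


class TestMonotonicX:
    def test_increasing_ok(self):
        pts = np.column_stack([np.array([0.0, 1, 2, 3]), np.zeros(4)])
        assert np.array_equal(validate_monotonic_x(pts), pts)

    def test_error_names_index(self):
        pts = np.column_stack([np.array([0.0, 2, 1, 3]), np.zeros(4)])
        with pytest.raises(ValidationError, match="index 2"):
            validate_monotonic_x(pts)

    def test_reversed_is_flipped(self):
        pts = np.column_stack([np.array([3.0, 2, 1, 0]), np.arange(4.0)])
        out = validate_monotonic_x(pts)
        assert np.array_equal(out, pts[::-1])


class TestSegmentOd:
    def _setup(self, seg_value, bg_value):
        image = np.full((20, 20), bg_value, dtype=float)
        image[2:10, 2:10] = seg_value
        corners = np.array([[2.0, 2.0], [10.0, 2.0], [10.0, 10.0], [2.0, 10.0]])
        box = (12.0, 12.0, 18.0, 18.0)
        return image, corners, box

    @pytest.mark.parametrize(
        "seg,bg,expected", [(120.0, 120.0, 0.0), (0.0, 120.0, 1.0), (30.0, 120.0, 0.75)]
    )
    def test_formula_identities(self, seg, bg, expected):
        image, corners, box = self._setup(seg, bg)
        od = segment_mean_od(image, corners, box, pixel_size=1.0)
        assert od == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_positive_scaling(self):
        image, corners, box = self._setup(37.0, 113.0)
        od1 = segment_mean_od(image, corners, box, pixel_size=1.0)
        od2 = segment_mean_od(image * 3.7, corners, box, pixel_size=1.0)
        assert od1 == pytest.approx(od2, abs=1e-12)

    def test_bright_polarity_inverts(self):
        image = np.full((20, 20), 100, dtype=np.uint8)
        image[2:10, 2:10] = 200  # bright signal on dim background
        corners = np.array([[2.0, 2.0], [10.0, 2.0], [10.0, 10.0], [2.0, 10.0]])
        od = segment_mean_od(
            image, corners, (12, 12, 18, 18), pixel_size=1.0, polarity="bright_signal"
        )
        assert od == pytest.approx(1.0 - 55.0 / 155.0)

    def test_zero_background_errors(self):
        image, corners, box = self._setup(10.0, 0.0)
        with pytest.raises(GeometryError):
            segment_mean_od(image, corners, box, pixel_size=1.0)


class TestProjectCenter:
    def test_point_on_line(self):
        assert project_center(Line(1, 0, 0), (0, 1), (0, 3)) == 0.0

    def test_vertical_line(self):
        assert project_center(Line(1, 0, 0), (2, 3), (4, 5)) == pytest.approx(3.0)

    def test_matches_perpendicular_foot_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p1, p2 = rng.normal(size=(2, 2))
            q1, q2 = p1 + rng.normal(size=2), p1 + rng.normal(size=2)
            line = Line.from_points(q1, q2)
            centre = (p1 + p2) / 2
            direction = (q2 - q1) / np.linalg.norm(q2 - q1)
            foot = q1 + np.dot(centre - q1, direction) * direction
            assert project_center(line, p1, p2) == pytest.approx(
                np.linalg.norm(centre - foot), abs=1e-10
            )


class TestAssignSegments:
    def test_grid_aligned_rectangle_partitions_exactly(self):
        # rectangular ribbon aligned with the pixel grid: no pixel lost or shared
        top = np.column_stack([np.linspace(2.0, 12.0, 6), np.full(6, 2.0)])
        bot = np.column_stack([np.linspace(2.0, 12.0, 6), np.full(6, 6.0)])
        labels = assign_segments((20, 20), top, bot, pixel_size=1.0)
        counts = np.bincount(labels.ravel())
        assert counts[1:].sum() == 40  # 10 x 4 interior pixel centres
        assert len(counts) == 6 and np.all(counts[1:] == 8)


def _uniform_phantom(**kwargs):
    geometry = RibbonGeometry(pixel_size=0.02, shape=kwargs.pop("shape", "rect"))
    return generate_phantom_slice(geometry, lambda lat: np.full_like(lat, 0.4), **kwargs)


class TestProfileSlice:
    meta = SliceMetadata("c", "a", "f.tif", 0.0)

    def test_uniform_ribbon_constant_od(self):
        image, d = _uniform_phantom()
        prof = profile_slice(image, d, self.meta, k=12)
        assert np.allclose(prof.od, 0.4, atol=0.02)
        assert prof.od.std() < 5e-3

    def test_dark_patch_raises_od_locally(self):
        geometry = RibbonGeometry(pixel_size=0.02, shape="rect")
        lo, hi = geometry.lateral_range
        mid = (lo + hi) / 2

        def field(lat):
            return 0.3 + 0.3 * (np.abs(lat - mid) < 0.3)

        image, d = generate_phantom_slice(geometry, field)
        prof = profile_slice(image, d, self.meta, k=16)
        under = np.abs(prof.lateral - mid) < 0.2
        flank = np.abs(prof.lateral - mid) > 0.45
        assert under.any() and flank.any()
        assert prof.od[under].min() > prof.od[flank].max()

    def test_vertical_ribbon_lateral_distances_analytic(self):
        image, d = _uniform_phantom()
        prof = profile_slice(image, d, self.meta, k=10)
        # rectangular ribbon: distance to the vertical medial line is just x - cx
        analytic = np.abs([s.center[0] + d.reference_line.c for s in prof.samples])
        assert np.allclose(prof.lateral, analytic, atol=1e-12)
        assert np.all(np.diff(prof.lateral) > 0)

    def test_landmarks_projected_like_centres(self):
        image, d = _uniform_phantom()
        prof = profile_slice(image, d, self.meta, k=10)
        expected = d.reference_line.distance(d.landmarks)
        assert np.allclose(prof.landmark_distances, expected)

    def test_straddling_reference_line_rejected(self):
        image, d = _uniform_phantom()
        mid_x = np.median(d.top_edge[:, 0])
        bad = SliceDelineation(
            top_edge=d.top_edge,
            bottom_edge=d.bottom_edge,
            reference_line=Line(1.0, 0.0, -float(mid_x)),
            background_box=d.background_box,
            pixel_size=d.pixel_size,
            landmarks=d.landmarks,
        )
        with pytest.raises(ValidationError, match="one side"):
            profile_slice(image, bad, self.meta, k=10)
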