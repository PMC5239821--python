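"""Map building: curvature-penalised smoothing, reference map, condition maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from topviewmap.errors import ValidationError
from topviewmap.maps import (
    AnimalMap,
    ConditionStack,
    build_reference_map,
    condition_mean,
    curvature_penalized_smooth,
    difference_map,
    map_animal_to_reference,
    refit_slice,
    sampling_distribution,
    second_derivative_weights,
    smooth_map_edges,
    threshold_map,
    weighted_moving_average,
)


def make_animal(
    animal="a1",
    condition="c",
    bregmas=None,
    lateral=None,
    od=None,
    landmarks=None,
    interval=0.1,
):
    bregmas = np.arange(5) * interval if bregmas is None else np.asarray(bregmas, float)
    n = len(bregmas)
    if lateral is None:
        lateral = np.tile(np.linspace(0.5, 2.5, 6), (n, 1))
    if od is None:
        od = np.full_like(lateral, 0.4)
    if landmarks is None:
        landmarks = np.tile(np.array([1.0, 2.0]), (n, 1))
    return AnimalMap(
        animal=animal,
        condition=condition,
        bregmas=bregmas,
        lateral=np.asarray(lateral, float).copy(),
        od=np.asarray(od, float).copy(),
        landmarks=np.asarray(landmarks, float).copy(),
        interval=interval,
    )


class TestCurvatureWeights:
    def test_constant_sequence_all_ones(self):
        assert np.allclose(second_derivative_weights([3.0] * 6), 1.0)

    def test_single_bump_hand_values(self):
        w = second_derivative_weights([0.0, 0.0, 10.0, 0.0, 0.0])
        assert np.allclose(w, [1.0, 0.5, 0.0, 0.5, 1.0])

    def test_linear_interior_weight_one(self):
        w = second_derivative_weights(np.arange(7.0))
        assert np.allclose(w[1:-1], 1.0)


class TestWeightedMovingAverage:
    def test_constant_unchanged(self):
        x = np.full(9, 2.5)
        out = weighted_moving_average(x, np.ones(9), 5)
        assert np.allclose(out, x)

    def test_bump_removed(self):
        x = np.array([0.0, 0.0, 10.0, 0.0, 0.0])
        out = weighted_moving_average(x, second_derivative_weights(x), 3)
        assert out[2] == pytest.approx(0.0)

    def test_window_one_is_identity(self):
        x = np.array([1.0, -4.0, 2.0, 7.0])
        assert np.allclose(weighted_moving_average(x, np.ones(4), 1), x)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.sampled_from([3, 5, 7]),
    )
    def test_total_variation_contracts(self, values, w):
        x = np.asarray(values)
        out = curvature_penalized_smooth(x, w)
        tv = lambda v: np.abs(np.diff(v)).sum()
        assert tv(out) <= tv(x) + 1e-9 * max(1.0, tv(x))

    def test_idempotent_on_constants(self):
        x = np.full(7, -1.3)
        assert np.allclose(curvature_penalized_smooth(x, 3), x)


class TestRefitSlice:
    def test_identity(self):
        pos, lm = refit_slice([1.0, 2.0], [1.5], (0.0, 10.0), (0.0, 10.0))
        assert np.allclose(pos, [1, 2]) and np.allclose(lm, [1.5])

    def test_pure_translation(self):
        pos, _ = refit_slice([0.0, 4.0, 10.0], [], (0.0, 10.0), (1.0, 11.0))
        assert np.allclose(pos, [1, 5, 11])

    def test_pure_scale(self):
        pos, _ = refit_slice([4.0], [], (0.0, 10.0), (0.0, 5.0))
        assert np.allclose(pos, [2.0])

    def test_degenerate_extent_flagged(self):
        with pytest.raises(ValidationError):
            refit_slice([1.0], [], (2.0, 2.0), (0.0, 1.0))


class TestSmoothMapEdges:
    def test_constant_edges_unchanged(self):
        amap = make_animal()
        out = smooth_map_edges(amap, w=3)
        assert np.allclose(out.lateral, amap.lateral)
        assert np.allclose(out.landmarks, amap.landmarks)

    def test_outlier_slice_pulled_to_neighbours(self):
        lateral = np.tile(np.linspace(0.5, 2.5, 6), (5, 1))
        lateral[2] += 1.0  # whole slice displaced laterally
        amap = make_animal(lateral=lateral)
        out = smooth_map_edges(amap, w=3)
        # direct evaluation of the smoother on the edge sequences
        med = curvature_penalized_smooth(lateral[:, 0], 3)
        lat = curvature_penalized_smooth(lateral[:, -1], 3)
        assert np.allclose(out.lateral[:, 0], med, atol=1e-9)
        assert np.allclose(out.lateral[:, -1], lat, atol=1e-9)
        assert abs(out.lateral[2, 0] - 0.5) < abs(lateral[2, 0] - 0.5)
        for i in (0, 1, 3, 4):
            assert np.allclose(out.lateral[i], amap.lateral[i], atol=1e-6)

    def test_two_slice_map_matches_hand_evaluation(self):
        lateral = np.array([[0.5, 1.5, 2.5], [0.7, 1.7, 2.7]])
        amap = make_animal(
            bregmas=[0.0, 0.1], lateral=lateral, od=np.ones((2, 3)),
            landmarks=np.zeros((2, 0)),
        )
        out = smooth_map_edges(amap, w=3)
        # N=2 with mirror padding: both weights vanish -> plain window mean
        assert np.allclose(out.lateral[:, 0], 0.6)
        assert np.allclose(out.lateral[:, -1], 2.6)


class TestReferenceMap:
    def test_single_animal_smooth_edges_identity(self):
        amap = make_animal()
        ref = build_reference_map([amap], w=3)
        assert np.allclose(ref.bregma_grid, amap.bregmas)
        assert np.allclose(ref.positions, amap.lateral, atol=1e-6)
        assert np.allclose(ref.landmarks, amap.landmarks, atol=1e-6)

    def test_identical_animals_average_to_common_map(self):
        maps = [make_animal(animal=f"a{i}") for i in range(3)]
        ref = build_reference_map(maps, w=3)
        assert np.allclose(ref.positions, maps[0].lateral, atol=1e-6)

    def test_constant_offset_animals_average_to_midpoint(self):
        a = make_animal(animal="a1")
        b = make_animal(animal="a2", lateral=a.lateral + 0.4)
        ref = build_reference_map([a, b], w=3)
        expected = curvature_penalized_smooth(a.lateral[:, 0] + 0.2, 3)
        assert np.allclose(ref.positions[:, 0], expected, atol=1e-6)
        assert np.allclose(ref.positions, a.lateral + 0.2, atol=1e-6)

    def test_permutation_invariant_in_animal_order(self):
        rng = np.random.default_rng(0)
        base = np.tile(np.linspace(0.5, 2.5, 6), (5, 1))
        maps = [
            make_animal(animal=f"a{i}", lateral=base + rng.normal(0, 0.02, (5, 1)))
            for i in range(4)
        ]
        ref1 = build_reference_map(maps, w=3)
        ref2 = build_reference_map(maps[::-1], w=3)
        assert np.allclose(ref1.positions, ref2.positions)
        assert np.allclose(ref1.landmarks, ref2.landmarks)

    def test_disjoint_ranges_error(self):
        a = make_animal(animal="a1", bregmas=[0.0, 0.1, 0.2])
        b = make_animal(animal="a2", bregmas=[5.0, 5.1, 5.2])
        with pytest.raises(ValidationError):
            build_reference_map([a, b])

    def test_roundtrip_single_animal_od(self):
        rng = np.random.default_rng(1)
        amap = make_animal(od=rng.uniform(0, 1, (5, 6)))
        ref = build_reference_map([amap], w=3)
        raster = map_animal_to_reference(amap, ref)
        assert np.array_equal(raster, amap.od)

    def test_constant_od_animal_gives_constant_raster(self):
        amap = make_animal(od=np.full((5, 6), 0.7))
        shifted = make_animal(animal="a2", lateral=make_animal().lateral * 1.1)
        ref = build_reference_map([amap, shifted], w=3)
        raster = map_animal_to_reference(amap, ref)
        assert np.allclose(raster[np.isfinite(raster)], 0.7)


def make_stack(rasters, condition="c"):
    rasters = np.asarray(rasters, dtype=float)
    n_rows, n_cols = rasters.shape[1:]
    ref_positions = np.tile(np.linspace(0.5, 2.5, n_cols), (n_rows, 1))
    from topviewmap.maps import ReferenceMap

    ref = ReferenceMap(
        bregma_grid=0.1 * np.arange(n_rows),
        positions=ref_positions,
        landmarks=np.zeros((n_rows, 0)),
        interval=0.1,
    )
    return ConditionStack(
        condition=condition,
        animals=[f"a{i}" for i in range(rasters.shape[0])],
        rasters=rasters,
        reference=ref,
    )


class TestConditionMaps:
    def test_single_animal_mean_is_identity(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(0, 1, (1, 5, 6))
        cmap = condition_mean(make_stack(r))
        assert np.array_equal(cmap.mean, r[0])

    def test_mean_of_v_and_2v(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.1, 1, (5, 6))
        cmap = condition_mean(make_stack(np.stack([v, 2 * v])))
        assert np.allclose(cmap.mean, 1.5 * v)

    def test_display_preserves_constants(self):
        cmap = condition_mean(make_stack(np.full((2, 5, 6), 0.37)))
        finite = np.isfinite(cmap.display)
        assert finite.any()
        assert np.allclose(cmap.display[finite], 0.37, atol=1e-9)

    def test_duplicate_animal_pulls_mean(self):
        a = np.full((5, 6), 0.2)
        b = np.full((5, 6), 0.8)
        m2 = condition_mean(make_stack(np.stack([a, b]))).mean
        m3 = condition_mean(make_stack(np.stack([a, b, b]))).mean
        assert np.all(m3 >= m2)

    def test_difference_antisymmetry_and_identity(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 1, (2, 5, 6))
        a = condition_mean(make_stack(v, "A"))
        b = condition_mean(make_stack(rng.uniform(0, 1, (2, 5, 6)), "B"))
        assert np.allclose(difference_map(a, b), -difference_map(b, a))
        assert np.allclose(difference_map(a, a), 0.0)
        z = condition_mean(make_stack(np.zeros((1, 5, 6)), "Z"))
        assert np.allclose(difference_map(a, z), a.mean)


class TestSamplingDistribution:
    def _ref(self, positions):
        from topviewmap.maps import ReferenceMap

        positions = np.atleast_2d(np.asarray(positions, float))
        return ReferenceMap(
            bregma_grid=0.1 * np.arange(positions.shape[0]),
            positions=positions,
            landmarks=np.zeros((positions.shape[0], 0)),
            interval=0.1,
        )

    def test_equal_spacings(self):
        ref = self._ref(np.cumsum(np.full(8, 0.25))[None, :].repeat(3, axis=0))
        out = sampling_distribution(ref)
        assert out["median_mm"] == pytest.approx(0.25)
        assert out["upper_quartile_mm"] == pytest.approx(0.25)
        assert out["upper_fence_mm"] == pytest.approx(0.25)

    def test_tukey_fence_hand_case(self):
        # spacings [1, 1, 1, 9]: Q1 = 1, Q3 = 3, fence = min(3 + 3, 9) = 6
        ref = self._ref(np.concatenate([[0.0], np.cumsum([1.0, 1.0, 1.0, 9.0])]))
        out = sampling_distribution(ref)
        assert out["median_mm"] == pytest.approx(1.0)
        assert out["upper_quartile_mm"] == pytest.approx(3.0)
        assert out["upper_fence_mm"] == pytest.approx(6.0)

    def test_quantiles_match_order_statistics_oracle(self):
        rng = np.random.default_rng(5)
        spac = rng.choice([0.1, 0.2, 0.4], size=11)
        ref = self._ref(np.concatenate([[0.0], np.cumsum(spac)]))
        out = sampling_distribution(ref)
        assert out["median_mm"] == pytest.approx(np.quantile(spac, 0.5))
        assert out["upper_quartile_mm"] == pytest.approx(np.quantile(spac, 0.75))


class TestThreshold:
    def test_q0_keeps_all(self):
        rng = np.random.default_rng(6)
        cmap = condition_mean(make_stack(rng.uniform(0, 1, (1, 5, 6))))
        assert threshold_map(cmap, 0.0).sum() == 30

    def test_constant_raster_all_kept(self):
        cmap = condition_mean(make_stack(np.full((1, 5, 6), 0.4)))
        assert threshold_map(cmap, 0.6).all()

    def test_checkerboard_upper_quartile(self):
        board = np.indices((6, 6)).sum(0) % 2
        cmap = condition_mean(make_stack(board[None].astype(float)))
        kept = threshold_map(cmap, 0.75)
        assert np.array_equal(kept, board == 1)
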