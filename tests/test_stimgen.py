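"""Stimulus generation: geometry solutions, placement, adjustment, rendering."""

import math

import numpy as np
import pytest

from numfish.magnitudes import compute_magnitudes, disk_hull_area, mean_nn_dist
from numfish.stimgen import (
    CONDITIONS,
    ControlCondition,
    GenerationConfig,
    Geometry,
    InfeasibleConditionError,
    PlacementError,
    Spatial,
    adjust_spatial,
    generate_pair,
    place_dots,
    render_image,
    solve_geometry,
    visual_angle,
)


class TestSolveGeometry:
    @pytest.mark.parametrize(
        "mode,expected_radius",
        [
            (Geometry.AREA_EQ, 4 / math.sqrt(2)),  # total area 48*pi both sides
            (Geometry.PERIM_EQ, 2.0),  # total perimeter 24*pi both sides
            (Geometry.RADIUS_FIXED, 4.0),
        ],
    )
    def test_closed_forms_3_to_6(self, mode, expected_radius):
        radii = solve_geometry(3, [4.0, 4.0, 4.0], 6, mode)
        assert radii.shape == (6,)
        assert np.allclose(radii, expected_radius, rtol=1e-12)

    def test_area_conserved_for_heterogeneous_reference(self):
        ref = [2.0, 3.0, 5.0]
        radii = solve_geometry(3, ref, 7, Geometry.AREA_EQ)
        assert np.isclose(np.sum(radii**2), np.sum(np.square(ref)), rtol=1e-12)

    def test_perimeter_conserved_for_heterogeneous_reference(self):
        ref = [2.0, 3.0, 5.0]
        radii = solve_geometry(3, ref, 4, Geometry.PERIM_EQ)
        assert np.isclose(np.sum(radii), np.sum(ref), rtol=1e-12)

    def test_radius_fixed_rejects_nonuniform_reference(self):
        with pytest.raises(InfeasibleConditionError):
            solve_geometry(3, [2.0, 3.0, 4.0], 6, Geometry.RADIUS_FIXED)

    def test_rejects_nonpositive_radii(self):
        with pytest.raises(ValueError):
            solve_geometry(2, [1.0, -1.0], 3, Geometry.AREA_EQ)


class TestPlaceDots:
    def test_single_dot_containment_bound(self, rng):
        arr = place_dots(1, [6.0], 30.0, rng)
        d = arr.dots[0]
        assert math.hypot(d.center_x, d.center_y) <= 24.0 + 1e-9

    def test_pairwise_distances_respect_gap(self, rng):
        arr = place_dots(9, [1.5] * 9, 30.0, rng, min_gap=1.0)
        c = arr.centers
        for i in range(9):
            for j in range(i + 1, 9):
                assert np.hypot(*(c[i] - c[j])) >= 3.0 + 1.0 - 1e-9
        arr.validate(min_gap=1.0)

    def test_same_seed_identical_arrays(self):
        a = place_dots(5, [2.0] * 5, 30.0, np.random.default_rng(7))
        b = place_dots(5, [2.0] * 5, 30.0, np.random.default_rng(7))
        assert a == b

    def test_too_dense_request_fails_with_named_error(self, rng):
        with pytest.raises(PlacementError):
            place_dots(9, [9.0] * 9, 30.0, rng, max_attempts=200)


class TestAdjustSpatial:
    def test_identity_target_is_noop(self, square_array, rng):
        target = mean_nn_dist(square_array)
        out = adjust_spatial(square_array, "mean_nn_dist", target, 0.05, rng)
        assert out == square_array

    def test_similarity_scaling_identities(self, square_array):
        k = 1.3
        centroid = square_array.centers.mean(axis=0)
        scaled = square_array.with_centers(
            centroid + (square_array.centers - centroid) * k
        )
        assert np.isclose(
            mean_nn_dist(scaled), k * mean_nn_dist(square_array), rtol=1e-12
        )
        # disk hull scales slightly less than k^2 because radii are unchanged
        ratio = disk_hull_area(scaled) / disk_hull_area(square_array)
        center_hull_ratio = k**2
        assert abs(ratio - center_hull_ratio) / center_hull_ratio < 0.15

    def test_hull_doubling_achieved_within_tolerance(self, rng):
        arr = place_dots(3, [2.0] * 3, 30.0, rng)
        target = 2.0 * disk_hull_area(arr)
        out = adjust_spatial(arr, "hull_area", target, 0.05, rng)
        assert abs(disk_hull_area(out) - target) <= 0.05 * target
        out.validate(min_gap=0.0)

    def test_requires_two_dots(self, rng):
        from numfish.stimgen import DotArray, Dot

        single = DotArray((Dot(0, 0, 2.0),))
        with pytest.raises(ValueError):
            adjust_spatial(single, "hull_area", 10.0, 0.05, rng)


class TestGeneratePair:
    def test_equal_numerosities_rejected(self, area_id_condition):
        with pytest.raises(ValueError):
            generate_pair(3, 3, area_id_condition, rng=0)

    def test_area_id_pair_constraints(self, area_id_condition):
        pair = generate_pair(3, 6, area_id_condition, rng=42)
        m_s = compute_magnitudes(pair.array_small)
        m_l = compute_magnitudes(pair.array_large)
        assert abs(m_l.total_area - m_s.total_area) / m_s.total_area < 1e-9
        assert (
            abs(m_l.mean_nn_dist - m_s.mean_nn_dist) / m_s.mean_nn_dist <= 0.05
        )

    def test_radius_fixed_ch_pair_constraints(self):
        cond = ControlCondition(Geometry.RADIUS_FIXED, Spatial.CH_EQ)
        pair = generate_pair(3, 6, cond, rng=42)
        radii = np.concatenate([pair.array_small.radii, pair.array_large.radii])
        assert np.allclose(radii, radii[0])
        m_s = compute_magnitudes(pair.array_small)
        m_l = compute_magnitudes(pair.array_large)
        assert abs(m_l.hull_area - m_s.hull_area) / m_s.hull_area <= 0.05

    def test_determinism_same_seed(self, area_id_condition):
        a = generate_pair(3, 6, area_id_condition, rng=9)
        b = generate_pair(3, 6, area_id_condition, rng=9)
        assert a.array_small == b.array_small and a.array_large == b.array_large

    @pytest.mark.parametrize("condition", CONDITIONS, ids=lambda c: c.label())
    def test_uncontrolled_magnitude_scaling_laws(self, condition):
        """Closed-form covariation of the free geometry magnitudes.

        With uniform radii: at equal total area the perimeter ratio is
        sqrt(n_l/n_s); at equal total perimeter the area ratio is n_s/n_l;
        with fixed radius both scale with the numerosity ratio.
        """
        pair = generate_pair(3, 6, condition, rng=5)
        m_s = compute_magnitudes(pair.array_small)
        m_l = compute_magnitudes(pair.array_large)
        if condition.geometry is Geometry.AREA_EQ:
            assert np.isclose(
                m_l.total_perimeter / m_s.total_perimeter,
                math.sqrt(2.0),
                rtol=1e-9,
            )
        elif condition.geometry is Geometry.PERIM_EQ:
            assert np.isclose(m_l.total_area / m_s.total_area, 0.5, rtol=1e-9)
        else:
            assert np.isclose(m_l.total_area / m_s.total_area, 2.0, rtol=1e-9)
            assert np.isclose(
                m_l.total_perimeter / m_s.total_perimeter, 2.0, rtol=1e-9
            )


class TestRenderImage:
    def test_empty_field_has_only_outline(self):
        from numfish.stimgen import DotArray, Dot

        arr = DotArray((Dot(0.0, 0.0, 2.0),))
        with_dot = render_image(arr, 4.0, draw_outline=True)
        # black pixels exist both on the ring and in the centre disk
        assert (with_dot == 0).sum() > 0
        no_outline = render_image(arr, 4.0, draw_outline=False)
        assert (no_outline == 0).sum() < (with_dot == 0).sum()

    def test_ink_area_matches_analytic(self, rng):
        arr = place_dots(3, [3.0] * 3, 30.0, rng)
        img = render_image(arr, 10.0, draw_outline=False)
        ink = (img == 0).sum()
        expected = 27 * math.pi * 100  # sum(pi r^2) * px_per_mm^2
        assert abs(ink - expected) / expected < 0.02

    def test_bit_identical_rerender(self, square_array):
        a = render_image(square_array, 8.0)
        b = render_image(square_array, 8.0)
        assert np.array_equal(a, b)

    def test_invalid_resolution(self, square_array):
        with pytest.raises(ValueError):
            render_image(square_array, 0.0)


class TestVisualAngle:
    @pytest.mark.parametrize(
        "extent,distance,expected",
        [(12.0, 400.0, 1.72), (3.0, 400.0, 0.43)],
    )
    def test_study_bounds(self, extent, distance, expected):
        assert round(visual_angle(extent, distance), 2) == expected

    def test_continuous_at_zero_extent(self):
        assert visual_angle(1e-4, 400.0) < 1e-4

    def test_positive_arguments_required(self):
        with pytest.raises(ValueError):
            visual_angle(0.0, 400.0)
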