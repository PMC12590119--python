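"""Circular distance, cortical responses, activation spread, map statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amblyosim import (
    ActivationMap,
    FilterSet,
    GratingParams,
    OrientationMap,
    amblyopic_response,
    circ_dist,
    fellow_response,
    grating_weight,
    map_metrics,
    spread,
    spread_ratio,
)


def _random_map(rng, shape=(24, 24), mm_per_pixel=0.05):
    return OrientationMap(rng.uniform(0, 180, size=shape), mm_per_pixel)


class TestCircDist:
    @pytest.mark.parametrize(
        "o1, o2, expected",
        [
            (45.0, 135.0, 1.0),  # orthogonal
            (30.0, 30.0, 0.0),  # identical
            (170.0, 10.0, 20.0 / 90.0),  # wrap-around branch
            (0.0, 180.0, 0.0),  # period
            (0.0, 45.0, 0.5),
        ],
    )
    def test_values(self, o1, o2, expected):
        assert circ_dist(o1, o2) == pytest.approx(expected)

    @given(
        a=st.floats(0.0, 360.0, allow_nan=False),
        b=st.floats(0.0, 360.0, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_bounded_periodic(self, a, b):
        d = circ_dist(a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(circ_dist(b, a))
        assert d == pytest.approx(circ_dist(a + 180.0, b), abs=1e-9)

    def test_vectorized(self):
        grid = np.array([[0.0, 45.0], [90.0, 135.0]])
        np.testing.assert_allclose(
            circ_dist(grid, 0.0), [[0.0, 0.5], [1.0, 0.5]]
        )


class TestFellowResponse:
    def test_matched_orthogonal_and_midpoint(self):
        omap = OrientationMap(np.array([[30.0, 120.0], [75.0, 30.0]]), 0.05)
        act = fellow_response(omap, 30.0)
        np.testing.assert_allclose(act.response, [[1.0, 0.0], [0.5, 1.0]])
        assert act.eye == "fellow"

    def test_range(self, rng):
        act = fellow_response(_random_map(rng), 77.0)
        assert act.response.min() >= 0.0 and act.response.max() <= 1.0


class TestGratingWeight:
    def test_matched_is_one(self):
        assert grating_weight(42.0, 42.0) == 1.0

    def test_orthogonal_closed_form(self):
        assert grating_weight(0.0, 90.0, sigma=0.2) == pytest.approx(
            np.exp(-12.5), rel=1e-12
        )

    def test_strictly_decreasing(self):
        ws = [grating_weight(0.0, o) for o in (0.0, 10.0, 30.0, 50.0, 70.0, 90.0)]
        assert all(a > b for a, b in zip(ws, ws[1:]))

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            grating_weight(0.0, 10.0, sigma=0.0)


class TestAmblyopicResponse:
    def test_single_matched_filter_equals_fellow(self, rng):
        omap = _random_map(rng)
        fs = FilterSet([GratingParams(40.0, 5.0)], np.array([0.8]))
        ar = amblyopic_response(omap, fs, 40.0)
        fr = fellow_response(omap, 40.0)
        np.testing.assert_allclose(ar.response, fr.response)

    def test_bounded_by_total_weight(self, rng):
        omap = _random_map(rng)
        fs = FilterSet(
            [GratingParams(0.0, 5.0), GratingParams(30.0, 4.0), GratingParams(100.0, 5.0)],
            np.array([0.8, 0.4, 0.2]),
        )
        ar = amblyopic_response(omap, fs, 0.0)
        total = sum(grating_weight(p.orientation, 0.0) for p in fs.filters)
        assert np.all(ar.response <= total + 1e-12)

    def test_orthogonal_pair_term_evaluation(self):
        omap = OrientationMap(np.array([[20.0]]), 0.05)
        fs = FilterSet(
            [GratingParams(20.0, 5.0), GratingParams(110.0, 5.0)], np.array([1.0, 1.0])
        )
        ar = amblyopic_response(omap, fs, 20.0)
        # matched term contributes 1; orthogonal term 0 * W_G
        assert ar.response[0, 0] == pytest.approx(1.0)


class TestSpread:
    def test_counts_match_bruteforce(self, rng):
        """Thresholded counts equal an explicit per-pixel loop exactly."""
        for _ in range(5):
            response = rng.uniform(0, 1, size=(17, 23))
            act = ActivationMap(response, eye="fellow", threshold_fraction=0.7)
            expected = 0
            peak = response.max()
            for i in range(response.shape[0]):
                for j in range(response.shape[1]):
                    if response[i, j] >= 0.7 * peak:
                        expected += 1
            assert spread(act) == expected

    def test_identical_maps_ratio_one(self, rng):
        response = rng.uniform(0, 1, size=(20, 20))
        a = ActivationMap(response, eye="fellow")
        b = ActivationMap(response.copy(), eye="amblyopic")
        result = spread_ratio(a, b)
        assert result.spread_ratio == 1.0
        assert result.n_active_fellow == result.n_active_amblyopic

    def test_matched_filter_ratio_exactly_one(self, rng):
        omap = _random_map(rng, shape=(30, 30))
        fs = FilterSet([GratingParams(65.0, 5.0)], np.array([0.8]))
        fel = fellow_response(omap, 65.0)
        amb = amblyopic_response(omap, fs, 65.0)
        assert spread_ratio(fel, amb).spread_ratio == 1.0

    def test_second_filter_matches_bruteforce_oracle(self, rng):
        omap = _random_map(rng, shape=(40, 40))
        fs = FilterSet(
            [GratingParams(0.0, 5.0), GratingParams(45.0, 5.0)], np.array([0.8, 0.4])
        )
        amb = amblyopic_response(omap, fs, 0.0)
        # per-pixel brute-force recomputation
        expected = np.zeros(omap.shape)
        for i in range(omap.shape[0]):
            for j in range(omap.shape[1]):
                o_c = omap.preferred_orientation[i, j]
                for p in fs.filters:
                    expected[i, j] += (1.0 - circ_dist(o_c, p.orientation)) * grating_weight(
                        p.orientation, 0.0
                    )
        np.testing.assert_allclose(amb.response, expected)
        act = ActivationMap(expected, eye="amblyopic")
        assert spread(act) == spread(amb)

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError):
            spread(ActivationMap(np.zeros((5, 5)), eye="fellow"))

    def test_shape_mismatch_rejected(self, rng):
        a = ActivationMap(rng.uniform(0, 1, (5, 5)), eye="fellow")
        b = ActivationMap(rng.uniform(0, 1, (6, 6)), eye="amblyopic")
        with pytest.raises(ValueError):
            spread_ratio(a, b)


class TestMapMetrics:
    def test_stripe_map_column_width(self):
        """Orientation cycling every 0.8 mm gives ~0.4 mm columns."""
        mm_per_pixel = 0.02
        n = 200
        xs = np.arange(n) * mm_per_pixel
        theta = (180.0 * xs / 0.8) % 180.0
        omap = OrientationMap(np.tile(theta, (n, 1)), mm_per_pixel)
        metrics = map_metrics(omap)
        assert metrics["column_width_mm"] == pytest.approx(0.4, abs=0.02)
        assert metrics["pinwheel_count"] == 0

    def test_constant_map_no_pinwheels(self):
        omap = OrientationMap(np.full((30, 30), 45.0), 0.05)
        metrics = map_metrics(omap)
        assert metrics["pinwheel_count"] == 0
        assert np.isnan(metrics["column_width_mm"])  # width undefined, flagged

    def test_pinwheel_count_rotation_invariant(self, rng):
        from amblyosim.synthetic import gen_orientation_map

        omap = gen_orientation_map(shape=(64, 64), target_column_wavelength_mm=0.8,
                                   mm_per_pixel=0.05, rng_seed=5)
        rotated = OrientationMap(np.rot90(omap.preferred_orientation), omap.mm_per_pixel)
        assert map_metrics(omap)["pinwheel_count"] == map_metrics(rotated)["pinwheel_count"]

    def test_small_map_rejected(self):
        with pytest.raises(ValueError):
            map_metrics(OrientationMap(np.zeros((10, 10)), 0.05))
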