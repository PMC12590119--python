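"""Grating synthesis, filter rectification, weights, and percept assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amblyosim import (
    AliasingError,
    FilterSet,
    Geometry,
    GratingParams,
    filter_weight,
    make_filter,
    make_grating,
    synthesize_percept,
)


class TestGratingParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duty_constant": 1.5},
            {"duty_constant": -1.2},
            {"saturation_threshold": 2.5},
            {"amblyopia_constant": -0.1},
            {"spatial_frequency": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = {"orientation": 0.0, "spatial_frequency": 5.0}
        base.update({k: v for k, v in kwargs.items() if k != "spatial_frequency"})
        if "spatial_frequency" in kwargs:
            base["spatial_frequency"] = kwargs["spatial_frequency"]
        with pytest.raises(ValueError):
            GratingParams(**base)

    def test_orientation_and_phase_wrap(self):
        p = GratingParams(orientation=190.0, spatial_frequency=5.0, phase=370.0)
        assert p.orientation == pytest.approx(10.0)
        assert p.phase == pytest.approx(10.0)


class TestMakeGrating:
    def test_zero_phase_center_value(self):
        # odd pixel count puts one sample exactly at the field center
        geom = Geometry(3.0, 21.0)  # 63 px
        g = make_grating(GratingParams(0.0, 1.0), geom)
        n = g.n_pixels
        assert g.values[n // 2, n // 2] == pytest.approx(0.0, abs=1e-12)

    def test_horizontal_grating_rows_constant(self, geometry64):
        g = make_grating(GratingParams(0.0, 5.0), geometry64)
        for row, mask_row in zip(g.values, g.aperture):
            inside = row[mask_row]
            if inside.size:
                assert np.ptp(inside) < 1e-12

    def test_aperture_mean_near_zero(self, geometry128):
        g = make_grating(GratingParams(0.0, 5.0), geometry128)
        assert abs(g.values[g.aperture].mean()) < 1e-3

    def test_range_and_background(self, geometry64):
        g = make_grating(GratingParams(30.0, 4.0, phase=120.0), geometry64)
        assert g.values.min() >= -1.0 and g.values.max() <= 1.0
        assert np.all(g.values[~g.aperture] == 0.0)

    def test_nyquist_guard(self, geometry64):
        with pytest.raises(AliasingError):
            make_grating(GratingParams(0.0, 10.0), geometry64)  # Nyquist at 20/2

    def test_bad_geometry(self):
        with pytest.raises(ValueError):
            Geometry(-1.0, 20.0)


class TestMakeFilter:
    def test_identity_when_clipping_inactive(self, geometry64):
        p = GratingParams(20.0, 4.0, duty_constant=0.0, saturation_threshold=1.0)
        g = make_grating(p, geometry64)
        f = make_filter(p, geometry64)
        np.testing.assert_allclose(f.values, g.values)

    def test_negative_duty_thickens_dark_lines(self, geometry128):
        # 40 px/deg: 8 samples per 5-cpd cycle avoids degenerate sampling
        p = GratingParams(0.0, 5.0, duty_constant=-0.5, saturation_threshold=1.0)
        f = make_filter(p, geometry128)
        inside = f.values[f.aperture]
        assert (inside < 0).mean() > (inside > 0).mean()

    def test_elementwise_clip_value(self, geometry64):
        # G = 0.6 at some pixel with K = 0.5, T = 0.8 -> clipped to 0.8
        assert np.clip(0.6 + 0.5, -0.8, 0.8) == pytest.approx(0.8)
        p = GratingParams(0.0, 5.0, duty_constant=0.5, saturation_threshold=0.8)
        g = make_grating(p.with_(duty_constant=0.0, saturation_threshold=1.0), geometry64)
        f = make_filter(p, geometry64)
        mask = g.aperture
        np.testing.assert_allclose(
            f.values[mask], np.clip(g.values[mask] + 0.5, -0.8, 0.8)
        )

    @given(
        k=st.floats(-1.0, 1.0),
        t=st.floats(0.0, 2.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_three_branch_rule_equals_clip(self, k, t, seed):
        """The rectification's three-branch definition is elementwise clip."""
        rng = np.random.default_rng(seed)
        g = rng.uniform(-1.5, 1.5, size=(16, 16))
        shifted = g + k
        branch = np.empty_like(shifted)
        for i in range(16):
            for j in range(16):
                v = shifted[i, j]
                if v >= t:
                    branch[i, j] = t
                elif v <= -t:
                    branch[i, j] = -t
                else:
                    branch[i, j] = v
        np.testing.assert_array_equal(branch, np.clip(shifted, -t, t))


class TestFilterWeight:
    def test_zero_amblyopia_constant(self, geometry64):
        p = GratingParams(0.0, 5.0, amblyopia_constant=0.0)
        s = make_grating(p.with_(amblyopia_constant=1.0), geometry64)
        assert filter_weight(s, p) == 0.0

    def test_matched_grating_half(self, geometry128):
        p = GratingParams(0.0, 5.0)
        s = make_grating(p, geometry128)
        assert filter_weight(s, p) == pytest.approx(0.5, abs=0.01)

    def test_orthogonal_gratings_near_zero(self, geometry128):
        p = GratingParams(0.0, 5.0)
        s = make_grating(p, geometry128)
        assert abs(filter_weight(s, p.with_(orientation=90.0))) < 0.01

    def test_nonsquare_field_rejected(self):
        from amblyosim import ImageField

        with pytest.raises(ValueError):
            ImageField(np.zeros((8, 10)), 3.2, 20.0)

    def test_weight_maximal_at_stimulus_orientation(self, geometry128):
        stim_p = GratingParams(40.0, 5.0)
        s = make_grating(stim_p, geometry128)
        weights = {
            theta: filter_weight(s, stim_p.with_(orientation=theta))
            for theta in range(0, 180, 5)
        }
        assert max(weights, key=weights.get) == 40


class TestSynthesizePercept:
    def test_single_filter_identity(self, geometry64):
        p = GratingParams(10.0, 4.0)
        fs = FilterSet([p], np.array([1.0]))
        percept = synthesize_percept(fs, geometry64)
        np.testing.assert_allclose(percept.values, make_grating(p, geometry64).values)

    def test_output_saturated(self, geometry64, rng):
        filters = [
            GratingParams(rng.uniform(0, 180), rng.uniform(1, 8), phase=rng.uniform(0, 360))
            for _ in range(4)
        ]
        fs = FilterSet(filters, rng.uniform(0.5, 1.5, size=4))
        percept = synthesize_percept(fs, geometry64)
        assert percept.values.min() >= -1.0 and percept.values.max() <= 1.0

    def test_orthogonal_pair_rotation_symmetry(self, geometry64):
        # cosine-phase orthogonal pair is invariant under 90-degree rotation
        fs = FilterSet(
            [GratingParams(0.0, 5.0, phase=90.0), GratingParams(90.0, 5.0, phase=90.0)],
            np.array([0.4, 0.4]),
        )
        percept = synthesize_percept(fs, geometry64)
        np.testing.assert_allclose(percept.values, np.rot90(percept.values), atol=1e-10)

    def test_linear_in_weights_before_saturation(self, geometry64):
        filters = [GratingParams(0.0, 5.0), GratingParams(60.0, 4.0, phase=45.0)]
        small = FilterSet(filters, np.array([0.2, 0.1]))
        double = FilterSet(filters, np.array([0.4, 0.2]))
        p1 = synthesize_percept(small, geometry64)
        p2 = synthesize_percept(double, geometry64)
        assert np.abs(p1.values).max() < 0.5  # saturation inactive
        np.testing.assert_allclose(2.0 * p1.values, p2.values, atol=1e-12)

    def test_empty_filter_set_rejected(self):
        with pytest.raises(ValueError):
            FilterSet([], np.array([]))
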