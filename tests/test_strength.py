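"""Linear scaling and strength (maximum isometric force) scaling."""

import numpy as np
import pytest

from mskwarp.core import LandmarkSet
from mskwarp.anthropometry import segment_lengths
from mskwarp.strength import (DEFAULT_PAIR_SPEC, AnthropometrySpec, MuscleStrengthSpec,
                              ScaleSet, apply_linear_scaling, apply_strength_scaling,
                              handsfield_volume, linear_scale_factors,
                              strength_scale_factor)


class TestHandsfieldVolume:
    def test_male_mean_anthropometry(self):
        v = handsfield_volume(AnthropometrySpec(mass=76.43, body_height=1.84))
        assert v == pytest.approx(47 * 76.43 * 1.84 + 1285)
        assert v == pytest.approx(7894.666, abs=1e-2)

    def test_female_mean_anthropometry(self):
        v = handsfield_volume(AnthropometrySpec(mass=59.53, body_height=1.64))
        assert v == pytest.approx(47 * 59.53 * 1.64 + 1285)

    def test_intercept_at_zero_mass_limit(self):
        v = handsfield_volume(AnthropometrySpec(mass=1e-12, body_height=1.7))
        assert v == pytest.approx(1285.0)

    def test_linear_in_mass_height_product(self):
        v1 = handsfield_volume(AnthropometrySpec(60.0, 1.70))
        v2 = handsfield_volume(AnthropometrySpec(120.0, 1.70))
        assert v2 - 1285 == pytest.approx(2 * (v1 - 1285))


class TestStrengthFactor:
    def test_identical_specs_unity(self):
        s = MuscleStrengthSpec("m", 100.0, 100.0, 0.1, 0.1, 1000.0)
        assert strength_scale_factor(s) == pytest.approx(1.0)

    def test_volume_ratio_two(self):
        s = MuscleStrengthSpec("m", 100.0, 200.0, 0.1, 0.1, 1000.0)
        assert strength_scale_factor(s) == pytest.approx(2.0)

    def test_pcsa_invariance(self):
        """Volume and fiber length both doubled: PCSA, hence force, unchanged."""
        s = MuscleStrengthSpec("m", 100.0, 200.0, 0.1, 0.2, 1000.0)
        assert strength_scale_factor(s) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            MuscleStrengthSpec("m", 0.0, 100.0, 0.1, 0.1, 1000.0)


class TestLinearScaleFactors:
    def test_identical_markers_unity(self, fixture_model):
        s = linear_scale_factors(fixture_model.skin_markers, fixture_model.skin_markers,
                                 DEFAULT_PAIR_SPEC)
        for f in s.factors.values():
            assert f == pytest.approx((1.0, 1.0, 1.0))

    def test_uniform_scaling_recovered(self, fixture_model):
        scaled = fixture_model.skin_markers.with_coords(
            fixture_model.skin_markers.coords * 1.05)
        s = linear_scale_factors(fixture_model.skin_markers, scaled, DEFAULT_PAIR_SPEC)
        for f in s.factors.values():
            assert f == pytest.approx((1.05, 1.05, 1.05))

    def test_two_marker_toy_hand_arithmetic(self):
        g = LandmarkSet(["a", "b"], [[0, 0, 0], [0.4, 0, 0]], "ISB_global", "m")
        p = LandmarkSet(["a", "b"], [[0, 0, 0], [0.5, 0, 0]], "ISB_global", "m")
        s = linear_scale_factors(g, p, {"seg": [("a", "b")]})
        assert s.factors["seg"] == pytest.approx((1.25, 1.25, 1.25))

    def test_zero_generic_distance_rejected(self):
        g = LandmarkSet(["a", "b"], np.zeros((2, 3)), "ISB_global", "m")
        with pytest.raises(ValueError, match="zero generic"):
            linear_scale_factors(g, g, {"seg": [("a", "b")]})


class TestApplyLinearScaling:
    def test_unit_factors_identity(self, fixture_model):
        s = ScaleSet({seg: (1.0, 1.0, 1.0) for seg in fixture_model.segments})
        out = apply_linear_scaling(fixture_model, s)
        for mu_o, mu_s in zip(fixture_model.muscles, out.muscles):
            for po, ps in zip(mu_o.points, mu_s.points):
                np.testing.assert_allclose(ps.position, po.position, atol=1e-9)
        for k in fixture_model.strength:
            assert out.strength[k].optimal_fiber_length == pytest.approx(
                fixture_model.strength[k].optimal_fiber_length)

    def test_uniform_doubling_doubles_segment_lengths(self, fixture_model):
        s = ScaleSet({seg: (2.0, 2.0, 2.0) for seg in fixture_model.segments})
        out = apply_linear_scaling(fixture_model, s)
        sl0 = segment_lengths(fixture_model, "r")
        sl2 = segment_lengths(out, "r")
        assert sl2["femur_length"] == pytest.approx(2 * sl0["femur_length"], rel=1e-9)
        assert sl2["tibia_length"] == pytest.approx(2 * sl0["tibia_length"], rel=1e-9)
        # fiber lengths scale with the spanned-segment mean factor
        assert out.strength["vastus_lateralis"].optimal_fiber_length == pytest.approx(
            2 * fixture_model.strength["vastus_lateralis"].optimal_fiber_length)

    def test_anisotropic_scaling_only_one_axis(self, fixture_model):
        s = ScaleSet({seg: (1.0, 2.0, 1.0) for seg in fixture_model.segments})
        out = apply_linear_scaling(fixture_model, s)
        sl0 = segment_lengths(fixture_model, "r")
        sl2 = segment_lengths(out, "r")
        # femur axis is along local y: length doubles, while a transverse
        # pelvis dimension (hip spacing along z) is unchanged
        assert sl2["femur_length"] == pytest.approx(2 * sl0["femur_length"], rel=1e-6)
        hips0 = np.linalg.norm(fixture_model.joint("hip_r").center_global
                               - fixture_model.joint("hip_l").center_global)
        hips2 = np.linalg.norm(out.joint("hip_r").center_global
                               - out.joint("hip_l").center_global)
        assert hips2 == pytest.approx(hips0, rel=1e-9)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            ScaleSet({"pelvis": (1.0, 0.0, 1.0)})


class TestApplyStrengthScaling:
    def test_identity_on_same_anthropometry(self, fixture_model):
        a = AnthropometrySpec(75.0, 1.80)
        out = apply_strength_scaling(fixture_model, a, a)
        for k in fixture_model.strength:
            assert out.strength[k].max_isometric_force == pytest.approx(
                fixture_model.strength[k].max_isometric_force)

    def test_uniform_volume_ratio_across_muscles(self, fixture_model):
        generic = AnthropometrySpec(75.0, 1.80)
        bigger = AnthropometrySpec(90.0, 1.90)
        out = apply_strength_scaling(fixture_model, bigger, generic)
        expected = handsfield_volume(bigger) / handsfield_volume(generic)
        for k in fixture_model.strength:
            ratio = out.strength[k].max_isometric_force / \
                fixture_model.strength[k].max_isometric_force
            assert ratio == pytest.approx(expected)

    def test_two_muscle_toy_hand_checked(self, fixture_model):
        """Fiber-length change enters inversely (PCSA logic)."""
        generic = AnthropometrySpec(75.0, 1.80)
        participant = AnthropometrySpec(90.0, 1.80)
        l_gen = fixture_model.strength["psoas"].optimal_fiber_length
        out = apply_strength_scaling(
            fixture_model, participant, generic,
            scaled_fiber_lengths={"psoas": 1.2 * l_gen})
        v_ratio = handsfield_volume(participant) / handsfield_volume(generic)
        got = out.strength["psoas"].max_isometric_force / \
            fixture_model.strength["psoas"].max_isometric_force
        assert got == pytest.approx(v_ratio / 1.2)

    def test_missing_fraction_rejected(self, fixture_model):
        with pytest.raises(ValueError, match="fraction"):
            apply_strength_scaling(fixture_model, AnthropometrySpec(75, 1.8),
                                   AnthropometrySpec(75, 1.8),
                                   generic_fractions={"psoas": 1.0})
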