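"""Bone-geometry measures: lengths, pelvis dimensions, angles, repeatability."""

import numpy as np
import pytest

from conftest import random_rotation
from mskwarp.core import (LandmarkSet, femur_landmark_positions,
                          tibia_landmark_positions)
from mskwarp.anthropometry import (bone_angles, femoral_torsion, landmark_repeatability,
                                   neck_shaft_angle, pelvis_dimensions,
                                   point_differences, segment_lengths, tibial_torsion)
from mskwarp.frames import build_frames, localize


def femur_set(side="r", **kw):
    lm = femur_landmark_positions(side, **kw)
    return LandmarkSet([f"{k}_{side}" for k in lm], np.array(list(lm.values())),
                       "ISB_global", "m")


def tibia_set(side="r", **kw):
    lm = tibia_landmark_positions(side, **kw)
    return LandmarkSet([f"{k}_{side}" for k in lm], np.array(list(lm.values())),
                       "ISB_global", "m")


class TestSegmentLengths:
    def test_fixture_lengths_match_joint_centers(self, fixture_model):
        sl = segment_lengths(fixture_model, "r")
        hip = fixture_model.joint("hip_r").center_global
        knee = fixture_model.joint("knee_r").center_global
        assert sl["femur_length"] == pytest.approx(np.linalg.norm(hip - knee))
        assert sl["femur_tibia_ratio"] == pytest.approx(
            sl["femur_length"] / sl["tibia_length"])

    def test_scaling_scales_lengths_not_ratio(self, fixture_model):
        m = fixture_model.copy()
        for j in m.joints:
            j.center_global = j.center_global * 2.0
        sl0 = segment_lengths(fixture_model, "r")
        sl2 = segment_lengths(m, "r")
        assert sl2["femur_length"] == pytest.approx(2 * sl0["femur_length"])
        assert sl2["femur_tibia_ratio"] == pytest.approx(sl0["femur_tibia_ratio"])


class TestPelvisDimensions:
    def test_toy_pelvis_hand_arithmetic(self, template):
        """Distances agree with coordinates read straight off the template."""
        dims = pelvis_dimensions(template.landmarks)
        ls = template.landmarks
        assert dims["ASIS_dist"] == pytest.approx(
            1000 * np.linalg.norm(ls.get("ASIS_r") - ls.get("ASIS_l")))
        # hand arithmetic: ASIS at z = +/-0.12 m, same x, y
        assert dims["ASIS_dist"] == pytest.approx(240.0)
        assert dims["IschTuber_dist"] == pytest.approx(120.0)

    def test_bilateral_distances_along_z_midline_in_plane(self, template):
        ls = template.landmarks
        d = ls.get("ASIS_r") - ls.get("ASIS_l")
        assert abs(d[0]) < 1e-12 and abs(d[1]) < 1e-12
        for name in ("pubic_symphysis_sup", "torso_origin"):
            assert abs(ls.get(name)[2]) < 1e-12

    def test_rigid_invariance(self, template, rng):
        Q = random_rotation(rng)
        moved = template.landmarks.with_coords(
            template.landmarks.coords @ Q.T + rng.normal(size=3))
        d0 = pelvis_dimensions(template.landmarks)
        d1 = pelvis_dimensions(moved)
        for k in d0:
            assert d1[k] == pytest.approx(d0[k], abs=1e-9)

    def test_missing_landmark_raises(self, template):
        sub = template.landmarks.subset(
            [n for n in template.landmarks.names if n != "torso_origin"])
        with pytest.raises(KeyError):
            pelvis_dimensions(sub)


class TestBoneAngles:
    @pytest.mark.parametrize("side", ["r", "l"])
    @pytest.mark.parametrize("av,nsa", [(15.0, 125.0), (25.0, 135.0), (0.0, 120.0),
                                        (-10.0, 115.0)])
    def test_femur_construction_oracle(self, side, av, nsa):
        """Parametrically built femora measure back their construction angles."""
        ls = femur_set(side, anteversion_deg=av, neck_shaft_deg=nsa)
        assert femoral_torsion(ls, side) == pytest.approx(av, abs=1e-6)
        assert neck_shaft_angle(ls, side) == pytest.approx(nsa, abs=1e-6)

    @pytest.mark.parametrize("side", ["r", "l"])
    @pytest.mark.parametrize("torsion", [0.0, 10.0, 20.0, -15.0])
    def test_tibia_construction_oracle(self, side, torsion):
        ls = tibia_set(side, torsion_deg=torsion)
        assert tibial_torsion(ls, side) == pytest.approx(torsion, abs=1e-6)

    def test_mirrored_limb_same_signed_magnitude(self):
        """The left limb, built as the mirror image, reports the same signed
        angles under the side-aware conventions."""
        r = femur_set("r", anteversion_deg=17.0, neck_shaft_deg=128.0)
        l = femur_set("l", anteversion_deg=17.0, neck_shaft_deg=128.0)
        assert femoral_torsion(l, "l") == pytest.approx(femoral_torsion(r, "r"), abs=1e-9)

    def test_chirality_flip_on_raw_mirror(self):
        """Mirroring a right tibia's coordinates and measuring it as a right
        tibia flips the torsion sign, equal magnitude."""
        ls = tibia_set("r", torsion_deg=20.0)
        mirrored = ls.with_coords(ls.coords * np.array([1.0, 1.0, -1.0]))
        assert tibial_torsion(mirrored, "r") == pytest.approx(-20.0, abs=1e-6)

    def test_rigid_and_scale_invariance(self, rng):
        ls = femur_set("r", anteversion_deg=13.0, neck_shaft_deg=127.0)
        Q = random_rotation(rng)
        s = rng.uniform(0.5, 2.0)
        moved = ls.with_coords(s * (ls.coords @ Q.T) + rng.normal(size=3))
        for fn in (femoral_torsion, neck_shaft_angle):
            assert fn(moved, "r") == pytest.approx(fn(ls, "r"), abs=1e-9)

    def test_degenerate_projection_rejected(self):
        lm = femur_landmark_positions("r")
        # put the neck base on the femur axis -> neck parallel to shaft axis
        lm["femoral_neck_base"] = lm["femoral_head_center"] + np.array([0.0, 0.05, 0.0])
        ls = LandmarkSet([f"{k}_r" for k in lm], np.array(list(lm.values())),
                         "ISB_global", "m")
        with pytest.raises(ValueError, match="degenerate projection"):
            femoral_torsion(ls, "r")

    def test_perpendicular_projections_give_90_deg(self):
        """Synthetic femur whose projected neck is orthogonal to the condyles."""
        ls = femur_set("r", anteversion_deg=90.0, neck_shaft_deg=125.0)
        assert femoral_torsion(ls, "r") == pytest.approx(90.0, abs=1e-6)


class TestPointDifferences:
    def _localized(self, model):
        return localize(model, build_frames(model.landmarks))

    def test_identical_models_zero(self, fixture_model):
        loc = self._localized(fixture_model)
        rep = point_differences(loc, loc)
        assert rep["mean_mm"] == 0.0
        assert all(v == 0.0 for g in rep["per_muscle"].values() for v in g.values())

    def test_single_offset_is_345(self, fixture_model):
        loc = self._localized(fixture_model)
        other = loc.copy()
        other.muscle("psoas").point("P1").position += np.array([0.003, 0.004, 0.0])
        rep = point_differences(loc, other)
        assert rep["per_muscle"]["psoas"]["P1"] == pytest.approx(5.0)

    def test_name_mismatch_rejected(self, fixture_model):
        loc = self._localized(fixture_model)
        other = loc.copy()
        other.muscle("psoas").points[1].label = "renamed"
        with pytest.raises(ValueError, match="differ"):
            point_differences(loc, other)


class TestRepeatability:
    def test_identical_sessions_zero(self, template):
        rep = landmark_repeatability([template.landmarks, template.landmarks.copy()])
        assert rep["mean_mm"] == 0.0 and rep["sd_mm"] == 0.0

    def test_uniform_offset(self, template):
        shifted = template.landmarks.with_coords(
            template.landmarks.coords + np.array([0.002, 0.0, 0.0]))
        rep = landmark_repeatability([template.landmarks, shifted])
        assert rep["mean_mm"] == pytest.approx(2.0)
        assert rep["sd_mm"] == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_noise_matches_closed_form(self, template, rng):
        """Mean distance between two noisy copies follows the 3D normal
        distance law E|N(0, 2 s^2 I3)| = 2 s sqrt(2/pi) * sqrt(2)... computed
        from the chi distribution with 3 dof."""
        s = 1.2  # mm per session
        n_rep = 40
        base = template.landmarks.to_mm()
        means = []
        for _ in range(n_rep):
            a = base.with_coords(base.coords + rng.normal(scale=s, size=base.coords.shape))
            b = base.with_coords(base.coords + rng.normal(scale=s, size=base.coords.shape))
            means.append(landmark_repeatability([a, b])["mean_mm"])
        observed = np.mean(means)
        # difference of two sessions ~ N(0, 2 s^2 I3); E||.|| = sigma_d * 2*sqrt(2/pi)
        # with sigma_d = s*sqrt(2): chi_3 mean = 2*sqrt(2/pi)
        expected = s * np.sqrt(2.0) * 2.0 * np.sqrt(2.0 / np.pi)
        assert observed == pytest.approx(expected, rel=0.02)

    def test_subgroup_report_present(self, template, rng):
        a = template.landmarks.to_mm()
        b = a.with_coords(a.coords + rng.normal(scale=1.0, size=a.coords.shape))
        rep = landmark_repeatability([a, b])
        assert "patella" in rep["subgroups"]

    def test_mismatched_sessions_rejected(self, template):
        sub = template.landmarks.subset(template.landmarks.names[:-1])
        with pytest.raises(ValueError, match="different"):
            landmark_repeatability([template.landmarks, sub])
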