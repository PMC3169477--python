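import dataclasses

import numpy as np
import pytest

from heartvol.geometry import Pose, ValidationError
from heartvol.phantom import (
    Appendage,
    HeartPhantom,
    analytic_mass,
    analytic_volume,
    make_phantom,
    slice_lax,
    slice_sax,
    voxel_volume,
)


class TestMakePhantom:
    @pytest.mark.parametrize("preset,lo,hi", [("canine", 18.0, 29.0),
                                              ("human", 78.0, 276.0)])
    def test_preset_edv_in_reported_range(self, preset, lo, hi):
        for seed in range(8):
            ph = make_phantom(preset, seed=seed)
            assert lo <= analytic_volume(ph) <= hi

    def test_canine_mass_scale(self):
        for seed in range(8):
            assert 90.0 <= analytic_mass(make_phantom("canine", seed=seed)) <= 110.0

    def test_deterministic_for_fixed_seed(self):
        a, b = make_phantom("canine", seed=11), make_phantom("canine", seed=11)
        assert a.lv_endo_semiaxes == b.lv_endo_semiaxes
        assert a.lv_epi_semiaxes == b.lv_epi_semiaxes

    def test_invalid_wall_rejected(self):
        with pytest.raises(ValidationError, match="epicardial"):
            HeartPhantom((20, 20, 40), (19, 25, 45), 0.6, (12, 12, 14))

    def test_unknown_preset(self):
        with pytest.raises(ValidationError, match="preset"):
            make_phantom("porcine", seed=0)


class TestAnalyticVolume:
    def test_untruncated_ellipsoid_closed_form(self):
        ph = HeartPhantom((15, 15, 45), (20, 20, 50), 1.0, (10, 10, 12))
        assert analytic_volume(ph) * 1000 == pytest.approx(
            4 / 3 * np.pi * 15 * 15 * 45, rel=1e-12)

    def test_sphere_closed_form(self):
        ph = HeartPhantom((10, 10, 10), (14, 14, 14), 1.0, (8, 8, 9))
        assert analytic_volume(ph) * 1000 == pytest.approx(4188.79, rel=1e-5)

    def test_truncation_formula(self):
        a, b, c, f = 14.0, 13.0, 30.0, 0.6
        ph = HeartPhantom((a, b, c), (a + 9, b + 9, c + 9), f, (12, 12, 14))
        expected = np.pi * a * b * c * (2 / 3 + f - f ** 3 / 3) / 1000
        assert analytic_volume(ph) == pytest.approx(expected, rel=1e-12)

    def test_tilted_base_matches_voxel_oracle(self):
        ph = make_phantom("canine", seed=0, mitral_tilt=15.0)
        vx = voxel_volume(ph, resolution=0.15)
        assert analytic_volume(ph) == pytest.approx(vx, rel=2e-3)

    def test_appendage_volume_matches_voxel_oracle(self):
        ph = make_phantom("canine", seed=5, with_appendage=True)
        vx = voxel_volume(ph, "LA", resolution=0.1)
        assert analytic_volume(ph, "LA") == pytest.approx(vx, rel=1e-3)

    def test_es_strictly_smaller_endocardial_volumes(self, canine):
        assert analytic_volume(canine, "LV", "endo", "ES") < \
            analytic_volume(canine, "LV", "endo", "ED")
        assert analytic_volume(canine, "LA", "endo", "ES") < \
            analytic_volume(canine, "LA", "endo", "ED")


class TestAnalyticMass:
    def test_wall_volume_times_density(self, canine):
        wall = analytic_volume(canine, "LV", "epi", "ES") - \
            analytic_volume(canine, "LV", "endo", "ES")
        assert analytic_mass(canine, "ES") == pytest.approx(
            wall * canine.myocardial_density, rel=1e-12)

    def test_zero_density(self, canine):
        ph = dataclasses.replace(canine, myocardial_density=0.0)
        assert analytic_mass(ph) == 0.0

    def test_mass_phase_invariant(self, canine):
        # the ES epicardium contracts to conserve wall volume exactly
        assert analytic_mass(canine, "ED") == pytest.approx(
            analytic_mass(canine, "ES"), rel=1e-9)

    def test_matches_voxel_wall_volume(self, canine):
        vx = (voxel_volume(canine, "LV", "epi", "ES", 0.15) -
              voxel_volume(canine, "LV", "endo", "ES", 0.15))
        assert analytic_mass(canine, "ES") == pytest.approx(vx * 1.05, rel=2e-3)


class TestSliceSax:
    def test_sphere_sections_are_circles(self, sphere_phantom):
        stack = slice_sax(sphere_phantom, 5.0, 0.0).select("LV", "endo", "ED")
        for c in stack.contours:
            z = float(c.plane.origin[2])
            r = np.hypot(*c.vertices.T)
            assert np.allclose(r, np.sqrt(400.0 - z ** 2), rtol=1e-9)

    def test_clinical_spacing(self, canine):
        stack = slice_sax(canine, 8.0, 2.0).select("LV", "endo", "ED")
        zs = sorted(float(c.plane.origin[2]) for c in stack.contours)
        assert np.allclose(np.diff(zs), 10.0)

    def test_plane_missing_chamber_emits_nothing(self, sphere_phantom):
        stack = slice_sax(sphere_phantom, 5.0, 0.0).select("LV", "endo", "ED")
        assert all(abs(float(c.plane.origin[2])) < 20.0 for c in stack.contours)

    def test_invalid_thickness(self, canine):
        with pytest.raises(ValidationError):
            slice_sax(canine, 0.0, 0.0)

    def test_pose_invariant_areas(self, canine):
        rotated = dataclasses.replace(
            canine, pose=Pose.from_axis_angle([0, 1, 0], 33.0, [10, -4, 2]))
        a0 = [c.area for c in slice_sax(canine, 8, 0).contours]
        a1 = [c.area for c in slice_sax(rotated, 8, 0).contours]
        assert np.allclose(a0, a1, rtol=1e-12)

    def test_atrial_spare_slice_available(self, canine):
        stack = slice_sax(canine, 8.0, 2.0)
        spares = [c for c in stack.extra_basal if c.layer == "endo"]
        assert len(spares) == 1
        assert spares[0].index_or_angle == -1.0


class TestSliceLax:
    def test_default_angles(self, canine):
        lax = slice_lax(canine, 6)
        assert lax.plane_angles == (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)

    def test_axisymmetric_contours_congruent(self, revolution_phantom):
        lax = slice_lax(revolution_phantom, 6).select("LV", "endo", "ED")
        areas = [c.area for c in lax.contours]
        assert np.allclose(areas, areas[0], rtol=1e-9)

    def test_appendage_between_planes_invisible(self):
        ph = make_phantom("canine", seed=5, with_appendage=True)
        assert ph.la_appendage.angular_center == 15.0
        areas = {c.index_or_angle: c.area
                 for c in slice_lax(ph, 6).contours if c.chamber == "LA"}
        bare = dataclasses.replace(ph, la_appendage=None)
        areas_bare = {c.index_or_angle: c.area
                      for c in slice_lax(bare, 6).contours if c.chamber == "LA"}
        assert areas == pytest.approx(areas_bare)

    def test_appendage_on_plane_changes_exactly_one_contour(self):
        ph = make_phantom("canine", seed=5, with_appendage=True)
        on_plane = dataclasses.replace(
            ph, la_appendage=dataclasses.replace(ph.la_appendage, angular_center=30.0))
        bare = dataclasses.replace(ph, la_appendage=None)
        a1 = {c.index_or_angle: c.area
              for c in slice_lax(on_plane, 6).contours if c.chamber == "LA"}
        a0 = {c.index_or_angle: c.area
              for c in slice_lax(bare, 6).contours if c.chamber == "LA"}
        changed = [k for k in a0 if abs(a1[k] - a0[k]) > 1e-6]
        assert changed == [30.0]

    def test_too_few_planes(self, canine):
        with pytest.raises(ValidationError):
            slice_lax(canine, 1)


class TestVoxelOracle:
    def test_sphere(self):
        ph = HeartPhantom((10, 10, 10), (14, 14, 14), 1.0, (8, 8, 9))
        assert voxel_volume(ph, resolution=0.1) * 1000 == pytest.approx(
            4188.79, rel=2e-3)

    def test_error_non_increasing_with_resolution(self, revolution_phantom):
        truth = analytic_volume(revolution_phantom)
        errs = [abs(voxel_volume(revolution_phantom, resolution=r) - truth)
                for r in (0.8, 0.4, 0.2)]
        assert errs[0] >= errs[1] >= errs[2]

    def test_agrees_with_analytic_across_presets(self):
        for seed in range(6):
            ph = make_phantom("canine" if seed % 2 else "human", seed=seed)
            assert voxel_volume(ph, resolution=0.2) == pytest.approx(
                analytic_volume(ph), rel=3e-3)

    def test_tiny_chamber_warns(self, caplog):
        ph = HeartPhantom((0.5, 0.5, 0.5), (5, 5, 5), 1.0, (1, 1, 1))
        with caplog.at_level("WARNING", logger="heartvol.phantom"):
            voxel_volume(ph, resolution=0.5)
        assert any("voxel" in r.message for r in caplog.records)


class TestAppendageValidation:
    def test_window_must_fit_axially(self):
        with pytest.raises(ValidationError, match="axial"):
            HeartPhantom((14, 14, 30), (23, 23, 39), 0.6, (12, 12, 14),
                         la_appendage=Appendage(5.0, 0.0, 20.0, 10.0, 12.0))
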