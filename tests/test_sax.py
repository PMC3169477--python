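import dataclasses

import numpy as np
import pytest

from heartvol.geometry import Contour, Line3, Plane, SaxStack, ValidationError
from heartvol.phantom import (
    analytic_mass,
    analytic_volume,
    make_phantom,
    slice_sax,
    voxel_volume,
)
from heartvol.sax import (
    clip_basal,
    function_params,
    mass_sax,
    polygon_area,
    stack_volume,
)


def _xy_plane(z):
    return Plane([0, 0, z], [0, 0, 1], np.array([[1, 0], [0, 1], [0, 0]]))


def _mitral(z, tilt_deg=0.0):
    t = np.deg2rad(tilt_deg)
    return Plane([0, 0, z], [0, -np.sin(t), np.cos(t)],
                 np.column_stack([[1, 0, 0], [0, np.cos(t), np.sin(t)]]))


_AXIS = Line3([0, 0, 0], [0, 0, 1])


def _circle_stack(areas, thickness, gap, z0=20.0):
    """Stack of circular contours with the given areas, mitral plane above."""
    contours = []
    for i, area in enumerate(areas):
        r = np.sqrt(area / np.pi)
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        verts = r * np.column_stack([np.cos(th), np.sin(th)])
        z = z0 - (thickness + gap) * (i + 0.5)
        contours.append(Contour(_xy_plane(z), verts, "LV", "endo", "ED", float(i)))
    return SaxStack(tuple(contours), thickness, gap, _mitral(z0), _AXIS)


class TestPolygonArea:
    def test_unit_square(self, unit_square):
        assert polygon_area(unit_square) == 1.0

    def test_reversed_orientation(self, unit_square):
        assert polygon_area(unit_square[::-1]) == 1.0

    def test_360gon_approximates_circle(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        verts = 20 * np.column_stack([np.cos(th), np.sin(th)])
        assert polygon_area(verts) == pytest.approx(np.pi * 400, rel=1e-4)

    def test_too_few_vertices(self):
        with pytest.raises(ValidationError):
            polygon_area(np.array([[0, 0], [1, 0]]))


class TestClipBasal:
    def _square_contour(self, z=0.0, side=20.0):
        s = side / 2
        verts = np.array([[-s, -s], [s, -s], [s, s], [-s, s]])
        return Contour(_xy_plane(z), verts, "LV", "endo", "ED", 0)

    def test_mitral_above_slice_keeps_contour(self):
        c = self._square_contour(z=0.0)
        assert clip_basal(c, _mitral(5.0), _AXIS) is c

    def test_mitral_below_slice_removes_contour(self):
        c = self._square_contour(z=10.0)
        assert clip_basal(c, _mitral(5.0), _AXIS) is None

    def test_oblique_plane_through_center_halves_area(self):
        # mitral plane tilted 45 deg about x crosses the z=5 slice at y=0
        c = self._square_contour(z=5.0)
        out = clip_basal(c, _mitral(5.0, tilt_deg=45.0), _AXIS)
        assert out.area == pytest.approx(c.area / 2, rel=1e-9)
        # the base plane rises with +y here, so the kept (ventricular)
        # half-square is the y >= 0 side
        assert out.vertices[:, 1].min() == pytest.approx(0.0, abs=1e-9)


class TestStackVolume:
    def test_slice_summation_arithmetic(self):
        stack = _circle_stack([100.0, 100.0, 100.0], 10.0, 0.0)
        assert stack_volume(stack, clip=False) == pytest.approx(3.0, rel=1e-4)

    def test_gap_volume_attributed_to_slice(self):
        stack = _circle_stack([100.0, 100.0, 100.0], 8.0, 2.0)
        assert stack_volume(stack, clip=False) == pytest.approx(3.0, rel=1e-4)

    def test_sphere_fine_slices_near_closed_form(self):
        from heartvol.phantom import HeartPhantom
        ph = HeartPhantom((10, 10, 10), (14, 14, 14), 1.0, (8, 8, 9))
        stack = slice_sax(ph, 1.0, 0.0).select("LV", "endo", "ED")
        assert stack_volume(stack) == pytest.approx(4.18879, rel=0.01)

    def test_mixed_labels_rejected(self, canine):
        stack = slice_sax(canine, 8.0, 0.0)  # LV endo+epi and LA together
        with pytest.raises(ValidationError, match="single chamber"):
            stack_volume(stack)

    def test_in_plane_rigid_motion_invariance(self):
        stack = _circle_stack([120.0, 90.0, 40.0], 5.0, 0.0)
        th = np.deg2rad(17.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = dataclasses.replace(stack, contours=tuple(
            c.with_vertices(c.vertices @ R.T + [3.0, -7.0]) for c in stack.contours))
        assert stack_volume(moved, clip=False) == pytest.approx(
            stack_volume(stack, clip=False), rel=1e-12)

    def test_error_shrinks_with_thickness(self):
        """Finer slicing tracks the analytic truth better (bias mechanism)."""
        ph = make_phantom("canine", seed=4)
        truth = analytic_volume(ph)
        errs = [abs(stack_volume(slice_sax(ph, t, 0.0).select("LV", "endo", "ED"))
                    - truth) for t in (10.0, 5.0, 1.0)]
        assert errs[0] > errs[2]

    def test_clip_improves_accuracy_with_tilted_base(self):
        errs = {True: [], False: []}
        for s in range(6):
            ph = make_phantom("canine", seed=s, mitral_tilt=15.0)
            vx = voxel_volume(ph, resolution=0.3)
            st = slice_sax(ph, 5.0, 0.0).select("LV", "endo", "ED")
            for clip in (True, False):
                errs[clip].append(abs(stack_volume(st, clip=clip) - vx))
        assert np.mean(errs[True]) < np.mean(errs[False])


class TestMassSax:
    def test_identical_stacks_zero_mass(self):
        stack = _circle_stack([100.0, 80.0], 10.0, 0.0)
        endo = dataclasses.replace(stack, contours=tuple(
            dataclasses.replace(c, layer="endo") for c in stack.contours))
        epi = dataclasses.replace(stack, contours=tuple(
            dataclasses.replace(c, layer="epi") for c in stack.contours))
        assert mass_sax(endo, epi) == pytest.approx(0.0, abs=1e-12)

    def test_epi_smaller_than_endo_rejected(self):
        big = _circle_stack([100.0, 80.0], 10.0, 0.0)
        small = _circle_stack([50.0, 40.0], 10.0, 0.0)
        small = dataclasses.replace(small, contours=tuple(
            dataclasses.replace(c, layer="epi") for c in small.contours))
        with pytest.raises(ValidationError, match="epicardial"):
            mass_sax(big, small)

    def test_canine_fine_slices_recover_analytic_mass(self, canine):
        es = slice_sax(canine, 5.0, 0.0, "ES")
        m = mass_sax(es.select("LV", "endo", "ES"), es.select("LV", "epi", "ES"))
        assert m == pytest.approx(analytic_mass(canine), rel=0.03)


class TestFunctionParams:
    @pytest.mark.parametrize("edv,esv,sv,ef", [
        (120.0, 48.0, 72.0, 60.0),
        (100.0, 100.0, 0.0, 0.0),
        (80.0, 0.0, 80.0, 100.0),
    ])
    def test_arithmetic(self, edv, esv, sv, ef):
        vs = function_params(edv, esv)
        assert (vs.sv, vs.ef) == (pytest.approx(sv), pytest.approx(ef))

    def test_zero_edv_undefined(self):
        with pytest.raises(ValidationError, match="undefined"):
            function_params(0.0, 0.0)

    def test_esv_above_edv_warns_negative_ef(self):
        with pytest.warns(UserWarning, match="negative EF"):
            vs = function_params(50.0, 60.0)
        assert vs.ef < 0
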