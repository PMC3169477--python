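"""Parametric digital heart phantoms with analytically known volumes.

The left ventricle (LV) is a truncated ellipsoid: endocardial and
epicardial surfaces are concentric ellipsoids cut by a basal (mitral)
plane, which may be tilted relative to the short-axis plane. The left
atrium (LA) is an ellipsoid sitting basal to the mitral plane, optionally
carrying a radial "appendage" bump — a smooth, compactly supported
raised-cosine outpouching, the simplest non-axisymmetric feature that a
sparse set of rotational long-axis planes can miss entirely.

Closed forms
------------
A plane cuts an ellipsoid with semi-axes (a, b, c) into two caps whose
volumes follow from mapping the ellipsoid onto the unit ball (x -> x/a,
...): the plane maps to a plane, and a unit-ball cap below signed height
h0 has volume pi*(2/3 + h0 - h0^3/3). The truncated-ellipsoid volume is
therefore exact even for a tilted mitral plane. The appendage volume has
no closed form; it is evaluated by high-resolution Simpson quadrature of
the cylindrical-shell integrand ((r0+b)^2 - r0^2)/2 over its angular and
axial support, which is part of this module's documented contract.

At end-systole the in-plane (a, b) semi-axes of the LV endocardium and of
the LA are multiplied by ``es_scale``; the epicardium contracts in-plane
by the factor that keeps the myocardial wall volume (hence mass) exactly
phase-invariant, as incompressible muscle demands. The long axis does not
shorten.

Units: mm for lengths, ml for volumes, g for mass, degrees for angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import brentq

from .geometry import (
    Chamber,
    Contour,
    GeometryError,
    LaxSet,
    Layer,
    Line3,
    Phase,
    Plane,
    Pose,
    SaxStack,
    ValidationError,
    clip_halfplane_2d,
)

__all__ = [
    "Appendage",
    "HeartPhantom",
    "make_phantom",
    "analytic_volume",
    "analytic_mass",
    "slice_sax",
    "slice_lax",
    "voxel_volume",
    "CANINE",
    "HUMAN",
]

log = logging.getLogger(__name__)

MYOCARDIAL_DENSITY = 1.05  # g/ml, literature-standard


@dataclass(frozen=True)
class Appendage:
    """Raised-cosine radial bump on the LA surface.

    The local radius gains ``amplitude * cos^2(pi*dtheta/angular_width)
    * cos^2(pi*dz/axial_width)`` inside the half-width windows around
    ``angular_center`` (deg, azimuth) and ``axial_center`` (mm, relative
    to the LA centre); outside it is exactly zero, so an appendage
    narrower than the angular gap between rotational planes placed
    between them is invisible to the long-axis method.
    """

    amplitude: float
    angular_center: float
    angular_width: float
    axial_center: float
    axial_width: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("appendage amplitude must be >= 0")
        if not (0 < self.angular_width <= 180):
            raise ValidationError("appendage angular_width must be in (0, 180] deg")
        if self.axial_width <= 0:
            raise ValidationError("appendage axial_width must be positive")

    def bump(self, theta_deg: np.ndarray, dz: np.ndarray) -> np.ndarray:
        """Radial excess (mm) at azimuth theta (deg) and axial offset dz (mm)."""
        dth = (np.asarray(theta_deg, float) - self.angular_center + 180.0) % 360.0 - 180.0
        dzz = np.asarray(dz, float) - self.axial_center
        inside = (np.abs(dth) <= self.angular_width / 2.0) & \
                 (np.abs(dzz) <= self.axial_width / 2.0)
        out = np.zeros(np.broadcast(dth, dzz).shape)
        ct = np.cos(np.pi * dth / self.angular_width) ** 2
        cz = np.cos(np.pi * dzz / self.axial_width) ** 2
        np.copyto(out, self.amplitude * ct * cz, where=inside)
        return out


@dataclass(frozen=True)
class HeartPhantom:
    """A parametric LV + LA geometry with analytically known ground truth.

    In the anatomical frame the long axis is +z, the LV ellipsoids are
    centred at the origin, the base is at larger z and the apex at
    smaller z. ``lv_truncation_fraction`` is the fraction of the basal
    half of the endocardial ellipsoid retained above the equator, so the
    mitral plane crosses the long axis at z = fraction * c_endo.
    """

    lv_endo_semiaxes: tuple[float, float, float]
    lv_epi_semiaxes: tuple[float, float, float]
    lv_truncation_fraction: float
    la_semiaxes: tuple[float, float, float]
    la_appendage: Appendage | None = None
    mitral_tilt: float = 0.0          # deg, about the +x axis
    es_scale: float = 0.65            # radial endocardial scaling at ES
    myocardial_density: float = MYOCARDIAL_DENSITY  # g/ml
    la_gap: float = 2.0               # mm between mitral plane and LA bottom pole
    pose: Pose = field(default_factory=Pose)

    def __post_init__(self) -> None:
        for name in ("lv_endo_semiaxes", "lv_epi_semiaxes", "la_semiaxes"):
            ax = tuple(float(x) for x in getattr(self, name))
            if len(ax) != 3 or any(x <= 0 for x in ax):
                raise ValidationError(f"{name} must be three positive lengths")
            object.__setattr__(self, name, ax)
        if any(e <= i for e, i in zip(self.lv_epi_semiaxes, self.lv_endo_semiaxes)):
            raise ValidationError(
                "epicardial semi-axes must strictly exceed endocardial semi-axes "
                "(positive wall thickness everywhere)")
        if not (0 < self.lv_truncation_fraction <= 1):
            raise ValidationError("lv_truncation_fraction must be in (0, 1]")
        if not (0 < self.es_scale < 1):
            raise ValidationError("es_scale must be in (0, 1)")
        if self.myocardial_density < 0:
            raise ValidationError("myocardial_density must be >= 0")
        if abs(self.mitral_tilt) >= 60:
            raise ValidationError("mitral_tilt must satisfy |tilt| < 60 deg")
        if self.la_appendage is not None:
            c = self.la_semiaxes[2]
            app = self.la_appendage
            if abs(app.axial_center) + app.axial_width / 2.0 > 0.85 * c:
                raise ValidationError(
                    "appendage axial window must stay within 85% of the LA axial extent")

    # ---- derived geometry (anatomical frame) -------------------------------

    @property
    def basal_z(self) -> float:
        """z of the mitral plane on the long axis."""
        return self.lv_truncation_fraction * self.lv_endo_semiaxes[2]

    @property
    def mitral_normal(self) -> np.ndarray:
        """Unit normal of the mitral plane, pointing atrial-ward (+z-ish)."""
        t = np.deg2rad(self.mitral_tilt)
        return np.array([0.0, -np.sin(t), np.cos(t)])

    @property
    def la_center_z(self) -> float:
        return self.basal_z + self.la_gap + self.la_semiaxes[2]

    def semiaxes(self, chamber: Chamber, layer: Layer = "endo",
                 phase: Phase = "ED") -> tuple[float, float, float]:
        if chamber == "LV":
            ax = self.lv_epi_semiaxes if layer == "epi" else self.lv_endo_semiaxes
            if phase == "ES":
                if layer == "endo":
                    return (ax[0] * self.es_scale, ax[1] * self.es_scale, ax[2])
                k = _es_epi_scale(self.lv_epi_semiaxes, self.lv_endo_semiaxes,
                                  self.es_scale, self.basal_z,
                                  tuple(self.mitral_normal))
                return (ax[0] * k, ax[1] * k, ax[2])
            return ax
        if layer != "endo":
            raise ValidationError("the LA has no epicardial surface in this phantom")
        ax = self.la_semiaxes
        if phase == "ES":
            return (ax[0] * self.es_scale, ax[1] * self.es_scale, ax[2])
        return ax

    def center_z(self, chamber: Chamber) -> float:
        return 0.0 if chamber == "LV" else self.la_center_z

    def mitral_plane(self) -> Plane:
        n = self.pose.vector(self.mitral_normal)
        t = np.deg2rad(self.mitral_tilt)
        b1 = self.pose.vector(np.array([1.0, 0.0, 0.0]))
        b2 = self.pose.vector(np.array([0.0, np.cos(t), np.sin(t)]))
        return Plane(self.pose.point(np.array([0.0, 0.0, self.basal_z])), n,
                     np.column_stack([b1, b2]))

    def long_axis(self) -> Line3:
        return Line3(self.pose.point(np.zeros(3)),
                     self.pose.vector(np.array([0.0, 0.0, 1.0])))


from functools import lru_cache


@lru_cache(maxsize=1024)
def _es_epi_scale(epi: tuple[float, float, float], endo: tuple[float, float, float],
                  es_scale: float, basal_z: float,
                  normal: tuple[float, float, float]) -> float:
    """In-plane epicardial contraction factor conserving wall volume at ES."""
    n = np.array(normal)
    v_epi_ed = _ellipsoid_halfspace_volume(epi, 0.0, n, basal_z)
    v_endo_ed = _ellipsoid_halfspace_volume(endo, 0.0, n, basal_z)
    v_endo_es = _ellipsoid_halfspace_volume(
        (endo[0] * es_scale, endo[1] * es_scale, endo[2]), 0.0, n, basal_z)
    target = v_endo_es + (v_epi_ed - v_endo_ed)

    def gap(k: float) -> float:
        return _ellipsoid_halfspace_volume((epi[0] * k, epi[1] * k, epi[2]),
                                           0.0, n, basal_z) - target

    return float(brentq(gap, 0.05, 1.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# presets

@dataclass(frozen=True)
class _Preset:
    """Sampling ranges for randomized phantoms at a given anatomical scale.

    Volume targets are drawn first, shape ratios second, and the wall
    thickness is solved so the end-systolic mass hits its target; this
    guarantees the analytic ground truth lands in the preset's range.
    """

    edv_ml: tuple[float, float]
    mass_g: tuple[float, float]
    la_ml: tuple[float, float]
    long_axis_ratio: tuple[float, float]   # c/a of the LV endocardium
    axis_ratio: tuple[float, float]        # b/a in-plane eccentricity
    truncation: tuple[float, float]
    es_scale: tuple[float, float]
    la_long_axis_ratio: tuple[float, float]


#: Canine-scale ranges (ex-vivo arm): LV cavity ~23 ml, LA ~12 ml, mass ~100 g.
CANINE = _Preset(
    edv_ml=(19.0, 28.0), mass_g=(94.0, 105.0), la_ml=(8.0, 16.0),
    long_axis_ratio=(2.0, 2.3), axis_ratio=(0.92, 1.0), truncation=(0.55, 0.65),
    es_scale=(0.60, 0.70), la_long_axis_ratio=(1.2, 1.5),
)

#: Human-scale ranges (clinical arm): LVEDV ~120-240 ml.
HUMAN = _Preset(
    edv_ml=(120.0, 240.0), mass_g=(110.0, 180.0), la_ml=(50.0, 90.0),
    long_axis_ratio=(1.7, 2.0), axis_ratio=(0.90, 1.0), truncation=(0.55, 0.65),
    es_scale=(0.60, 0.70), la_long_axis_ratio=(1.2, 1.5),
)

_PRESETS = {"canine": CANINE, "human": HUMAN}


def _truncation_gain(f: float) -> float:
    """Retained fraction integrand: V = pi*a*b*c*(2/3 + f - f^3/3)."""
    return 2.0 / 3.0 + f - f ** 3 / 3.0


def make_phantom(preset: str | _Preset = "canine", seed: int = 0,
                 axisymmetric: bool = False, with_appendage: bool = False,
                 mitral_tilt: float = 0.0, pose: Pose | None = None,
                 density: float = MYOCARDIAL_DENSITY) -> HeartPhantom:
    """Draw a randomized phantom whose analytic truth matches the preset scale.

    Parameters
    ----------
    preset : "canine", "human" or a _Preset with explicit sampling ranges.
    seed : controls every random draw; a fixed seed gives a fixed phantom.
    axisymmetric : force a = b (solid of revolution when untilted and
        appendage-free).
    with_appendage : attach an LA appendage of angular width < 30 deg
        centred between the default rotational planes (at 15 deg).
    """
    if isinstance(preset, str):
        try:
            ranges = _PRESETS[preset]
        except KeyError:
            raise ValidationError(
                f"unknown preset {preset!r}; expected one of {sorted(_PRESETS)}") from None
    else:
        ranges = preset
    rng = np.random.default_rng(seed)
    edv = rng.uniform(*ranges.edv_ml) * 1000.0          # mm^3
    aspect = rng.uniform(*ranges.long_axis_ratio)
    ba = 1.0 if axisymmetric else rng.uniform(*ranges.axis_ratio)
    f = rng.uniform(*ranges.truncation)
    es = rng.uniform(*ranges.es_scale)
    mass = rng.uniform(*ranges.mass_g)

    a = (edv / (np.pi * ba * aspect * _truncation_gain(f))) ** (1.0 / 3.0)
    b, c = ba * a, aspect * a

    la_v = rng.uniform(*ranges.la_ml) * 1000.0
    la_aspect = rng.uniform(*ranges.la_long_axis_ratio)
    la_ba = 1.0 if axisymmetric else rng.uniform(*ranges.axis_ratio)
    la_a = (la_v / (4.0 / 3.0 * np.pi * la_ba * la_aspect)) ** (1.0 / 3.0)
    la = (la_a, la_ba * la_a, la_aspect * la_a)

    appendage = None
    if with_appendage:
        # angular support 28 deg < the 30 deg inter-plane gap, centred at 15 deg
        appendage = Appendage(amplitude=0.8 * la_a, angular_center=15.0,
                              angular_width=28.0, axial_center=0.0,
                              axial_width=1.2 * la[2])

    def es_mass(t: float) -> float:
        ph = HeartPhantom((a, b, c), (a + t, b + t, c + t), f, la,
                          mitral_tilt=mitral_tilt, es_scale=es,
                          myocardial_density=density)
        return analytic_mass(ph, phase="ES") - mass

    t_wall = brentq(es_mass, 0.2, 40.0, xtol=1e-10)
    return HeartPhantom(
        lv_endo_semiaxes=(a, b, c),
        lv_epi_semiaxes=(a + t_wall, b + t_wall, c + t_wall),
        lv_truncation_fraction=f,
        la_semiaxes=la,
        la_appendage=appendage,
        mitral_tilt=mitral_tilt,
        es_scale=es,
        myocardial_density=density,
        pose=pose if pose is not None else Pose(),
    )


# ---------------------------------------------------------------------------
# analytic ground truth

def _ellipsoid_halfspace_volume(semiaxes: Sequence[float], center_z: float,
                                normal: np.ndarray, plane_z: float) -> float:
    """Volume (mm^3) of {ellipsoid} cut to the side where n.(p - p0) <= 0.

    The ellipsoid is centred at (0, 0, center_z); p0 = (0, 0, plane_z).
    Exact via the unit-ball cap formula under the affine map x -> x/a.
    """
    a, b, c = semiaxes
    n = np.asarray(normal, float)
    h = float(n @ np.array([0.0, 0.0, plane_z - center_z]))
    m = np.array([n[0] * a, n[1] * b, n[2] * c])
    h0 = h / np.linalg.norm(m)
    if h0 >= 1.0:
        frac = 4.0 * np.pi / 3.0
    elif h0 <= -1.0:
        frac = 0.0
    else:
        frac = np.pi * (2.0 / 3.0 + h0 - h0 ** 3 / 3.0)
    return a * b * c * frac


def _appendage_volume(phantom: HeartPhantom, phase: Phase,
                      n_theta: int = 801, n_z: int = 801) -> float:
    """Appendage excess volume (mm^3) by 2-D Simpson quadrature.

    Integrates the cylindrical shell ((r0 + bump)^2 - r0^2)/2 over the
    bump's compact angular x axial support. Grid resolution is fixed and
    fine enough that the result is converged well below 0.1%.
    """
    app = phantom.la_appendage
    if app is None or app.amplitude == 0.0:
        return 0.0
    a, b, c = phantom.semiaxes("LA", "endo", phase)
    th = np.deg2rad(np.linspace(app.angular_center - app.angular_width / 2.0,
                                app.angular_center + app.angular_width / 2.0, n_theta))
    dz = np.linspace(app.axial_center - app.axial_width / 2.0,
                     app.axial_center + app.axial_width / 2.0, n_z)
    TH, DZ = np.meshgrid(th, dz, indexing="ij")
    s2 = np.clip(1.0 - (DZ / c) ** 2, 0.0, None)
    q = 1.0 / np.sqrt(np.cos(TH) ** 2 / a ** 2 + np.sin(TH) ** 2 / b ** 2)
    r0 = np.sqrt(s2) * q
    bump = app.bump(np.rad2deg(TH), DZ)
    integrand = ((r0 + bump) ** 2 - r0 ** 2) / 2.0
    return float(simpson(simpson(integrand, x=dz, axis=1), x=th))


def analytic_volume(phantom: HeartPhantom, chamber: Chamber = "LV",
                    layer: Layer = "endo", phase: Phase = "ED") -> float:
    """Closed-form chamber volume in ml (exact for appendage-free phantoms).

    LV volumes are truncated-ellipsoid cap volumes (exact, tilt included);
    the LA is a full ellipsoid plus, when present, the appendage volume by
    the quadrature documented in ``_appendage_volume``.
    """
    ax = phantom.semiaxes(chamber, layer, phase)
    if chamber == "LV":
        v = _ellipsoid_halfspace_volume(ax, 0.0, phantom.mitral_normal,
                                        phantom.basal_z)
    else:
        v = 4.0 / 3.0 * np.pi * ax[0] * ax[1] * ax[2]
        v += _appendage_volume(phantom, phase)
    return v / 1000.0


def analytic_mass(phantom: HeartPhantom, phase: Phase = "ES") -> float:
    """LV myocardial mass in g: (epi - endo cavity volume) x density."""
    v_epi = analytic_volume(phantom, "LV", "epi", phase)
    v_endo = analytic_volume(phantom, "LV", "endo", phase)
    return (v_epi - v_endo) * phantom.myocardial_density


# ---------------------------------------------------------------------------
# slicing

def _sax_plane(phantom: HeartPhantom, z0: float) -> Plane:
    pose = phantom.pose
    return Plane(pose.point(np.array([0.0, 0.0, z0])),
                 pose.vector(np.array([0.0, 0.0, 1.0])),
                 np.column_stack([pose.vector(np.array([1.0, 0.0, 0.0])),
                                  pose.vector(np.array([0.0, 1.0, 0.0]))]))


def _lv_section(phantom: HeartPhantom, layer: Layer, phase: Phase, z0: float,
                n_vertices: int) -> np.ndarray | None:
    a, b, c = phantom.semiaxes("LV", layer, phase)
    s2 = 1.0 - (z0 / c) ** 2
    if s2 <= 1e-12:
        return None
    s = np.sqrt(s2)
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([a * s * np.cos(th), b * s * np.sin(th)])


def _la_section(phantom: HeartPhantom, phase: Phase, z0: float,
                n_vertices: int) -> np.ndarray | None:
    a, b, c = phantom.semiaxes("LA", "endo", phase)
    dz = z0 - phantom.la_center_z
    s2 = 1.0 - (dz / c) ** 2
    if s2 <= 1e-12:
        return None
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    q = 1.0 / np.sqrt(np.cos(th) ** 2 / a ** 2 + np.sin(th) ** 2 / b ** 2)
    r = np.sqrt(s2) * q
    if phantom.la_appendage is not None:
        r = r + phantom.la_appendage.bump(np.rad2deg(th), np.full_like(th, dz))
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def slice_sax(phantom: HeartPhantom, thickness: float, gap: float = 0.0,
              phase: Phase = "ED", n_vertices: int = 360,
              anchor_offset: float = 0.0,
              chambers: Sequence[Chamber] = ("LV", "LA")) -> SaxStack:
    """Cut a short-axis stack of exact conic-section contours.

    Slice planes are perpendicular to the long axis at spacing
    ``thickness + gap``; the basal-most LV plane centre sits half a
    spacing (plus ``anchor_offset``) apical to the mitral plane, mimicking
    a technologist planning full coverage. Planes continue atrial-ward to
    cover the LA. LV contours are emitted for planes whose centre lies
    apical to the mitral plane at the long-axis crossing; one atrial-side
    spare LV contour (when the geometry extends there) is stored in
    ``extra_basal`` for the basal-misassignment perturbation.
    """
    if thickness <= 0:
        raise ValidationError("slice thickness must be positive")
    if gap < 0:
        raise ValidationError("slice gap must be non-negative")
    spacing = thickness + gap
    zb = phantom.basal_z
    z_top_lv = zb - spacing / 2.0 - anchor_offset
    c_epi = phantom.lv_epi_semiaxes[2]
    la_top = phantom.la_center_z + phantom.la_semiaxes[2] + \
        (phantom.la_appendage.amplitude if phantom.la_appendage else 0.0)

    i_min = -int(np.ceil((la_top - z_top_lv) / spacing)) - 1
    i_max = int(np.ceil((z_top_lv + c_epi) / spacing)) + 1

    contours: list[Contour] = []
    extra: list[Contour] = []
    for i in range(i_min, i_max + 1):
        z0 = z_top_lv - i * spacing
        plane = _sax_plane(phantom, z0)
        if "LV" in chambers:
            for layer in ("endo", "epi"):
                verts = _lv_section(phantom, layer, phase, z0, n_vertices)
                if verts is None:
                    continue
                contour = Contour(plane, verts, "LV", layer, phase, float(i))
                if i >= 0 and z0 < zb:
                    contours.append(contour)
                elif i == -1:
                    extra.append(contour)
        if "LA" in chambers:
            verts = _la_section(phantom, phase, z0, n_vertices)
            if verts is not None:
                contours.append(Contour(plane, verts, "LA", "endo", phase, float(i)))
    return SaxStack(tuple(contours), thickness, gap, phantom.mitral_plane(),
                    phantom.long_axis(), tuple(extra))


def _lax_plane(phantom: HeartPhantom, angle_deg: float) -> Plane:
    al = np.deg2rad(angle_deg)
    e1 = np.array([np.cos(al), np.sin(al), 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    n = np.array([np.sin(al), -np.cos(al), 0.0])
    pose = phantom.pose
    return Plane(pose.point(np.zeros(3)), pose.vector(n),
                 np.column_stack([pose.vector(e1), pose.vector(e2)]))


def _ellipse_radius(a: float, b: float, angle_deg: float) -> float:
    al = np.deg2rad(angle_deg)
    return 1.0 / np.sqrt(np.cos(al) ** 2 / a ** 2 + np.sin(al) ** 2 / b ** 2)


def _lv_lax_contour(phantom: HeartPhantom, layer: Layer, phase: Phase,
                    angle_deg: float, n_vertices: int) -> np.ndarray | None:
    """Full (u, z) ellipse section clipped at the mitral plane."""
    a, b, c = phantom.semiaxes("LV", layer, phase)
    q = _ellipse_radius(a, b, angle_deg)
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack([q * np.cos(t), c * np.sin(t)])
    # ventricular side of the (possibly tilted) mitral plane, in (u, z):
    # (z - zb)*cos(tau) - y*sin(tau) <= 0 with y = u*sin(azimuth)
    tau = np.deg2rad(phantom.mitral_tilt)
    al = np.deg2rad(angle_deg)
    m = np.array([-np.sin(tau) * np.sin(al), np.cos(tau)])
    offset = -phantom.basal_z * np.cos(tau)
    return clip_halfplane_2d(verts, m, offset)


def _la_lax_contour(phantom: HeartPhantom, phase: Phase, angle_deg: float,
                    n_vertices: int) -> np.ndarray | None:
    a, b, c = phantom.semiaxes("LA", "endo", phase)
    zc = phantom.la_center_z
    m = max(n_vertices // 2 + 1, 8)
    t = np.linspace(0.0, np.pi, m)
    pts: list[np.ndarray] = []
    for az, sign, ts in ((angle_deg, 1.0, t), ((angle_deg + 180.0) % 360.0, -1.0, t[::-1][1:-1])):
        q = _ellipse_radius(a, b, az)
        z = zc + c * np.cos(ts)
        r = q * np.sin(ts)
        if phantom.la_appendage is not None:
            r = r + phantom.la_appendage.bump(np.full_like(ts, az), z - zc)
        pts.append(np.column_stack([sign * r, z]))
    return np.vstack(pts)


def slice_lax(phantom: HeartPhantom, n_planes: int = 6, phase: Phase = "ED",
              n_vertices: int = 360, angle_offset: float = 0.0,
              chambers: Sequence[Chamber] = ("LV", "LA")) -> LaxSet:
    """Cut rotational long-axis contours on planes containing the long axis.

    Planes sit at azimuths ``angle_offset + k*180/n_planes``; the default
    six planes reproduce the clinical 30-degree rotational protocol. LV
    contours include the straight basal truncation edge where the mitral
    plane cuts the ellipse section.
    """
    if n_planes < 2:
        raise ValidationError("rotational volumetry needs n_planes >= 2")
    angles = sorted((angle_offset + k * 180.0 / n_planes) % 180.0
                    for k in range(n_planes))
    contours: list[Contour] = []
    for al in angles:
        plane = _lax_plane(phantom, al)
        if "LV" in chambers:
            for layer in ("endo", "epi"):
                verts = _lv_lax_contour(phantom, layer, phase, al, n_vertices)
                if verts is not None:
                    contours.append(Contour(plane, verts, "LV", layer, phase, al))
        if "LA" in chambers:
            verts = _la_lax_contour(phantom, phase, al, n_vertices)
            if verts is not None:
                contours.append(Contour(plane, verts, "LA", "endo", phase, al))
    return LaxSet(tuple(contours), tuple(angles), phantom.long_axis())


# ---------------------------------------------------------------------------
# voxel oracle

def voxel_volume(phantom: HeartPhantom, chamber: Chamber = "LV",
                 layer: Layer = "endo", phase: Phase = "ED",
                 resolution: float = 0.5) -> float:
    """Brute-force volume in ml: voxel centres inside x resolution^3.

    The independent oracle for every other volume computation. Evaluated
    in the anatomical frame (rigid pose does not change volumes),
    vectorized one z-slab at a time.
    """
    if resolution <= 0:
        raise ValidationError("voxel resolution must be positive")
    a, b, c = phantom.semiaxes(chamber, layer, phase)
    zc = phantom.center_z(chamber)
    margin = phantom.la_appendage.amplitude \
        if (chamber == "LA" and phantom.la_appendage) else 0.0
    r = resolution

    xs = np.arange(-(a + margin) + r / 2.0, a + margin, r)
    ys = np.arange(-(b + margin) + r / 2.0, b + margin, r)
    zs = np.arange(zc - c + r / 2.0, zc + c, r)
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    count = 0
    if chamber == "LV":
        E = (X / a) ** 2 + (Y / b) ** 2
        tau = np.deg2rad(phantom.mitral_tilt)
        zb = phantom.basal_z
        for z in zs:
            lim = 1.0 - (z / c) ** 2
            if lim <= 0:
                continue
            mask = E <= lim
            if phantom.mitral_tilt != 0.0:
                mask &= (z - zb) * np.cos(tau) - Y * np.sin(tau) <= 0
            elif z > zb:
                continue
            count += int(np.count_nonzero(mask))
    else:
        R = np.hypot(X, Y)
        TH = np.rad2deg(np.arctan2(Y, X))
        q = 1.0 / np.sqrt(np.cos(np.deg2rad(TH)) ** 2 / a ** 2 +
                          np.sin(np.deg2rad(TH)) ** 2 / b ** 2)
        app = phantom.la_appendage
        for z in zs:
            s2 = 1.0 - ((z - zc) / c) ** 2
            lim = np.sqrt(s2) * q if s2 > 0 else np.zeros_like(q)
            if app is not None:
                lim = lim + app.bump(TH, np.full_like(TH, z - zc))
            count += int(np.count_nonzero(R <= lim))
    if count < 100:
        log.warning("voxel oracle counted only %d voxels at %.3g mm resolution; "
                    "result is unreliable", count, resolution)
    return count * r ** 3 / 1000.0
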