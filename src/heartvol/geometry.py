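"""Planes, contours and contour collections.

All lengths are millimetres. The anatomical frame puts the left-ventricular
long axis on +z with the base (mitral plane) at larger z and the apex at
smaller z; azimuths are measured from +x, right-handed. A rigid ``Pose``
maps the anatomical frame into the scanner frame.

Contours are ordered planar polygons: vertices are 2-D coordinates in the
plane's orthonormal in-plane basis, implicitly closed (the first vertex
follows the last). Polygon primitives (area, simplicity, half-plane
clipping) are backed by shapely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShPolygon

__all__ = [
    "Pose",
    "Line3",
    "Plane",
    "Contour",
    "SaxStack",
    "LaxSet",
    "ValidationError",
    "GeometryError",
    "shoelace_area",
    "is_simple_polygon",
    "clip_halfplane_2d",
]

Chamber = Literal["LV", "LA"]
Layer = Literal["endo", "epi"]
Phase = Literal["ED", "ES"]

_TOL = 1e-9


class ValidationError(ValueError):
    """An object violates a documented invariant."""


class GeometryError(ValueError):
    """A geometric precondition is not met."""


def _as_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < _TOL:
        raise ValidationError(f"{name} has zero length")
    return v / n


@dataclass(frozen=True)
class Pose:
    """Rigid transform (rotation then translation) anatomical -> scanner."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("pose needs a 3x3 rotation and length-3 translation")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValidationError("pose rotation is not a proper rotation matrix")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def point(self, p: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(p, dtype=float) + self.translation

    def vector(self, v: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(v, dtype=float)

    @staticmethod
    def from_axis_angle(axis: Sequence[float], angle_deg: float,
                        translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "Pose":
        a = _as_unit(np.asarray(axis, float), "axis")
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        return Pose(R, np.asarray(translation, float))


@dataclass(frozen=True)
class Line3:
    """A 3-D line: point + unit direction (the long axis)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", _as_unit(self.direction, "line direction"))


@dataclass(frozen=True)
class Plane:
    """Oriented plane with an orthonormal in-plane basis.

    A 2-D point ``(u, v)`` maps to ``origin + u*basis[:,0] + v*basis[:,1]``.
    """

    origin: np.ndarray
    normal: np.ndarray
    basis: np.ndarray  # (3, 2)

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        n = _as_unit(self.normal, "plane normal")
        B = np.asarray(self.basis, dtype=float)
        if B.shape != (3, 2):
            raise ValidationError("plane basis must be 3x2")
        if not np.allclose(B.T @ B, np.eye(2), atol=1e-8):
            raise ValidationError("plane basis vectors must be orthonormal")
        if np.any(np.abs(n @ B) > 1e-8):
            raise ValidationError("plane basis must be orthogonal to the normal")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "basis", B)

    def to_world(self, verts2d: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(verts2d, dtype=float))
        return self.origin + v @ self.basis.T

    def to_plane(self, pts3d: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts3d, dtype=float))
        return (p - self.origin) @ self.basis


def shoelace_area(vertices: np.ndarray) -> float:
    """Absolute polygon area (mm^2) of an implicitly closed vertex list."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValidationError("polygon needs >= 3 two-dimensional vertices")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def is_simple_polygon(vertices: np.ndarray) -> bool:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        return False
    return _ShPolygon(v).is_valid


def clip_halfplane_2d(vertices: np.ndarray, normal2d: np.ndarray,
                      offset: float) -> np.ndarray | None:
    """Clip a polygon to the half-plane ``{p : normal2d . p + offset <= 0}``.

    Returns the clipped vertex array, or None when nothing (with positive
    area) survives. The clip keeps the straight chord along the cut.
    """
    v = np.asarray(vertices, dtype=float)
    m = np.asarray(normal2d, dtype=float)
    nm = np.linalg.norm(m)
    if nm < _TOL:
        raise GeometryError("degenerate half-plane normal")
    m = m / nm
    off = offset / nm
    s = v @ m + off
    if np.all(s <= _TOL):
        return v
    if np.all(s >= -_TOL):
        return None
    # big rectangle covering the keep side
    span = float(np.max(np.abs(v))) + abs(off) + 10.0
    L = 4.0 * span
    t = np.array([-m[1], m[0]])
    x0 = -off * m  # a point on the boundary line
    rect = np.array([x0 + L * t, x0 - L * t, x0 - L * t - L * m, x0 + L * t - L * m])
    out = _ShPolygon(v).buffer(0).intersection(_ShPolygon(rect))
    if out.is_empty:
        return None
    if out.geom_type == "MultiPolygon":
        out = max(out.geoms, key=lambda g: g.area)
    if out.area < 1e-9:
        return None
    verts = np.asarray(out.exterior.coords)[:-1]
    if len(verts) < 3:
        return None
    return verts


@dataclass(frozen=True)
class Contour:
    """One closed, simple planar polygon with chamber/layer/phase labels."""

    plane: Plane
    vertices: np.ndarray  # (n, 2) in-plane mm
    chamber: Chamber
    layer: Layer
    phase: Phase
    index_or_angle: float  # slice index (SAX) or plane azimuth in deg (LAX)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("contour vertices must be an (n, 2) array")
        if len(v) < 3:
            raise ValidationError("contour needs at least 3 vertices")
        if self.chamber not in ("LV", "LA"):
            raise ValidationError(f"unknown chamber {self.chamber!r}")
        if self.layer not in ("endo", "epi"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.phase not in ("ED", "ES"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        if not is_simple_polygon(v):
            raise ValidationError("contour polygon is self-intersecting")
        if shoelace_area(v) <= 0:
            raise ValidationError("contour encloses no area")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        """Enclosed area in mm^2."""
        return shoelace_area(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        c = _ShPolygon(self.vertices).centroid
        return np.array([c.x, c.y])

    def world_vertices(self) -> np.ndarray:
        return self.plane.to_world(self.vertices)

    def with_vertices(self, vertices: np.ndarray) -> "Contour":
        return replace(self, vertices=np.asarray(vertices, dtype=float))


def _check_same_labels(contours: Sequence[Contour]) -> None:
    labels = {(c.chamber, c.layer, c.phase) for c in contours}
    if len(labels) > 1:
        raise ValidationError(f"contours mix chamber/layer/phase labels: {sorted(labels)}")


@dataclass(frozen=True)
class SaxStack:
    """Parallel short-axis contours perpendicular to the long axis.

    ``extra_basal`` holds the atrial-side spare slice contours used by the
    basal-misassignment perturbation; they do not contribute to volumes.
    """

    contours: tuple[Contour, ...]
    thickness: float
    gap: float
    mitral_plane: Plane
    long_axis: Line3
    extra_basal: tuple[Contour, ...] = ()

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValidationError("slice thickness must be positive")
        if self.gap < 0:
            raise ValidationError("slice gap must be non-negative")
        object.__setattr__(self, "contours", tuple(self.contours))
        object.__setattr__(self, "extra_basal", tuple(self.extra_basal))
        d = self.long_axis.direction
        for c in self.contours:
            if abs(abs(float(c.plane.normal @ d)) - 1.0) > 1e-6:
                raise ValidationError("SAX slice planes must be perpendicular to the long axis")

    @property
    def spacing(self) -> float:
        """Effective inter-slice spacing: thickness + gap (mm)."""
        return self.thickness + self.gap

    def select(self, chamber: Chamber, layer: Layer = "endo",
               phase: Phase = "ED") -> "SaxStack":
        keep = tuple(c for c in self.contours
                     if (c.chamber, c.layer, c.phase) == (chamber, layer, phase))
        spare = tuple(c for c in self.extra_basal
                      if (c.chamber, c.layer, c.phase) == (chamber, layer, phase))
        return replace(self, contours=keep, extra_basal=spare)


@dataclass(frozen=True)
class LaxSet:
    """Radial long-axis contours on planes sharing the long axis."""

    contours: tuple[Contour, ...]
    plane_angles: tuple[float, ...]
    long_axis: Line3

    def __post_init__(self) -> None:
        object.__setattr__(self, "contours", tuple(self.contours))
        angles = tuple(float(a) for a in self.plane_angles)
        if any(not (0.0 <= a < 180.0) for a in angles):
            raise ValidationError("LAX plane angles must lie in [0, 180)")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValidationError("LAX plane angles must be strictly increasing")
        object.__setattr__(self, "plane_angles", angles)
        p0, d = self.long_axis.point, self.long_axis.direction
        for c in self.contours:
            if abs(float(c.plane.normal @ d)) > 1e-6 or \
               abs(float((p0 - c.plane.origin) @ c.plane.normal)) > 1e-6:
                raise ValidationError("every LAX plane must contain the long axis")

    def select(self, chamber: Chamber, layer: Layer = "endo",
               phase: Phase = "ED") -> "LaxSet":
        keep = tuple(c for c in self.contours
                     if (c.chamber, c.layer, c.phase) == (chamber, layer, phase))
        return replace(self, contours=keep)
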