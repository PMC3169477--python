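"""Short-axis volumetry: slice summation with cross-referenced basal clipping.

The short-axis (SAX) method sums per-slice cross-sectional areas times the
effective slice spacing (thickness + gap; the gap's volume is attributed
to its slice). The dominant subtlety is the basal slice: blood on the
atrial side of the mitral plane must be excluded while the outflow-tract
side is included, which a reader achieves by cross-referencing a
perpendicular long-axis view. Here the cross-reference is formalized as a
polygon/half-plane clip of the basal contour along the line where the
mitral plane crosses the slice plane.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (
    Chamber,
    Contour,
    Line3,
    Plane,
    SaxStack,
    ValidationError,
    clip_halfplane_2d,
    shoelace_area,
)

__all__ = ["VolumeSet", "polygon_area", "clip_basal", "stack_volume",
           "mass_sax", "function_params"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumeSet:
    """Global function parameters for one heart/chamber/method.

    edv/esv/sv in ml, ef in percent, mass in g.
    """

    edv: float
    esv: float
    sv: float
    ef: float
    mass: float
    method: str
    chamber: Chamber = "LV"

    def __post_init__(self) -> None:
        if not np.isclose(self.sv, self.edv - self.esv, atol=1e-9):
            raise ValidationError("stroke volume must equal EDV - ESV")
        if self.edv > 0 and not np.isclose(self.ef, 100.0 * self.sv / self.edv,
                                           atol=1e-9):
            raise ValidationError("EF must equal 100*SV/EDV")
        if not np.isnan(self.mass) and self.mass < 0:
            raise ValidationError("mass must be >= 0")


def polygon_area(contour: Contour | np.ndarray) -> float:
    """Absolute (orientation-independent) shoelace area in mm^2."""
    verts = contour.vertices if isinstance(contour, Contour) else contour
    return shoelace_area(verts)


def clip_basal(contour: Contour, mitral_plane: Plane,
               long_axis: Line3) -> Contour | None:
    """Keep the ventricular part of a basal SAX contour.

    The mitral plane (possibly oblique to the slice) cuts the slice plane
    along a line; the sub-polygon on the ventricular side — the side of
    the mitral plane toward the apex, i.e. opposite the long-axis
    direction — is returned. None means the whole contour is atrial;
    the contour comes back unchanged when the mitral plane does not cross
    it. A degenerate clip (< 3 vertices) also returns None and is logged.
    """
    n = mitral_plane.normal
    if float(n @ long_axis.direction) < 0:
        n = -n  # orient atrial-ward (toward the base)
    B, o = contour.plane.basis, contour.plane.origin
    m = B.T @ n                       # 2-D trace of the half-space
    offset = float((o - mitral_plane.origin) @ n)
    if np.linalg.norm(m) < 1e-9:      # mitral plane parallel to the slice
        return contour if offset <= 0 else None
    verts = clip_halfplane_2d(contour.vertices, m, offset)
    if verts is None or len(verts) < 3:
        if verts is None:
            log.debug("basal clip removed the whole contour (fully atrial)")
        else:
            log.info("degenerate basal clip (<3 vertices); contour dropped")
        return None
    if len(verts) == len(contour.vertices) and np.array_equal(verts, contour.vertices):
        return contour
    return contour.with_vertices(verts)


def stack_volume(stack: SaxStack, clip: bool = True) -> float:
    """Slice-summation (Simpson) volume in ml.

    Every contour in the stack must share one chamber/layer/phase (use
    ``SaxStack.select`` first). Each slice contributes area x
    (thickness + gap); with ``clip`` enabled, contours crossed by the
    mitral plane are clipped to their ventricular sub-polygon first and
    fully atrial contours drop out.
    """
    contours = stack.contours
    if not contours:
        return 0.0
    labels = {(c.chamber, c.layer, c.phase) for c in contours}
    if len(labels) > 1:
        raise ValidationError(
            f"stack_volume needs a single chamber/layer/phase, got {sorted(labels)}")
    total = 0.0
    for c in contours:
        if clip and c.chamber == "LV":
            c = clip_basal(c, stack.mitral_plane, stack.long_axis)
            if c is None:
                continue
        total += c.area * stack.spacing
    return total / 1000.0


def mass_sax(endo_stack: SaxStack, epi_stack: SaxStack,
             density: float = 1.05, clip: bool = True) -> float:
    """LV mass in g from endo/epi SAX stacks: wall volume x density."""
    phases = {c.phase for c in endo_stack.contours} | \
             {c.phase for c in epi_stack.contours}
    if len(phases) > 1:
        raise ValidationError(f"endo and epi stacks mix phases: {sorted(phases)}")
    if not np.isclose(endo_stack.spacing, epi_stack.spacing):
        raise ValidationError("endo and epi stacks must share slice spacing")
    v_endo = stack_volume(endo_stack, clip=clip)
    v_epi = stack_volume(epi_stack, clip=clip)
    if v_epi < v_endo:
        raise ValidationError(
            f"epicardial volume ({v_epi:.2f} ml) below endocardial ({v_endo:.2f} ml)")
    return (v_epi - v_endo) * density


def function_params(edv: float, esv: float, mass: float = float("nan"),
                    method: str = "SAX", chamber: Chamber = "LV") -> VolumeSet:
    """Assemble EDV/ESV into SV and EF.

    EF is 100*(EDV-ESV)/EDV; ``edv = 0`` is undefined and raises, and
    ``esv > edv`` is physically suspect — it warns and reports a negative
    EF so the caller can decide.
    """
    if edv == 0:
        raise ValidationError("EF is undefined for EDV = 0")
    if esv < 0 or edv < 0:
        raise ValidationError("volumes must be non-negative")
    if esv > edv:
        warnings.warn("ESV exceeds EDV; reporting a negative EF", stacklevel=2)
    sv = edv - esv
    return VolumeSet(edv=edv, esv=esv, sv=sv, ef=100.0 * sv / edv,
                     mass=mass, method=method, chamber=chamber)
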