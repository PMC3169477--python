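"""Observer-variability emulation: smooth contour perturbation and basal
slice misassignment.

A human reader's contour differs from the true boundary by a smooth,
spatially correlated error rather than white jitter, so each vertex is
displaced radially (about the contour centroid) by a periodic Gaussian
random field with standard deviation ``radial_sd`` and angular
correlation length ``smoothness_scale``. The dominant short-axis specific
error reported for slice-summation volumetry — including or excluding
the most basal slice — is modelled separately as an integer
``basal_shift`` (or, for stochastic observers, a per-seed draw with
probability ``basal_shift_prob``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    Contour,
    LaxSet,
    SaxStack,
    ValidationError,
    is_simple_polygon,
)

__all__ = ["NoiseModel", "perturb"]

_MAX_RETRIES = 20
_N_HARMONICS = 32


@dataclass(frozen=True)
class NoiseModel:
    """Parameters of one simulated observer.

    radial_sd : mm, pointwise SD of the radial contour displacement.
    smoothness_scale : deg, angular correlation length of the error field.
    basal_shift : +1 include one extra atrial-side slice, -1 drop the true
        basal slice, 0 none (SAX stacks only).
    basal_shift_prob : probability that a stochastic observer mis-assigns
        the basal slice (sign equiprobable); overrides ``basal_shift``
        when positive.
    seed : makes the observer deterministic.
    """

    radial_sd: float = 0.0
    smoothness_scale: float = 30.0
    basal_shift: int = 0
    basal_shift_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radial_sd < 0:
            raise ValidationError("radial_sd must be >= 0")
        if self.smoothness_scale <= 0:
            raise ValidationError("smoothness_scale must be positive")
        if self.basal_shift not in (-1, 0, 1):
            raise ValidationError("basal_shift must be -1, 0 or +1")
        if not (0.0 <= self.basal_shift_prob <= 1.0):
            raise ValidationError("basal_shift_prob must be a probability")


def _smooth_radial_field(theta: np.ndarray, radial_sd: float,
                         smoothness_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean periodic field with SD radial_sd at every point."""
    ell = np.deg2rad(smoothness_deg)
    k = np.arange(_N_HARMONICS + 1)
    w = np.exp(-0.5 * (k * ell) ** 2)
    s = radial_sd * w / np.sqrt(np.sum(w ** 2))
    a = rng.standard_normal(_N_HARMONICS + 1)
    b = rng.standard_normal(_N_HARMONICS + 1)
    b[0] = 0.0
    ang = np.outer(theta, k)
    return (np.cos(ang) * (s * a) + np.sin(ang) * (s * b)).sum(axis=1)


def _perturb_contour(contour: Contour, noise: NoiseModel,
                     seed_seq: np.random.SeedSequence) -> Contour:
    centroid = contour.centroid
    rel = contour.vertices - centroid
    r = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    unit = np.column_stack([np.cos(theta), np.sin(theta)])
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng(seed_seq.spawn(1)[0] if attempt else seed_seq)
        d = _smooth_radial_field(theta, noise.radial_sd, noise.smoothness_scale, rng)
        new_r = r + d
        if np.min(new_r) <= 0.05 * np.mean(r):
            continue
        verts = centroid + new_r[:, None] * unit
        if is_simple_polygon(verts):
            return contour.with_vertices(verts)
    raise ValidationError(
        f"could not produce a simple perturbed polygon after {_MAX_RETRIES} tries "
        f"(radial_sd={noise.radial_sd} mm is likely too large for this contour)")


def _draw_shift(noise: NoiseModel, rng: np.random.Generator) -> int:
    if noise.basal_shift_prob > 0.0:
        if rng.random() < noise.basal_shift_prob:
            return int(rng.choice([-1, 1]))
        return 0
    return noise.basal_shift


def perturb(obj: SaxStack | LaxSet, noise: NoiseModel) -> SaxStack | LaxSet:
    """Apply one simulated observer to a contour collection.

    Deterministic for a fixed ``noise.seed``; with ``radial_sd = 0`` and
    no basal shift the input is returned unchanged (bitwise identity).
    Self-intersecting perturbations are retried with fresh sub-seeds a
    bounded number of times, then raise.
    """
    if isinstance(obj, LaxSet):
        if noise.radial_sd == 0.0:
            return obj
        contours = tuple(
            _perturb_contour(c, noise, np.random.SeedSequence([noise.seed, 1, i]))
            for i, c in enumerate(obj.contours))
        return replace(obj, contours=contours)
    if not isinstance(obj, SaxStack):
        raise ValidationError("perturb expects a SaxStack or LaxSet")

    shift_rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 2]))
    shift = _draw_shift(noise, shift_rng)
    contours = list(obj.contours)
    extra = list(obj.extra_basal)
    if shift == +1 and extra:
        contours.extend(extra)
        extra = []
    elif shift == -1:
        lv_idx = [c.index_or_angle for c in contours if c.chamber == "LV"]
        if lv_idx:
            basal = min(lv_idx)
            contours = [c for c in contours
                        if not (c.chamber == "LV" and c.index_or_angle == basal)]
    if shift == 0 and noise.radial_sd == 0.0:
        return obj
    if noise.radial_sd > 0.0:
        contours = [
            _perturb_contour(c, noise, np.random.SeedSequence([noise.seed, 3, i]))
            for i, c in enumerate(contours)]
        extra = [
            _perturb_contour(c, noise, np.random.SeedSequence([noise.seed, 4, i]))
            for i, c in enumerate(extra)]
    return replace(obj, contours=tuple(contours), extra_basal=tuple(extra))
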