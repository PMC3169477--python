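# Methods

## The phantom

The left ventricle is modelled as two concentric ellipsoids (endocardial
and epicardial surfaces) cut by a basal "mitral" plane; the left atrium
as a separate ellipsoid sitting basal to that plane. This is the
simplest family that (i) has closed-form volumes, (ii) can be truncated
obliquely (a tilted mitral plane, to exercise basal clipping), and
(iii) can be made non-axisymmetric — unequal in-plane semi-axes, plus an
optional LA "appendage" bump — to exercise the angular-sampling
behaviour of rotational volumetry. Papillary muscles, trabeculation and
the right ventricle are deliberately absent (see Limitations).

Conventions: the anatomical long axis is +z, base at larger z, apex at
smaller z; azimuths from +x, right-handed; lengths in mm, volumes in ml,
mass in g, angles in degrees. A rigid pose maps the anatomical frame to
the scanner frame; slicing is planned relative to the anatomical axis,
so all volumetric results are pose-invariant by construction (covered by
tests).

### Closed forms

A plane cuts an ellipsoid with semi-axes (a, b, c) into caps whose
volumes follow from the affine map onto the unit ball: a unit-ball cap
below signed height h₀ has volume π(2/3 + h₀ − h₀³/3), so the truncated
LV volume is exact even with a tilted basal plane. With truncation
fraction f (basal plane at z = f·c) and no tilt this reduces to
V = π a b c (2/3 + f − f³/3).

The LA appendage is a compactly-supported raised-cosine radial bump,
amplitude · cos²(πΔθ/w_θ) · cos²(πΔz/w_z) inside its angular/axial
half-width windows and exactly zero outside. Compact support is the
point: an appendage whose angular support lies strictly between two
rotational planes contributes nothing to any sampled radius, which is
the geometric mechanism behind rotational underestimation of LA volume.
(A Gaussian bump would leak into every plane and blur that mechanism.)
The appendage volume has no closed form; it is evaluated by 2-D Simpson
quadrature of the cylindrical-shell integrand ((r₀+b)² − r₀²)/2 on a
fixed 801×801 grid over the support, converged well below 0.1% (checked
against the voxel oracle at 0.1 mm).

### Contraction

At end-systole the endocardial (and LA) in-plane semi-axes scale by
`es_scale` (default draw 0.60–0.70, giving ejection fractions near 60%);
the long axis does not shorten. The epicardium contracts in-plane by the
factor — solved exactly from the cap closed forms — that conserves wall
volume, so LV mass is phase-invariant, as incompressible myocardium
requires. Mass is nevertheless quantified at end-systole by default,
matching clinical practice.

### Presets

Two anatomical scales are provided, each a set of sampling ranges from
which `make_phantom(preset, seed)` draws deterministically:

| parameter | canine | human |
|---|---|---|
| LV EDV (ml) | 19–28 | 120–240 |
| LV mass (g) | 94–105 | 110–180 |
| LA volume (ml) | 8–16 | 50–90 |
| c/a (endo) | 2.0–2.3 | 1.7–2.0 |
| b/a | 0.92–1.0 | 0.90–1.0 |
| truncation f | 0.55–0.65 | 0.55–0.65 |
| es_scale | 0.60–0.70 | 0.60–0.70 |

Volume and mass targets are drawn first and the geometry solved from
them (the wall thickness by root-finding on the closed-form mass), so
the analytic ground truth is guaranteed to land in the preset's range.
Myocardial density is fixed at 1.05 g/ml, the literature-standard value
for muscle tissue.

## Slicing

Short-axis stacks are cut perpendicular to the long axis at spacing
thickness + gap; each contour is the exact conic section of the surface,
discretized at 360 vertices by default (polygonal-area error of a 40 mm
circle < 0.01%). The basal-most LV plane centre sits half a spacing
apical to the mitral plane — a technologist planning full coverage — and
the anchor offset is configurable for placement-sensitivity studies,
since acquisition protocols do not pin this down. One atrial-side spare
slice contour is kept aside for the basal-misassignment model. Long-axis
sets place N planes through the axis at 180°/N increments; LV contours
include the straight basal truncation edge.

## Quantification

**Slice summation** attributes each slice's area to the full effective
spacing (thickness + gap), the standard clinical convention; no
half-slice apical correction is applied, which keeps the
thickness-scaling experiment interpretable (the summation error on
smooth untruncated shapes scales as thickness², verified as a log-log
slope of 2.0 ± 0.3). A slice enters the LV sum iff its central plane is
apical to the mitral plane at the long-axis crossing; with clipping
enabled, contours crossed by an oblique mitral plane are cut to their
ventricular sub-polygon (a polygon/half-plane clip in the slice plane),
which formalizes the visual cross-referencing procedure readers use.

**Rotational volumetry** splits each contour at the axis into two radius
profiles on a common uniform level grid (256 levels over the union of
axial extents by default; doubling changes results by < 0.1%), and
integrates triangle-fan cross-sections with midpoint Δz weighting.
Where a level line crosses the boundary more than once (overhang), the
outermost crossing is used and a note logged. The chord-to-arc
correction (sector area ½ rₖ rₖ₊₁ Δθ instead of ½ rₖ rₖ₊₁ sin Δθ) is on
by default: without it every circular cross-section is underestimated by
the fixed factor sin(Δθ)/Δθ (−4.5% at 6 planes) — a formula artifact,
not a sampling property — whereas with it, solids of revolution are
recovered exactly at any N and azimuth (rotation invariance holds to
machine precision). The uncorrected variant remains available for
studying that artifact.

## Observer model

A reader's contour error is smooth and spatially correlated, not white:
vertices are displaced radially about the contour centroid by a periodic
Gaussian random field (squared-exponential spectrum over 32 harmonics)
with pointwise SD `radial_sd` (default 0.5 mm, sub-pixel at clinical
resolution) and angular correlation length `smoothness_scale` (default
30°). The field is zero-mean, so enclosed area is preserved to first
order (Monte-Carlo verified within 1% at 200 replicates). Separately,
`basal_shift` includes one extra atrial-side slice (+1) or drops the
true basal slice (−1); stochastic observers draw a shift with
probability `basal_shift_prob` (sign equiprobable). Everything is
deterministic per seed; perturbations that would self-intersect are
retried with fresh sub-seeds a bounded number of times, then raise.

In the simulated two-observer study, SAX observers carry basal-shift
noise (probability 0.5) while LAX observers carry only radial noise —
the long-axis method has no basal slice to mis-assign, which is exactly
its claimed robustness. This reproduces the direction (smaller LAX
inter-observer differences on LV volumes) of published reader studies;
magnitudes depend on the assumed noise levels and are not calibrated to
any particular reader population.

## Statistics

Differences follow the method − reference convention (negative bias =
underestimation). Limits of agreement use the conventional 1.96
multiplier (an exact-t option exists for small n, off by default).
Pearson r and the paired t test come from scipy; degenerate cases
(zero-variance differences) are handled explicitly and flagged. The
coefficient of variation is defined as 100·SD(differences)/mean of the
reference series; CV conventions vary across the literature (some
published tables even print negative "CV" values, which no standard
definition produces), so the definition used here is stated rather than
reverse-engineered from any source. No multiple-testing correction is
applied.

## What the generator does and does not emulate

It emulates: anatomically scaled LV/LA geometry at two species scales,
ED/ES phases with realistic ejection fractions, clinical and ex-vivo
slicing protocols (10/8/5 mm contiguous; 8 mm + 2 mm gap; 6 radial
planes at 30°), smooth observer noise, and basal-slice misassignment.

It does not emulate: papillary muscles and trabeculation (so the
SAX-includes/LAX-excludes convention difference for those structures is
out of reach), regional wall-motion abnormality or shape irregularity,
through-plane motion, partial-volume intensity effects (inputs are
contours, not pixels), or long-axis shortening. Passing tests therefore
demonstrate the geometric and statistical machinery on smooth-walled
anatomy, not performance on pathological shapes.

## Numerical choices

- Voxel oracle: count of voxel centres inside the implicit surface ×
  resolution³, evaluated slab-by-slab; 0.1 mm for oracle-grade checks
  (agrees with closed forms within 0.1%), 0.2–0.3 mm where it is only a
  cross-check. A warning is logged below 100 counted voxels.
- Root-finding (wall thickness, ES epicardial scale): Brent's method on
  the closed forms, tolerance 1e-10 mm.
- Polygon predicates (area, simplicity, clipping) are exact shapely
  operations; degenerate clips (< 3 vertices) yield an empty result and
  a log entry.
- Problem sizes in the test suite and acceptance script (12–20 phantoms
  per experiment, 30–50 simulated observer pairs, 256 levels, 360
  vertices) were chosen so each experiment's Monte-Carlo/discretization
  error sits well below the effect it measures.
- Seeds: study seeds derive from a master seed via counter-based seed
  sequences keyed on (stage, heart, observer, protocol, phase), so
  enlarging a study never reshuffles existing hearts; all outputs are
  byte-reproducible.

## Known limitations

- The ellipsoidal family cannot represent highly irregular ventricles,
  where rotational methods are known to degrade; conclusions about
  method ranking transfer only to reasonably regular shapes.
- LA volume at ES uses the same in-plane scale factor as the LV, a
  simplification (a real atrium expands during ventricular systole).
- The rotational integration formula in commercial packages is not
  public; the triangle-fan-with-chord-correction default here is a
  declared choice, with the uncorrected variant exposed for comparison.
- Observer noise amplitudes are plausible but uncalibrated; only
  directions of observer effects, not magnitudes, should be read from
  the simulated reader studies.
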