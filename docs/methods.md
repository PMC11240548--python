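# Methods

## Serial microregistration

A temporary surface marker (a ~10 mm tattoo-style sticker with a 2.5 × 8 mm
rectangular opening whose serrated inner edge provides sharp tips) stays on
the skin between imaging sessions. Two tips on opposite long edges of the
opening are read out as stage coordinates (µm) at every session. Two point
pairs determine a 2D similarity transform exactly, and that is the model we
fit:

- rotation `θ = angle(f₂ − f₁) − angle(b₂ − b₁)`,
- isotropic scale `s = |f₂ − f₁| / |b₂ − b₁|`,
- translation chosen so the baseline tip midpoint maps onto the follow-up
  midpoint,

where `b` and `f` are baseline and follow-up tip coordinates. Anchoring at
the midpoint makes the fit an exact interpolant of both tips and keeps the
translation estimate independent of the rotation error to first order at
the ROI, which sits near the opening centre. The physical marker cannot
stretch, so scale is retained only as a deformation check: estimates outside
`1 ± 0.05` raise a non-fatal `MarkerDeformationWarning`. Setting the
tolerance to 0 effectively enforces a rigid model.

Relocalization quality is scored two ways:

- **Radial-distance consistency** (percent): `100 · max(0, 1 − d/d_max)`
  with `d` the distance between predicted and reference ROI centres and
  `d_max = 200 µm` (one field of view). The linear map is the minimal model
  through the two defined endpoints (100 % at 0, 0 % at 200 µm); it clamps
  at zero beyond `d_max`.
- **ROI overlap fraction** for two axis-aligned squares of side `L`:
  `max(0, L−|dx|) · max(0, L−|dy|) / L²`. A 200 µm FOV relocated to within
  50 µm in both axes keeps `(150/200)² = 56.25 %` of the baseline area.
  Residual rotation of the FOV square is deliberately ignored: the stage
  translates but cannot rotate the objective, so rotation is absorbed by the
  transform before the overlap is evaluated. This is a documented
  approximation, not an oversight.

`refine_by_correlation` automates the manual fine-tuning step: it scans
integer pixel offsets within a search radius, maximizing the Pearson
normalized cross-correlation over the overlap region. Ties break toward the
smallest `|dx|+|dy|`, then smallest `dy`, then `dx`, so a flat correlation
surface yields the most conservative (smallest) shift. Peaks below 0.5 are
flagged unconfident.

`accuracy_monte_carlo` simulates repeated sessions: follow-up tip readings
are the true transform applied to the baseline tips plus isotropic Gaussian
localization noise (σ per coordinate), and each trial is re-estimated and
scored. One named, seeded generator drives each run; seeds are recorded in
reports.

## Melanin quantification (810 nm TPF, SHG-masked)

At 810 nm excitation the epidermal TPF is dominated by melanin, but elastin
at the DEJ and in the dermis fluoresces too. Elastin colocates with
collagen, and collagen alone produces SHG, so the co-registered SHG plane
identifies the dermal region to strip. Per plane:

smooth (Gaussian σ = 2 px) → Otsu threshold → morphological closing (disk
r = 3 px) → drop foreground components < 25 px → binary mask with 0 inside
collagen, 1 elsewhere → multiply into the TPF plane.

The recipe is deliberately parameter-light and deterministic; every knob is
in `MelaninConfig`. One guard is added on top: Otsu always splits a
histogram, even a pure-noise one, so a plane whose foreground/background
class separation is below `min_contrast` (default 4) background standard
deviations is declared collagen-free and returned as an all-ones mask.
Without the guard, noise-only planes above the DEJ would be shredded by a
garbage mask.

The depth profile sums masked TPF per plane over the epidermal analysis
range [top of SG, mean DEJ]. The SC is excluded because keratin fluoresces
strongly there; the top of the SG is taken as the mean SC-bottom depth (the
SG begins where the SC ends — the boundary module provides it). Masking is
applied only at depths within 10 µm above the mean DEJ (`mask_band_above_dej_um`):
the DEJ undulates by several µm, so collagen enters the view above its mean
depth, while planes far above contain no collagen and are summed as-is.
The volumetric presumed-melanin intensity is the inclusive sum over
[top-of-SG, DEJ] — a sum, not a mean, so the value is a true integral over
the stack; the per-plane mean is reported alongside for reference.
Longitudinal change is the fold change of this integral versus the baseline
session; it is a ratio of arbitrary units and carries no absolute
concentration meaning.

## Thickness from vertical sections

Ten adjacent XZ sections are sliced around the stack's mid-y row (the slice
location is a free choice; adjacency keeps the sections statistically
dependent the same way a real vertically-scanned set is). Per column, on
z-profiles smoothed with a Gaussian of σ = 2 planes:

- **surface** — shallowest depth where RCM holds ≥ 50 % of the column
  maximum for ≥ 3 consecutive planes;
- **DEJ** — same criterion on SHG (collagen exists only below the DEJ);
- **SC bottom** — shallowest depth below the surface where 810 nm TPF falls
  below 50 % of its SC-band peak (the maximum within 8 planes under the
  surface) for ≥ 3 consecutive planes.

Relative thresholds make the estimates exactly invariant to detector gain;
the 3-plane run requirement rejects isolated speckle/noise bumps, which the
z-smoothing correlates over ~2 planes. The 50 % fraction, run length, and
window are `BoundaryConfig` fields. Columns violating
surface ≤ SC bottom ≤ DEJ, or with no detectable signal, are flagged
invalid and excluded from the means — never imputed — and the report errors
if more than half the columns are invalid, since a mean over a minority of
columns would be silently biased. ET is the flat mean of (DEJ − surface)
over every valid column of every section; SC likewise; the
viable-epidermis thickness is exactly their difference.

## Blood-flow mapping

The per-pixel standard deviation over a short burst of RCM frames (10 by
default) highlights vessels: moving blood cells decorrelate the speckle
while static tissue does not. Population STD (divide by N) is used —
the frames are the entire burst, not a sample — with `ddof=1` available as
a flag. No inter-frame motion correction is applied by default;
`refine_by_correlation` can be run on the frames first if needed.
`flow_index` (mean STD inside a vessel mask) is an explicit package-defined
arbitrary-unit proxy for flow strength, not a velocity. The overlay
renders min–max-normalized STD in red over min–max-normalized SHG in cyan;
constant inputs normalize to a zero channel with a logged note.

## Cell density

Density is dots / en-face area: `area_mm2 = area_px · pixel_size² · 1e-6`.
The counted-region area travels inside the annotation file, so the density
never relies on an assumed FOV. Counting is annotation-driven by design —
the dots come from a blinded human rater — and no automatic nucleus
detector is included. The time-course table orders rows
baseline → 1h → 24h → 3d → 1w → 2w.

## The phantom

The generator renders the structures each channel reports on, at the study
geometry: 200 µm FOV at 256 px, 1 µm z-step over 120 planes, SC 12.0 µm and
total epidermal thickness 40.4 µm, DEJ undulation modeled as a 2D sinusoid
(amplitude 6 µm, period 64 µm — a controllable stand-in for the strongly
undulating real DEJ). Layer boundaries are rendered with one-plane linear
coverage ramps, so a boundary at depth `d` crosses 50 % intensity at plane
`round(d)`: threshold detection is unbiased, and exact for integer depths.

Channel content: RCM = SC (amplitude 1.0) + Voronoi-polygon cell borders
(0.6; SB cells drawn smaller than SG/SS) + dim dermis (0.1); TPF735 =
cytoplasm of viable-layer cells (0.8); TPF810 = SC keratin (1.0) + melanin
granules (3D Gaussian blobs, σ 1.8 µm, 800 per layer, layer amplitudes
SG 0.3 / SS 0.6 / SB 1.2, globally multiplied by `melanin_scale`) +
optional elastin colocated with the collagen texture (`elastin_amp`,
default 0); SHG810 = oriented sinusoidal fibre fringes in [0.6, 1.0]
(period 5 px) strictly below the DEJ. Melanin is clipped at the
half-coverage DEJ boundary so it is exactly disjoint from the truth
collagen mask, and the truth melanin total is the noiseless granule field
summed over [mean top-of-SG, mean DEJ] — hence exactly proportional to
`melanin_scale` at fixed seed.

Additive Gaussian detector noise (default σ = 0.02 against unit signal, a
clean acquisition; recovery under degraded conditions is exercised by
setting σ = 0.2, i.e. SNR 5) is clipped at zero. The clipping makes the
zero-background noise floor slightly positive, which inflates summed
intensities by a few percent at default geometry — visible in the melanin
integral, which recovers truth to ~1 % at 256 px but degrades on very small
test fixtures where the background-to-signal pixel ratio is larger.

The flow phantom draws a static smoothed-speckle background with two tube
vessels (radius 5 µm) whose interior pixels are re-sampled independently
each frame with amplitude 0.5. The marker phantom places the baseline tips
at (±3000, ∓1250) µm — opposite long edges of the 2.5 × 8 mm opening,
inset from the corners, tip span 6500 µm — and generates follow-ups by
applying a known transform plus per-coordinate Gaussian noise.

Every generator derives independent RNG sub-streams from `(seed, offset)`
pairs, so adding a component never perturbs the others, and equal seeds
give bit-identical output.

### What the phantom does not emulate

No optical PSF or depth-dependent scattering/attenuation, no photon
(Poisson) noise, no motion artifacts, no real melanin-cap morphology, no
biological variation between sessions. Passing recovery tests therefore
demonstrates correctness of the measurement pipelines under the stated
geometric and noise model — not that the biological effect sizes of any in
vivo study are reproducible, which they inherently are not from a desk.

## Numerical choices and problem sizes

Float32 storage for images, float64 accumulation in statistics. Inclusive
integration bounds; depth grids are exact multiples of the z-step.
Degenerate inputs error loudly (flat images in correlation, empty masks,
all-invalid columns, zero baselines) rather than returning silent defaults.
Recovery tests run at the full 256 px / 120-plane geometry with 10 seeds
for thickness (SNR 5) and melanin fold change ({1.0, 1.3, 1.6}); smaller
96 px fixtures are used where a test only exercises plumbing or ordering
properties. Transform-recovery and overlap-oracle checks use 1000 random
draws; the rasterization oracle samples pixel centres at 0.1 µm.

## Known limitations

- The overlap metric ignores FOV rotation (see above); at the ≤ 3° session
  rotations the marker geometry permits, the error is well under the
  metric's reporting precision.
- The SC-bottom criterion assumes the SC-band TPF peak lies within 8 planes
  of the surface; very thick SC needs `sc_peak_window_planes` raised.
- Collagen segmentation assumes collagen-containing planes show bimodal
  intensity; a plane uniformly filled with flat-textured collagen would be
  mis-declared collagen-free, which is why the melanin profile stops at the
  mean DEJ where planes are reliably mixed.
- Fold change compares integrals over each session's own boundary
  estimates; systematic boundary shifts between sessions propagate into the
  ratio.
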