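# Methods

This note documents the models behind `vesselct`, the parameter defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions a user should know before trusting a
green test.

## Phantom model

**Vessel trees.** A phantom is a connected tree of straight cylindrical
segments. A `BranchingSpec` fixes the lumen diameter per branch generation
(root first, non-increasing — arterial calibers proceed from wide to
narrow), the branching factor (default 2), per-level segment lengths
(default 10 diameters, a typical caliber-to-length ratio for ocular
arteries), and a mean branch angle (default 35 deg with +/-30% jitter and
random azimuths, seeded). Radii are exactly half the specified diameters,
so the defaults reproduce the reference caliber ladders
(200/110/95/80/40 um for the fundus arteries, 210/70/30 um for the iris
ring and its branches).

**Attenuation.** Lumens carry a uniform attenuation coefficient, default
`2e-3 / um`. With that value a 200 um root artery absorbs ~33% of the beam
(mu*d = 0.4) and an 18 um terminal vessel ~3.5% — placing the smallest
calibers near the noise floor of a realistic photon budget, which is the
regime in which the absorption/phase comparison is meaningful. The beam
energy (22 keV) and propagation distance (700 mm) of the emulated setup are
carried as acquisition metadata only; they do not parameterize the contrast
model.

**Voxelization.** Ground-truth grids mark every voxel whose centre lies
within a segment's radius (capsule test). Vessels thinner than one voxel
are guaranteed a one-voxel-wide footprint along their centreline with
attenuation scaled by the lumen/voxel area fraction, so the 2-px caliber
class (18 um at 9 um pitch) never disappears from the ground truth.

## Projection model

Parallel-beam geometry, rotation axis = z, detector columns measuring the
Radon coordinate `t = x cos(theta) + y sin(theta)`, angles 0..179 deg in
1 deg steps (the 180 deg frame is redundant with 0 deg for a parallel beam
and is not simulated).

Two projectors are provided:

- **Analytic (default for trees).** Chord lengths from the exact
  ray/finite-cylinder intersection, summed over segments. Grid-free, exact
  to float precision — a centred axisymmetric phantom projects *identically*
  at every angle, and the closed-form profile `2 mu sqrt(R^2 - x^2)` is
  reproduced to ~1e-16. Overlap regions at bifurcations are double-counted;
  for the caliber ratios simulated here the bias is confined to the few
  voxels at a junction.
- **Grid (for voxel phantoms).** Bilinear resampling along rays at 1 px
  steps. Its discretization error (~1-4% against the analytic projector) is
  the reason the analytic path is the default simulator: it avoids
  compounding voxelization error into the projections.

**Contrast modes.** Absorption: `I = flat * exp(-P)` (Beer-Lambert).
Phase: the log-projection is replaced by `P - lambda * laplacian(P)` before
exponentiation, a phenomenological stand-in for near-field propagation
fringes. `lambda` (default 1 px^2) sets fringe strength; the Laplacian sums
to ~zero so total attenuation mass is conserved, and the model reproduces
exactly the property that matters downstream: edge-enhanced films push
small/faint vessels above the detection floor. It does *not* model
Fresnel diffraction, polychromaticity, or scatter, so fringe shapes are not
quantitatively comparable to a wave-optics simulation.

**Flat field and noise.** The background frames apply a low-order 2D
polynomial (default ~10% tilt + curvature, floored at 0.5) with optional
vignetting. Noise is Poisson at a configurable photon budget (default
5e4 photons/pixel — a bright synchrotron beam; the twin-mode experiments
use budgets derived from a requested contrast-to-noise ratio instead) plus
Gaussian read noise (default 0.2% of the flat field). Both are applied to
projections *and* background frames from one seeded generator; the same
seed reproduces a `ProjectionSet` bit for bit.

**Stage groups.** `split_stage_groups` cuts a phantom into `n_groups`
sub-volumes offset by 4 mm (444 voxels at 9 um) labeled CT1..CT4 from the
fundus end, zero-padded where the phantom ends; overlap is configurable and
defaults to 0 (the acquisition protocol does not state any).

## Reconstruction

`-log(I / I0)` with `I0` the mean of the pre/post-scan backgrounds;
non-positive intensities (possible at low photon counts) are replaced by
the smallest positive 3x3-neighbour value and counted in the log. The
log-attenuation is clipped below at 0 by default; phase-contrast pipelines
pass `floor=None` because bright fringes are legitimately negative.

The rotation axis is estimated by mirror-matching the 0 deg sinogram row
against the row at the largest available angle (179 deg) on a 0.1-column
grid. The 1 deg shortfall from a true opposed pair displaces a feature at
radius r by ~0.017 r columns, so the estimate is reliable when signal lies
within a few tens of columns of the axis; induced offsets of +/-5 columns
are recovered within 0.2 columns in the tests.

FBP uses the band-limited Ram-Lak filter built from its real-space kernel
(h[0] = 1/4, h[odd] = -1/(pi n)^2) — the textbook discrete form, which
avoids the low-frequency cupping of a naive `|f|` ramp — with optional
Shepp-Logan or Hann apodization, zero-padding to the next power of two at
least twice the row width, and linear-interpolation back-projection scaled
by `pi / (2 n_angles)`. Output units are attenuation per pixel length.
Negative reconstructed values are kept; clipping would bias Otsu
thresholds downstream. A noiseless 128^2 cylinder reconstructs with NRMSE
< 0.05 inside the lumen, and the implementation matches a brute-force
per-pixel back-projection oracle to ~1e-12 relative.

Background equalization estimates the tissue-free gray level as the
histogram mode (256 bins) over a central annulus (default radii 0.55-0.85
of the half-width, chosen to sit outside the vessel-bearing core but inside
the reconstruction circle) and shifts the slice so that level maps to 0.5.
A constant slice passes through unchanged with a warning.

## Segmentation

Global Otsu (256 bins over the ROI's own range, via scikit-image) seeds the
segmentation; each 40x40 block is then re-thresholded by its own Otsu
value clamped to +/- `clamp` x (ROI value range) around the global
threshold (default 10%). The clamp is a reproducible surrogate for the
manual per-block histogram adjustment used in practice; `clamp=0` reduces
exactly to global thresholding. Polarity is explicit: vessels are dark on
films (absorbing lumens), bright on reconstructed slices.

Two guards keep Otsu from hallucinating vessels where there are none:

- a **spread guard**: blocks whose value range is below 10% of the ROI's
  range are background (they contain no contrast to split);
- a **noise-floor guard**: a block's unclamped threshold must differ from
  the block median by more than `noise_floor_k` (default 1.5) robust noise
  SDs, with noise estimated from the median absolute first difference
  along rows — an estimator that cancels extended structure (vessels,
  shading) but not pixel noise. This guard is what sets the detectability
  floor for faint vessels, and an all-noise ROI therefore yields an empty
  mask.

The cleanup step is a 3x3 **opening** (erosion then dilation). The
procedure it reimplements is described in places as dilation followed by
erosion (which is closing), but its stated purpose — removing specks that
do not belong to vessels — is exactly what opening does, so opening is the
default and a `closing` flag is kept for fidelity experiments. Opening
removes anything narrower than 3 px, including real 2-px vessels; see the
detectability note below.

## Quantification

**Angiographic score** = vessel pixels / total pixels of an ROI mask,
computed in exact rational arithmetic. The sampling scheme takes films at
turntable angles 0, 90 and 180 deg — 180 maps to the 179 deg projection,
and since only one projection exists per angle, the three "films" of an
angle are the projections at the nominal angle and its two angular
neighbours (89/90/91), preserving the 27-samples-per-group design and its
intent of averaging out small angular differences. ROI placements are
uniform within the designated field, non-overlapping within a film, and
deterministic given a seed.

**Diameters** are measured on line profiles (bilinear interpolation at unit
spacing): background = median of the outer 20% of the profile, vessel =
dominant extremum, width = distance between the two half-depth crossings
located by linear interpolation. This yields fractional pixel counts
(7.8 px x 9 um = 70.2 um, reported to two significant figures as 70 um).
Note the estimator's geometry: on *projections* a cylinder produces a
chord (semi-elliptic) profile whose FWHM is sqrt(3)/2 ~ 0.87 of the true
diameter, while on reconstructed *cross-sections* the profile is flat-topped
and the FWHM recovers the diameter within 1 px for 3-25 px calibers.
Whether the reference pixel counts were obtained by FWHM or by manual
cursor placement is not stated anywhere; FWHM is this package's choice and
is consistent with the worked 7.8-px example only in the final product.

**Minimum detectable diameter** sweeps single-tube phantoms (ascending) and
returns the first diameter whose thresholded film mask recovers >= 50% of
the rays through the lumen, with photon noise calibrated so a 36 um
reference tube has the requested peak CNR. Detectability is judged on the
mask *before* opening: a 3x3 opening erases any 2-px vessel outright,
whereas minimum visible calibers are assessed on the gray images, not on
the cleaned density masks. At CNR 5, absorption films detect ~36-54 um
while phase films detect ~18-27 um — the direction (and rough magnitude) of
the reported 36 vs 18 um comparison; the package asserts the direction
only, since fringe strength is phenomenological.

## Statistics

Groups of 27 scores are summarized as mean and sample SD (n-1). Pairwise
comparisons default to Welch's t (Mann-Whitney U optional), two-sided, with
`*`/`**` stars at 0.05/0.01 and no multiple-testing correction by default
(Bonferroni behind a flag) — matching the reporting convention of the
emulated study, whose comparison table is labeled a "correlation analysis"
but reads as starred pairwise p-values; that reading is implemented and the
label discrepancy simply recorded. Identical constant groups report p = 1
with a log entry. Null calibration (same-distribution groups, n = 27) lands
in 4-6% rejections at alpha = 0.05 for both tests over 1000 replicates.

## What a green test establishes — and what it does not

The generator produces ideal straight-cylinder vasculature with uniform
contrast filling, stationary noise and a smooth flat field. It does not
emulate: contrast sedimentation and vessel breakpoints, motion or ring
artifacts, polychromatic beam hardening, scatter, detector point-spread
beyond the implicit pixel integration, or real fringe profiles. Green
tests therefore establish that the *analysis chain* is correct and
well-calibrated on its stated model — not that the phenomenological phase
model predicts quantitative fringe contrast, and not that the hand-tuned
per-block thresholds of the original workflow are reproduced (the clamp
parameter is a stand-in that cannot be validated against them).

## Numerical details worth knowing

- Otsu on 256 bins is ambiguous when the histogram valley is empty (the
  between-class variance is flat across empty bins); mirror-symmetry of the
  threshold holds only up to that flat region.
- FBP fidelity is evaluated inside the lumen support against the voxelized
  truth; edge voxels carry partial-volume disagreement by construction.
- The end-to-end density recovery test uses a periodic tube lattice whose
  per-cell lumen fraction is exact by construction; scores recover designed
  fractions of 0.16-0.27 within +/-0.01 under light noise (the +/-0.03
  asserted bound leaves room for noise seeds).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-stage seeds are derived from the master
  seed by hashing, and two pipeline runs with equal configuration are
  byte-identical (checksummed manifests).
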