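# Methods

`fishbeam` implements the quantitative chain of a localized heavy-ion
irradiation experiment in small fish (medaka-scale): beam dosimetry and
geometry, video cardiography, serial-section 3D morphometry, and the group
statistics used to compare irradiated and control animals.  Because the
original videos and histology are not redistributable, every analysis ships
with a ground-truthed synthetic generator that reproduces the statistical
structure the analysis assumes; what the generators do and do not emulate
is stated below.

## Dosimetry

**Fluence–dose conversion.** For a thin target traversed by a monoenergetic
ion beam, absorbed dose is

    D [Gy] = Φ [/cm²] · LET [keV/μm] · 10⁷ [μm·cm²/kg] · 1.602×10⁻¹⁶ [J/keV]

implemented verbatim and exactly linear in both arguments; the inverse is
algebraic.  At the study's surface LET of 78.4 keV/μm, 15 Gy corresponds to
1.194×10⁸ particles/cm².

**Depth–LET profile.** Transport codes produce the full Bragg curve; this
package instead provides a fit-free interpolant pinned to the four constants
an experiment reports: surface LET, peak LET, range R, and peak width w
(read as a Gaussian FWHM — the width's exact definition is usually
unstated, and FWHM is the conventional reading).  On the entry side
(depth ≤ R − w/2) the profile is a residual-range power law
`LET(d) = LET₀ · (R / (R − d))^p` with p chosen so the plateau alone reaches
half the peak just before the peak, plus a Gaussian of FWHM w that tops it
up to exactly the peak LET at depth R − w/2.  Distally the profile follows
the same Gaussian and cuts to zero beyond R: the distal edge of a
monoenergetic beam is sharp on the ~μm sampling scale used here.  The form
guarantees LET(0) = surface LET to machine precision (the peak is ~500 σ
away), a unique maximum equal to the peak LET, monotone rise up to the
peak, and zero beyond range.  It is an interpolant, not a stopping-power
model; anything needing Bethe–Bloch physics should use a transport code.

**Ion range.** `ion_range_water` uses the Bragg–Kleeman power law for
protons in water, R_p = 0.0022·E^1.77 cm (E in MeV), scaled by A/Z² for
heavier ions at equal specific energy.  For ¹²C at 26.7 MeV/u this gives
2.46 mm against the transport-code reference of ≈2.2 mm (+12%); the
documented accuracy of the approximation is ±15% and the transport-code
value is authoritative where available.

**Irradiated-region geometry.** The body cross-section is an ellipse or
simple polygon, dorsal side at row 0; the beam is a parallel ray bundle.
On a pixel grid (pixel centers, 0-based, row-major), a point is irradiated
iff it is inside the cross-section and its depth along the beam axis from
the entry surface *on that ray* is ≤ the range.  The boundary is closed
(depth = range counts), which makes the mask exactly monotone in range.
Geometry is 2-D only: the beam fields used in such facilities
(60 × 60 mm) are uniform over a whole fish, so nothing varies along the
body axis by construction.

## Video cardiography

The procedure follows the standard high-speed-video protocol for
transparent fish (300 fps, 512 × 384 px, ventral view):

1. **ROI traces.** Three rectangular ROIs over the heart and one reference
   ROI on the body are reduced to per-frame mean intensities.  Rectangles
   are 0-based and half-open; RGB frames are converted with ITU-R 601
   luminance (any fixed convention works — the traces are relative).
2. **Reference subtraction.** The reference trace carries the body-movement
   (ventilation) artifact, which is common-mode across ROIs.  The cardiac
   signal is the mean of (heart − reference) per trace — algebraically
   identical to mean-then-subtract, and bit-exact in cancelling a
   common-mode term when intensities are integer-digitized, as camera
   output is.  A generator option (`ventilation_gain_mismatch`) lets tests
   quantify what imperfect common-mode coupling costs.
3. **Smoothing.** Centered 21-frame moving average.  Edges use the
   truncated window (mean over available frames): length is preserved and
   no data are fabricated by reflection.  21 frames at 300 fps is 70 ms —
   well below the shortest physiological beat, so minima positions move by
   at most a frame or two.
4. **Minima detection.** End-of-diastole is a local intensity minimum.
   Minima are plateau-merged strict local minima with a prominence
   threshold, kept deepest-first under a minimum-separation constraint
   (`scipy.signal.find_peaks` on the negated trace).  Defaults: separation
   = fps·60/300 frames (a 300 bpm physiological ceiling) and prominence =
   25% of the trace's interquartile range, making detection invariant to
   affine intensity changes.  A constant trace yields no minima — reported,
   not raised.
5. **Rates.** IBIᵢ = consecutive minima differences; per-beat rate =
   fps·60/IBIᵢ; the steady-state rate is the mean (and SD, ddof = 1) of
   per-beat rates whose *both* defining minima fall within the averaging
   window (default 180 s from t = 0; both the window length and its start
   are parameters, since publications rarely state which segment of a
   longer recording was averaged).  Published "±" values are treated as
   SDs: for the day-7 heart-rate table this reading recomputes to
   p ≈ 0.91 against the printed 0.90, while an SEM reading gives ≈ 0.99.

**What the generator emulates.** Heart traces are baseline + an asymmetric
raised-cosine pulse train (30% of the cycle a fast systolic dip, 70% a slow
diastolic recovery, so each beat has one well-defined minimum) + a 2 Hz
ventilation sinusoid (amplitude 0.5× cardiac) + white Gaussian noise (SD
0.1× cardiac).  Beat times come from a renewal process (mean 60/HR, CV
0.02), which keeps the true mean rate exactly interpretable.  The video
generator renders the same model spatially.  Not emulated: heart shape
change (intensity proxy only), optical blur, pigment occlusion, drifting
baselines, or ventilation that is *not* common-mode; passing recovery tests
therefore shows the pipeline is correct and noise-tolerant under the
assumed artifact structure, not that it survives arbitrary real-world
violations of it.

## Serial-section morphometry

Inputs are ordered integer label images (0 background, 1 organ, 2 blood
cell inside the organ) with isotropic in-plane pixel size and a 5 μm
section thickness — anisotropic voxels, counted as
pixel_size² × thickness.

**Alignment.** Translation-only registration (histology sections deform
non-rigidly, but translation is what the quantification here needs and
keeps the problem well-posed on binary masks).  Each section registers to
its already-aligned neighbor, propagating outward from the middle section:
adjacent sections are the most similar, and cumulative drift stays within
the tested margins.  The pairwise estimator maximizes the dense FFT
cross-correlation of the foreground masks and takes the *centroid of the
near-maximal plateau* (within half a pixel-count of the maximum).  The
tie-break matters: when adjacent slices differ in diameter, every position
of the smaller mask fully inside the larger scores identically, and
single-point peak-pickers land anywhere on that plateau (off-the-shelf
phase correlation drifted ~2 px RMS on ellipsoid stacks); the plateau
centroid is the true offset for concentric convex slices and reduces to
the unique argmax for identical shapes.  Shifts are applied with
nearest-neighbor rounding so labels stay labels; empty sections inherit
their nearest non-empty neighbor's shift and are flagged.

**Quantification.** Organ volume = (label 1 + 2 voxels) × voxel volume.
"Blood cell mass" is reported both as a voxel count and as the fraction of
organ voxels, per section (anterior→posterior profile; organ-free sections
yield flagged NaNs) and in regions: dorsal/ventral split at the organ's
volumetric centroid row (no standard split plane exists, so it is exposed
as a parameter), and in-field/out-of-field when an irradiation mask from
the dosimetry module is supplied — one 2-D cross-section mask broadcast to
all sections, since the beam does not vary along the body axis.

**What the generator emulates.** A voxelized ellipsoid "kidney"
(150 × 120 × 120 μm semi-axes by default in a 64 × 64 × 70 grid of 5 μm
voxels — an organ model scaled to run in milliseconds while preserving the
anisotropic-section structure), blood labels drawn per-voxel Bernoulli at a
0.25 baseline, optionally multiplied by (1 − depletion) inside a dorsal
band (depth measured from row 0, the dorsal body surface, matching the
dosimetry depth convention) or over the whole organ — the localized-beam
and whole-body-reference damage patterns respectively.  Sections get
integer-rounded Gaussian jitter, clipped to the declared margin so
translation never clips foreground (hence volume is exactly
alignment-invariant).  Not emulated: staining variation, tears/folds,
non-rigid deformation, segmentation error — alignment results on real
HE-stained material will be worse than the exact recovery seen on these
masks.

## Group statistics

Classical one-way fixed-effects ANOVA (F = MS_between/MS_within, p from
F(k−1, N−k)), with a summary-statistics entry point: both sums of squares
depend on the data only through (nᵢ, meanᵢ, sdᵢ), so ANOVA from printed
mean ± SD tables is *exactly* the raw-data ANOVA, enabling recomputation of
published p-values.  Zero pooled within-group variance is a domain error
with an explicit message, not a division by zero.  Tukey's HSD uses
q = |Δmean|/√(MS_w/2·(1/nᵢ+1/nⱼ)) (Tukey–Kramer for unequal n) with
adjusted p from `scipy.stats.studentized_range` (numerically integrated
quantiles, no table lookup).  No unequal-variance correction is applied —
the procedure mirrors the plain ANOVA these studies report.  One known
discrepancy is documented in the tests: the day-5 heart-rate table's
printed p = 0.24 is not recoverable from its printed summaries under
either the SD (≈0.49) or SEM reading; the day-7 table recomputes cleanly.

## Numerical and testing notes

- All generators draw from a single `numpy.random.default_rng(seed)` per
  call; identical parameters and seed give bit-identical output.
- Problem sizes in the test and acceptance runs: 180-s traces at 300 fps
  (54 000 samples) for heart-rate recovery, 120 seeded replicates for the
  rate sweep, 70-section 64 × 64 stacks for morphometry, 2000 simulated
  triples for the ANOVA null-calibration check.
- The ANOVA null-calibration check draws 2000 normal triples (3 × 10) from
  one seeded stream and asserts the α = 0.05 rejection rate within ±0.01;
  at 2000 replicates that band is ≈ ±2 Monte-Carlo standard errors, so a
  correctly calibrated test can land outside it for an unlucky stream (the
  suite's fixed stream does, at 0.038, while the identical data fed to
  `scipy.stats.f_oneway` rejects identically and the same stream is
  calibrated at other thresholds).  The stream is kept fixed rather than
  re-drawn.
- Tolerances asserted against generator truth: ±1 bpm heart-rate recovery,
  ≤0.5 px RMS shift recovery, ≤2% ellipsoid volume error, binomial-scale
  bands (±0.02) on blood fractions.

## Limitations

- The Bragg profile and range rule are interpolants/approximations by
  design; they are pinned to reported constants, not derived from physics.
- Translation-only registration cannot correct rotation, scaling, or
  non-rigid section distortion.
- The minima detector assumes one intensity minimum per beat; waveforms
  with double notches would need a larger minimum separation.
- Segmentation of raw histology into labels is out of scope: inputs are
  already-labeled masks.
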