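# Methods

This note documents the models behind `spindleprofiler`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
benchmarks do and do not establish about real microscopy data.

## Image model

Synthetic spindles are rendered as sums of elliptical 2D Gaussian sources
on a calibrated pixel grid — single focal plane, no point-spread-function
convolution, no z-dimension. Pixel convention: (row, col) indices,
0-based, pixel centers at integer coordinates, physical position =
index × `pixel_size_um`. Per channel:

- **pole** (γ-tubulin): one isotropic spot of sd `pole_spot_sigma_um`
  (default 0.5 µm) per pole;
- **dna**: a band at the spindle midpoint with axial sd
  `dna_band_sigma_um` (default 1.5 µm) and a fixed transverse sd of 3.0 µm
  — a metaphase plate is narrow along the pole axis and wide across it;
- **motor** (KIF18A): one isotropic peak (sd 0.6 µm) per principal pole,
  placed `motor_peak_offset_um` from that pole along the axis toward the
  center. The localization continuum is deliberately one number: ≈3.5 µm
  reads as plus-end-tip accumulation, ≈0 as pole accumulation;
- **tubulin** (α-tubulin): an elongated Gaussian between the poles (axial
  sd = L/4, transverse sd 1.5 µm), plus one fan per extra pole in
  multipolar renders.

Amplitudes are peak photon counts; a constant background (default 10) is
added and noise is applied last — Poisson on the expected counts by
default, optionally additive Gaussian or none. Every source's analytic
mass `A·2πσ₁σ₂/px²` is exposed so noiseless renders can be checked against
closed-form integrals (they agree to <1% truncation error on the default
canvas). Multipolar renders place extra poles at radius max(L/2, 2 µm)
from the midpoint at angles ≥45° off the main axis, alternating sides, so
all pole pairs are ≥2 µm apart and counting is unambiguous.

Absolute intensity scales are not reported for the real assays, so
defaults were chosen to give a realistic photon budget: peak amplitudes of
100–200 photons over background 10 put the per-pixel peak SNR near 10
under Poisson noise (`A/sqrt(A+B)`), typical of fixed-cell epifluorescence.
Recovery experiments labelled "SNR 10" use amplitude 110 over background
10.

Time lapses apply a treatment at one frame: afterwards the motor channel's
expectation becomes `mask_t · base + (gain(t) − 1) · pole_component`,
where `mask_t` zeroes the axial band within `gap_halfwidth_um(t)` of the
midpoint and the pole component is a motor-amplitude peak at each pole.
Both treatment functions must be non-decreasing in time after treatment;
`linear_ramp` builds the capped linear form used throughout. Timestamps
are `(frame − treatment_frame) · frame_interval_s`, so the live-imaging
defaults (−90 s initial, +720 s final, 30-s cadence) fall on frames 0 and
27 of a 28-frame acquisition with treatment at frame 3.

## Line scans

`extract_profile` samples at pixel-pitch steps along the anchor→target
direction; each sample is the mean of `width_px` bilinear sub-samples
spaced one pixel apart perpendicular to the line, centered on it (the
Fiji wide-line convention — documented here because "10-pixel-wide line"
is dialect-dependent). At width 1 on axis-parallel lines this reduces
exactly to direct pixel indexing, which the tests assert. Pole anchoring
in batch mode is the global maximum of the 3×3-mean-smoothed pole channel
within a user ROI; ties resolve to the smallest row, then column.

Order of operations is normalize (each channel to its own maximum), then
align (shift each scan so the reference-channel argmax is at 0), then
average per pixel distance. Mean-profile positions covered by fewer than
50% of scans are dropped; the fraction is configurable. `distance_to_max`
breaks ties toward the pole and records that a tie occurred. Both
per-scan distances and the distance on the averaged profile are emitted,
since cohort plots may use either.

## Chromosome alignment

The axial profile averages the chosen channel over a box of height 5 µm
(default; the assay specifies a fixed height without a value) perpendicular
to the pole-to-pole axis, then normalizes to its maximum. The Gaussian
model includes an offset term `b` because internally normalized profiles
retain a nonzero floor from background and neighboring signal.
Initialization is from moments (intensity-weighted mean/sd, offset = min);
bounds keep µ and σ within the spindle, b ∈ [0, 1] and a ∈ (0, 2].
Non-convergence is reported as a flag on the record — cells are excluded
from cohort summaries explicitly, never silently dropped. No smoothing or
windowing is applied to the profile before fitting.

## Relocalization

ROI profiles are column-wise means in raw units (no internal
normalization: the final/initial ratio needs commensurate scales; mean vs
sum across the ROI height cancels in the ratio for a fixed ROI). Each
profile maps onto its own 0–100% length scale by linear interpolation
(default 101 grid points), and the ratio divides pointwise with the
denominator floored at 1% of the initial profile's mean — floor hits are
counted in the result metadata. AUC is the trapezoid rule over [0, 100]
with baseline y = 0, so an unchanged cell scores exactly 100. Profiles
whose physical lengths differ by more than 2× are rejected as mismatched
ROIs. For z-stacks a max (default) or mean projection helper is provided.

With the default treatment dynamics (gap half-width → 2 µm, pole gain →
1.5 by +12 min) the pole-gain term outweighs the central suppression and
treated AUC sits above 100; the benchmark checks the sign against a
closed-form oracle built from the same source formulas rather than
asserting a fixed direction, because the sign is a property of the
gap/gain balance, not of the estimator.

## Counting and proliferation

Counts pool across fields before any ratio is formed, so the pooled
mitotic index equals the count-weighted mean of per-field indices exactly.
The chi-squared comparison is the 2×2 Pearson statistic on pooled counts
(outcome vs rest), df = 1, no continuity correction (pooled counts are in
the hundreds-to-thousands); pairwise-vs-control is the primary interface
and a full R×2 variant is exposed separately. Expected cells below 1 set a
warning flag; a degenerate table returns statistic 0 rather than raising.
Null calibration over 100 seeded replicate pairs gives a type-I error
within binomial noise of 5%.

Pole counting takes local maxima of the smoothed pole channel above 30%
of its global maximum, separated by ≥2 µm, and keeps those where the
smoothed α-tubulin channel exceeds background. The background estimate is
the channel's 10th percentile — not the median, which is biased upward
when spindle fans cover much of the frame — plus 5% of the dynamic range
above it. On seeded noisy renders with 2–4 poles this count matches the
manifest exactly in ≥95% of cases (300/300 in the shipped benchmark).

Growth curves follow `N(t) = K / (1 + (K/n0 − 1)·2^(−t/Td))`, reducing to
exponential for K = ∞ and to a constant for Td = ∞ (arrest). Count noise
is mean-preserving lognormal at the requested CV so noiseless runs are
exactly the closed form. Fold change is final/initial per well; the
normalized fold change divides by the reference-condition mean (not
paired wells), making the reference mean exactly 1.

## Dose–response

Percent inhibition is the exact control-anchored formula and is not
clipped to [0, 100] — out-of-range values carry information about noise.
Control wells travel in the tidy CSV under reserved concentration codes
(0 = positive control with enzyme, −1 = no-enzyme floor). The 4PL is
fitted in log10-concentration space (the "variable slope" convention)
with unconstrained-but-bounded plateaus, hill ∈ [0.1, 10], IC50 within
two decades of the tested range, and the half-maximal crossing as the
IC50 initializer. Replicates are fitted pointwise by default; averaging
first is an option. Curves spanning <20 percentage points are flagged
shallow. Noiseless self-generated curves round-trip all four parameters
to ≤1%.

## What the benchmarks show — and what they do not

Every stage is validated by parameter recovery against the generator's
manifests at study-scale problem sizes chosen to run in seconds on one
CPU: 200 cells for FWHM recovery, 100 line scans per phenotype (plus 20
reruns of 20 for the contrast direction), 9 + 7 relocalization cells per
rerun, 100 null count replicates, 100 noisy inhibition curves. The
generator reproduces the geometry and first-order photon statistics of
the assays but deliberately omits optics (PSF, chromatic shift,
photobleaching), cell-to-cell morphological variability, segmentation
errors and focus drift. Passing recovery therefore demonstrates that the
estimators are unbiased and correctly implemented on images satisfying
the stated model — not that they are robust to every artifact of real
micrographs. Stage boundaries mirror the real workflow (poles or ROIs may
be supplied from manual annotation), so real TIFF + sidecar inputs drop
in wherever synthetic ones are used.

## Known limitations

- Lines and boxes are specified by coordinates or auto-anchored at
  detected poles; there is no interactive drawing, segmentation or
  metaphase-stage classification.
- The relocalization module assumes the spindle long axis lies along the
  ROI columns; rotated spindles need a pre-rotated ROI.
- Beyond the chi-squared counting comparison, hypothesis testing is out of
  scope by design: the pipeline emits tidy per-cell tables for standard
  statistical tooling.
- The 4PL fit does not model plate effects or reject outliers.
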