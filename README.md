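# spindleprofiler

Quantification pipeline for mitotic-spindle fluorescence microscopy, built
for studies of the kinesin-8 motor KIF18A in chromosomally unstable (CIN)
cancer cells. When KIF18A is inhibited or carries motor-domain (alpha-4
helix) mutations it relocalizes from kinetochore-microtubule plus-ends to
the spindle poles; downstream, chromosomes lose alignment, spindles
lengthen, the mitotic index and spindle multipolarity rise, and CIN-cell
proliferation drops. `spindleprofiler` implements the image and data
analyses that quantify each of those phenotypes, together with a synthetic
data generator that renders every input with known ground truth so the
whole pipeline is testable by parameter recovery.

## What it measures

- **Motor localization (line scans).** A 10-pixel-wide line is anchored at
  a γ-tubulin pole signal and drawn toward the spindle center; each
  channel's profile is normalized internally to its maximum, scans are
  aligned on the γ-tubulin peak, averaged per pixel distance, and
  summarized by the distance from the pole to the maximum motor signal.
  Plus-end-localized KIF18A gives distances of several µm; pole-accumulated
  KIF18A gives distances near zero.
- **Chromosome alignment and spindle length.** The DNA or centromere
  channel is profiled along the pole-to-pole axis inside a fixed-height
  box, normalized, and fitted with a Gaussian
  `b + a·exp(−(x−µ)²/(2σ²))`; the alignment statistic is
  `FWHM = 2·sqrt(2 ln 2)·σ` (smaller = tighter metaphase plate). Spindle
  length is the Euclidean pole-to-pole distance.
- **Live-cell relocalization.** Motor fluorescence profiles across a
  spindle ROI at an initial (−1:30 min) and final (+12 min) timepoint are
  resampled to a 0–100% spindle-length scale and divided; the final/initial
  ratio curve is summarized by its trapezoidal AUC (an untreated cell gives
  exactly 100).
- **Counting statistics.** Pooled mitotic index and multipolar-spindle
  fraction per condition, compared by a 2×2 Pearson chi-squared test on
  pooled counts (no continuity correction); image-based spindle-pole
  counting from the γ-tubulin channel gated by α-tubulin signal.
- **Proliferation.** Kinetic cell-count series normalized to their first
  timepoint; per-well fold change normalized to the control-condition mean.
- **Dose–response.** Percent inhibition
  `100·(pos − sample)/(pos − neg)` and a variable-slope four-parameter
  logistic fit in log10-concentration space yielding the IC50 and Hill
  slope.

The synthetic generator renders bipolar and multipolar spindles as sums of
2D Gaussian sources on a calibrated pixel grid, time lapses in which a
central gap in motor signal expands poleward while poles brighten,
multinomial mitotic/multipolar count tables, logistic growth curves and
4PL inhibition tables — each paired with a ground-truth manifest
(spindle length, band FWHM, motor offset, fold change, IC50).

## Worked example

Simulate an inhibition assay and fit it from the shell:

```bash
spindleprofiler simulate dose --seed 3 --out demo
spindleprofiler dose --table demo/dose.csv --out demo/fit.json
```

which prints the fit report:

```json
{
  "top_pct": 99.99999999999979,
  "bottom_pct": 2.2376640585460657e-14,
  "ic50_nM": 8.199999999999989,
  "hill": 1.0000000000000049,
  "converged": true,
  "shallow": false
}
```

The noiseless table was generated with IC50 = 8.2 nM, and the 4PL fit
returns it to machine precision; `top`/`bottom` are the fitted plateaus on
the percent-inhibition scale. The same round trip from Python, for the
imaging stages:

```python
import spindleprofiler as sp

img, truth = sp.render_spindle_image(sp.SpindleSpec(seed=42))  # Poisson noise
anchor = sp.detect_pole_anchor(img, roi=(0, 0, 160, 80))
scan = sp.normalize_internal(sp.extract_profile(img, anchor, (8.0, 14.0), 6.5, 10))
aligned = sp.align_scans([scan], reference="pole")
print(sp.distance_to_max(aligned.scans[0], "motor"))  # 3.5  (truth: 3.5 µm)

rec = sp.measure_alignment(img)
print(rec["spindle_length_um"], rec["fwhm_um"])       # 12.0, 3.544 (truth: 12, 3.532)
```

The distance-to-max recovers the simulated motor peak offset (3.5 µm, the
plus-end phenotype) and the Gaussian FWHM of the chromosome band recovers
`2·sqrt(2 ln 2)·1.5 µm = 3.532 µm` to within noise.

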