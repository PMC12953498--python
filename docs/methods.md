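# Methods

`ppglucose` estimates capillary blood glucose (mg/dL) from a single
15 s green-light photoplethysmogram (PPG) sampled at ~127 Hz. This note
documents the models, the numerical choices, and what the synthetic
test-bench does and does not demonstrate.

## Signal model and preprocessing

A raw finger PPG is modelled as a periodic cardiac waveform plus
baseline drift (respiration, sub-0.5 Hz), mains interference, broadband
sensor noise and transient motion bursts. Cleaning follows the standard
offline chain:

1. **Detrend** — remove the least-squares linear trend (also zeroes the
   mean).
2. **Band-pass** — order-2 Butterworth, 0.5–5 Hz, applied
   forward–backward (`sosfiltfilt` with reflect padding). Zero-phase
   filtering preserves fiducial timing on short records at the cost of
   squaring the magnitude response: each cutoff sits at −3 dB per pass,
   −6 dB after both passes. All downstream beat timing is measured on
   this signal.
3. **Band-power SNR** — Welch periodogram (segments ≈ 4 s, 50 %
   overlap, Hann window), signal power = spectral power inside
   [0.5, 5] Hz (band edges inclusive, DC excluded), noise power =
   everything else including DC and Nyquist. No estimator is canonical
   for this quantity; the averaged periodogram is a conventional,
   low-variance choice.

### The morphology pathway

The acceleration plethysmogram (APG, second difference) weights the
spectrum by a factor that grows with frequency, so the a–e wave
micro-structure lives largely **above** 5 Hz; a 0.5–5 Hz band-pass
provably erases the c and d waves of any realistic pulse. The package
therefore maintains two views of each record: the 0.5–5 Hz signal for
beat detection, amplitude statistics and SNR, and a 0.5–15 Hz zero-phase
order-2 band-pass of the detrended signal ("morphology smoothing") for
APG fiducial detection and peak-amplitude features. 15 Hz retains the
dicrotic-notch curvature while suppressing broadband noise enough for
stable second differences at 127 Hz.

## Pulse segmentation

Systolic peaks and inter-pulse valleys are detected with a
physiology-bounded moving window: a candidate extremum must be the
largest point within 0.8 × the minimum credible cardiac period
(0.6 s at 100 bpm) on either side, and must exceed a prominence of
0.3 × the record's amplitude range. Range-relative prominence makes
detection invariant to amplitude scaling; the distance bound rejects
dicrotic-notch doublets. Valleys are then forced to alternate with
peaks (keeping the deepest valley between consecutive peaks), and the
record is split into complete valley-to-valley pulses; truncated
boundary pulses are discarded.

Three consecutive pulses are selected for analysis by maximising the
mean pairwise Pearson correlation of the pulse shapes resampled to a
common length. Window scores within 5 × 10⁻³ of the best are treated as
tied and resolved to the earliest window: pulse-length rounding and
filter edge effects perturb the score at the 10⁻³ level even on
perfectly periodic signals, whereas a genuine artifact depresses it by
well over 10⁻². Pulse rate is 60 / mean inter-peak interval over the
whole record.

## Features

Per record, 35 features:

- **Statistical (21)** — Min, Max, RMS, signal energy (Σy²), mean,
  sample SD and sample variance ((n−1) convention) of the PPG, VPG and
  APG of the concatenated three selected pulses (a per-pulse-then-
  average mode is available). VPG and APG are the raw first/second
  sample differences as printed in the field's convention; a flag
  rescales them by fs and fs² for physical units — the eight APG ratios
  are unaffected either way.
- **Waveform (6)** — systolic peak amplitude (S_Peak), diastolic peak
  amplitude (D_Peak), mean inter systolic-peak interval, valley-to-
  valley pulse width, pulse rate, and the interval between successive
  diastolic peaks (T_interval). Amplitudes are measured on the
  morphology-smoothed signal **relative to the pulse foot** (the pulse
  minimum); band-passing removes the DC reference, so absolute
  amplitudes would be meaningless. D_Peak is the first PPG local
  maximum after the e wave, falling back (flagged) to the post-systolic
  inflection (VPG maximum) when the diastolic wave is only a shoulder.
- **APG ratios (8)** — b/a, c/a, d/a, e/a, (b−c−d−e)/a, (b−e)/a,
  (b−c−d)/a, (c+d−b)/a, averaged over the pulses in which they are
  defined.

### a–e fiducial detection

On each pulse's APG: **a** is the largest positive local maximum at or
before the systolic peak; **b** the deepest minimum after a; **e** the
largest positive maximum after b (the dicrotic-notch curvature peak);
**c** is the largest interior maximum between b and e exceeding 10 % of
the e-wave amplitude, and **d** the deepest minimum between c and e.
When no such interior pair exists — a genuinely shallow or absent notch
— c and d are flagged absent and the five ratios that reference them
carry NaN, which downstream selection and modelling treat as missing.
Pulse width, detection windows and indices are 0-based with half-open
intervals throughout.

## Feature preparation

- **Scaling** — min-max to [0, 1] (configurable range). Inside the
  model pipeline the min/max are learned on training rows only to avoid
  leakage; a standalone call fits on all rows. Constant columns map to
  the range minimum with a warning.
- **Selection** — keep features with |Pearson r| ≥ 0.3 against the
  reference glucose (pairwise-complete rows). The threshold is a
  package default: it reproduces a shortlist of the size practitioners
  report for this kind of feature set; it is configurable. The full
  correlation map is always written as a report.
- **Outlier removal** — rows with glucose outside the 65–160 mg/dL
  inclusion range are dropped (study inclusion rule), then rows where
  any shortlisted feature lies beyond 1.5 × IQR fences. The
  deterministic fence rule replaces interactive scatter-plot screening
  so that runs are reproducible.
- **Engineered features (6)** — maximum, mean, SD and variance averaged
  across the PPG/VPG/APG families, the systolic-to-diastolic peak
  ratio, and SDmean = SD − mean. Computed from unscaled source features
  by default; the scale-then-engineer order is available via config.

## Modelling and evaluation

Default model: random-forest regression with 100 trees, max depth 10,
min samples split 2, min samples leaf 1, √p feature subsampling,
bootstrap on, seed 42 — the configuration this class of study reports.
The zoo also exposes SVR, k-NN, gradient-boosted trees (XGBoost),
a decision tree and linear regression under shared splits.

The default split is 50/50 at the **record** level, mirroring the
80-train/80-test design of a paired fasting/postprandial cohort. A
record-level split can place one subject's two records on opposite
sides; the subject-grouped split is exposed and recommended when
subject-level generalisation is the question. No validation set or
cross-validation is used by default.

By default the model trains on the six engineered features; `selected`
(shortlist only) and `combined` modes are configurable. Evaluation:
MSE, RMSE, MAE, R²; Bland–Altman bias and 1.96 × SD limits of agreement
on differences defined as predicted − actual; the fraction of
|difference| ≤ 10 mg/dL; and bias stratified by actual glucose into
<90, 90–120 and ≥120 mg/dL ranges (empty ranges report n = 0). The
"SD of differences" column is the literal sample SD of per-record
differences within the range.

## Synthetic cohort generator

No public dataset accompanies this acquisition protocol, so the
test-bench generates one: 80 subjects × {fasting, postprandial} = 160
records of 15 s at 127 Hz. Reference glucose is drawn from
N(93, 22²) mg/dL fasting and N(113, 30²) postprandial, rejection-sampled
into [65, 160] mg/dL (rejection, not clipping, avoids probability mass
at the range edges); a subject's postprandial draw is redrawn until it
is no more than 10 mg/dL below their fasting value. Heart rate is
uniform on 60–100 bpm per subject and constant within a record; ages
are uniform on 18–50.

**Beat template.** Each beat is a systolic Gaussian (amplitude 1 a.u.,
width 0.08 s, centre 0.18 s after onset) plus a delayed diastolic
Gaussian (fraction 0.42 of systolic amplitude, delay 0.33 s, width
ratio 1.2) minus a narrow notch Gaussian (depth 0.12, width 0.025 s) at
the minimum between the two component peaks — the simplest shape that
produces a dicrotic notch and the full a–e APG pattern. All time
constants scale with the cardiac period (reference 72 bpm), mirroring
the shortening of systole at higher rates; without this the diastolic
wave of a fast beat collides with the next beat and the notch, rather
than the inter-beat gap, becomes the per-period minimum. Records start
at a random phase. Ground truth (beat onsets, per-beat clean-signal
argmax systolic peaks, notch positions) is stored with every record.

**Glucose coupling.** Morphology parameters shift linearly with
glucose about a 100 mg/dL pivot: slopes 5 × 10⁻³ (systolic amplitude),
2 × 10⁻³ (diastolic fraction), 6 × 10⁻⁴ s (diastolic delay) and
4 × 10⁻⁴ (notch depth) per mg/dL. **These effect sizes are statistical
stand-ins** — no quantitative glucose→waveform coupling is published
for this modality — sized against the per-subject morphology
variability (Gaussian jitter with SDs 0.03, 0.01 and 0.008 s on
amplitude, diastolic fraction and delay) so that the planted signal is
recoverable by the pipeline-end regression but not trivially so.
Because the coupling is linear, a linear model is correctly specified
for this generator and performs on par with the forest; the generator
makes no attempt to manufacture forest superiority.

**Noise.** Baseline drift 0.3 a.u. at 0.2 Hz, 50 Hz mains at 0.02 a.u.
(configurable for other grids), white noise SD 0.01, and
Gaussian-windowed 2–4 Hz motion bursts at 2/min (amplitude 0.8,
duration 0.5 s) at Poisson times. Noise draws are consumed from the
random stream even at zero amplitude, so silencing the noise reproduces
the clean template under the same seed.

**What passing tests show.** The synthetic cohort demonstrates that the
implementation recovers a planted monotone glucose→morphology coupling
through the full chain at realistic noise levels, and that every
operation matches its independent oracle. It does **not** validate the
physiological premise that human PPG morphology encodes glucose, nor
the transferability of any reported accuracy to real sensors: the
generator has no sensor electronics, no reference-glucose measurement
error, no beat-to-beat HR variability, no ectopy, and a hand-chosen
coupling. Accuracy floors in the acceptance suite (R² ≥ 0.8,
MAE ≤ 8 mg/dL on the default cohort) are properties of the default
generator settings, not reproductions of any study's values.

## Numerical choices and degenerate inputs

- Seeds: one global seed; per-stage substreams derived through a stable
  string hash, so stages can be re-run in isolation; identical
  config + seed gives byte-identical artifacts (feature CSVs are
  written at %.17g and read with round-trip float parsing).
- Flat or constant signals raise "no pulses detected"; records with
  fewer than 3 complete pulses raise, and the orchestrated run skips
  and logs such records rather than aborting the cohort.
- Constant features raise on correlation; a cohort where no feature
  passes the selection threshold errors in the standalone API but
  completes (with an empty shortlist report) in the orchestrated run,
  because a no-signal cohort is a legitimate null experiment.
- Division guards: zero a-wave amplitude, zero diastolic peak and
  constant actuals (R² undefined) all raise typed errors.

## Known limitations

- The "enhanced moving window" peak detector is one concrete
  realisation of an under-specified family; its contract (window max,
  spacing ≥ 0.8 × min period, range-relative prominence) is tested
  against a brute-force oracle, but other realisations would place
  boundary-case peaks differently.
- The three-pulse quality criterion (template correlation) is a
  documented surrogate for whatever manual or automatic selection a
  human operator would perform.
- Record-level 50/50 splitting leaks subject identity between train and
  test by design fidelity to the emulated protocol; use
  `grouping: subject` for honest subject-level claims.
- APG c/d waves are frequently absent under heavy noise; their ratio
  features then rely on the pulses where they are defined, and
  `selected` mode imputes remaining missing values with training-set
  medians.
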