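# Methods

`swaquant` implements the quantitative pipeline of a preclinical sleep
intervention study: slow-wave-activity (SWA) enhancement during NREM sleep
in a transgenic amyloidosis mouse model, evaluated through EEG delta power,
behavior, stereology and ELISA. This note records the models, the defaults,
the numerical choices, and what the synthetic data generator does and does
not emulate.

## Signal model and post-processing

A recording is a single EEG channel in µV, digitized at a native rate near
200 Hz (±200 mV input range) on a Zeitgeber-time axis (ZT 0 = lights-on).
Post-processing runs in a fixed order:

1. **Clipping detection** — maximal runs of ≥ 2 consecutive samples with
   |x| ≥ 0.999 × input range are flagged; their 4-s epochs are excluded
   from all spectra. The amplifier rail is the physical definition of
   clipping; the 0.999 threshold and 2-sample minimum are conventions
   (config-overridable) chosen to be robust to float rounding while never
   firing on in-range signal.
2. **3-point moving average + Fermi taper** — the moving average uses a
   shrinking window at the ends (mean of the two available samples) to
   avoid edge transients. Flagged samples are zeroed and each contiguous
   clean segment is tapered with a Fermi–Dirac-shaped window: value 0.5
   exactly at the segment boundary, roll-off width 1% of the segment
   length (kT = width/4, so the taper saturates within the roll-off). A
   width of 0 disables tapering, making the step a pure moving average.
3. **Resampling to exactly 200 Hz** — polyphase rational resampling; the
   ratio is recovered from the stated native rate (e.g. 198.7 →
   2000/1987). Native rates outside [150, 250] Hz are rejected.
4. **Zero-phase equiripple band-pass 0.5–30 Hz** — a Parks–McClellan
   high-pass (transition 0.25–0.5 Hz) and low-pass (30–33 Hz), each
   applied forward and backward so the cascade has exactly zero phase.
   Single-pass stop-band attenuation ≥ 40 dB and pass ripple ≤ 0.5 dB
   set the filter orders (≈1450 and ≈120 taps); because the kernels run to
   thousands of taps, the forward–backward passes are applied by FFT
   overlap-add convolution with odd-reflection edge padding (numerically
   equivalent to `filtfilt`, feasible on multi-hour traces).
5. **NREMS outlier reconstruction** — one interquartile range is computed
   over all scored-NREMS samples of the whole recording. Runs of fewer
   than 7 consecutive samples exceeding ±8×IQR are replaced by cubic
   splines through 6 flanking clean samples per side; runs of ≥ 7 samples
   become regional artifacts and exclude their epochs instead. The
   "< 7 samples" bound is read strictly (runs of length ≤ 6 are respliced).
   A second pass over reconstructed output flags nothing new (idempotence,
   tested).

## Spectral quantification

Each scored 4-s epoch receives a power spectrum from Hamming-windowed 4-s
analysis segments (800 samples at 200 Hz → 0.25 Hz resolution) advanced by
2 s; an epoch's spectrum averages the segments whose centers fall inside
it (its aligned segment and the one straddling the previous epoch — this
is how a per-epoch output is reconciled with the stated 2-s overlap).
Spectra are restricted to 0.5–30 Hz (119 bins) and normalized per epoch to
sum to 100%. Delta is 0.5–4 Hz inclusive (rodent SWA convention; the band
is config-overridable and band edges must sit on the 0.25 Hz grid).

Hourly NREMS delta power is the unweighted mean over non-artifact NREM
epochs in each ZT hour ([h, h+1), anchored at lights-on); hours with fewer
than 15 qualifying epochs (1 min) are missing. **Delta-activity gain** is
the treatment-day minus baseline-day hourly value at matched ZT hours, in
percentage points; its scalar summary is the *mean* of the gains in ZT
hours 9 and 10 — the two hours following the second (ZT9) administration
(a config switch selects the sum instead). ΔNREM is the difference in
NREMS percent of scored time between the two days.

## Statistics battery

* Independent t-tests run as Student (pooled) or Welch; "auto" selects
  Welch when Levene's test (center = mean) rejects at α = 0.05 and needs
  raw values. All tests are computable from printed (n, M, SD) summaries.
* Cohen's d uses the unweighted average of the two group variances,
  d = |Δм| / √((s₁² + s₂²)/2). This variant — not the n-weighted pooled
  SD — reproduces the study's printed effect sizes (1.64, 0.91, 1.80)
  exactly from the printed summaries; the pooled-SD variant does not.
* The hourly gain series is compared between groups with one independent
  t-test per ZT hour and Benjamini–Hochberg adjustment across the 24
  hourly p-values (family = one comparison's 24 hours), flags at q = 0.05.
* The two-way genotype × treatment ANOVA uses Type-III sums of squares
  with sum-to-zero contrasts (statsmodels OLS); partial eta squared is
  F·df₁/(F·df₁+df₂) per effect. Pairwise cell comparisons are unadjusted
  (LSD-style) with standard errors from the residual mean square, matching
  the study's reporting of raw pairwise p-values with 95% CIs.
* The biserial correlation transforms the point-biserial r by
  r_b = r_pb·√(p(1−p))/φ(Φ⁻¹(p)) with p the success proportion of the
  fail/success dichotomy (success strictly > 50% correct; exactly 50 is a
  fail). The p-value is carried from the point-biserial t-test. The exact
  fail/success splits behind the study's printed transforms are not
  printed; a brute-force search over all splits identifies the unique
  (n = 8: 4/4) and near-unique (n = 9: 7/2 up to labelling) splits that
  reproduce them, and the tests freeze those.
* The assumption screen reports 1.5×IQR boxplot fences, bias-corrected
  skewness/kurtosis, and Levene's statistic.
* A printed p = 0.791 accompanying t(8) = 0.638 in the source material is
  not reproducible from a two-sided t distribution (which gives ≈ 0.54);
  the package always reports the computed p.

## Tissue quantification

The area-fraction fractionator tiles the mask with a square sampling grid
from a seeded random origin; each grid cell's counting frame (its first
`frame` pixels per axis) contributes its plaque-positive and
ROI-intersected pixels, and burden is Σplaque/ΣROI over sampled pixels.
Default frames are 150 µm (hippocampus) and 200 µm (cortex) with grid =
frame, in which case the probe scans the entire ROI and the estimate
equals exhaustive pixel counting exactly (tested as an identity, not a
tolerance). Frames clipped at the ROI boundary contribute their
intersection — the probe estimates area fraction, so no exclusion lines
apply. Subject-level burden is the ratio of summed areas across the five
sections, not the mean of per-section ratios. Raw summed areas (µm²) are
emitted alongside the dimensionless fraction.

ELISA readouts are normalized to pg/mg tissue; the Aβ-42/Aβ-40 ratio is
formed within each solubility fraction and flagged missing when either
analyte of a pair is absent. T-maze performance is percent correct of the
trials (4 at test), classed success iff > 50%.

## Synthetic data generator

The generator exists so every stage is testable with known ground truth;
it emulates the *statistical structure* the analysis assumes, not murine
electrophysiology.

* **Hypnogram**: semi-Markov chain over WAKE/NREM/REM with geometric dwell
  times (defaults 120/240/60 s means), REM entered only from NREM
  (NREM→REM 0.3, REM→WAKE 0.6). These give NREM fractions near 60% of
  recording time, a plausible light-period figure.
* **EEG**: each 4-s epoch is colored noise synthesized in the frequency
  domain from a per-state PSD — a (f+0.5)^−α trend plus a Gaussian band
  peak (NREM: α = 1, delta peak at 2 Hz, target SD 45 µV; REM: theta peak
  at 7 Hz; WAKE: flatter, lower amplitude). Absolute levels are
  conventions (the study reports only relative power); defaults put NREM
  relative delta power near 50% of total 0.5–30 Hz power.
* **Ground truth is defined in the measured domain.** The pipeline's
  moving average tilts the 0.5–30 Hz balance (≈+3.5 p.p. of relative
  delta) and the windowed estimator smears band edges (≈−2 p.p.), so the
  generator computes, per state, the *expected measured spectrum*: the
  source PSD weighted by the pipeline power transfer (MA² × |HP|⁴ × |LP|⁴)
  and convolved with the estimator's spectral kernel (the mix of full- and
  half-Hamming windows its 2-s-stepped averaging produces). The injected
  treatment effect — a target relative-delta gain decaying exponentially
  (default 8 p.p., τ = 2 h) after each administration (ZT1, ZT9) — is
  realized by scaling delta-band amplitude with a factor solved in closed
  form in this measured domain (the expectation is linear in the scaling).
  A small residual bias (≈−0.5 p.p. at an 8 p.p. effect) remains because
  each epoch's spectrum is normalized *before* averaging — a
  ratio-of-noisy-quantities (Jensen) effect inherent to the prescribed
  per-epoch normalization; it sits well inside the ±1 p.p. recovery band
  the tests enforce.
* **Artifacts**: clipping events (Poisson, default 1/h; 0.1–1 s at the
  rail) and 3-sample NREM transients (default 4/h at 20× the nominal
  NREMS IQR) are injected non-overlapping and logged.
* **Cohort draws**: each subject's baseline and treatment days draw
  independent hypnograms (sleep architecture varies between days; the
  treatment moves delta power, not NREMS time, so ΔNREM is a null contrast
  with real between-day variance). Baseline T-maze scores per genotype × cohort and
  post-treatment scores per genotype × treatment × cohort are normal draws
  at the study's printed means/SDs (the subgroup baselines the study
  prints for its paired analyses differ slightly from the genotype-level
  baselines because they are subsets; the genotype-level values generate).
  Baseline and post draws are independent (the paired correlation is not
  derivable from printed values). ELISA insoluble Aβ-40 carries the
  printed group contrast; the other analyte/fraction cells are null
  contrasts at plausible pg/mg levels. Plaque masks are non-overlapping
  disks with radii rescaled so the analytic disk area hits the target
  fraction exactly; burden targets 0.075/0.035 (Tg placebo/SO) and 0.004
  (WT), SD 0.015.
* **Not emulated**: EMG, pharmacokinetics, spindle/slow-oscillation
  morphology, cross-frequency coupling, within-subject day-to-day
  spectral drift, and the weekday-ON/weekend-OFF dosing calendar (runs
  model one baseline and one treatment day, the two days actually
  recorded). Passing tests therefore demonstrate correctness of the
  machinery under the assumed statistical structure, not performance on
  real recordings.

## Evaluation problem sizes

The recovery and calibration checks state their sizes as the package's
evaluation conditions: delta-gain recovery uses 12-h recordings (ZT0–12
covers both administrations and the ZT9/10 summary window) at an even
200 Hz native rate, 20 seeds, asserting |mean error| ≤ 1 p.p.; null FDR
calibration uses 500 simulated 24-hour families of 8 + 8 subjects at the
statistics layer; fractionator exactness uses 50 random masks; cohort
parameter recovery uses 200 seeds at the printed group sizes (n = 17/18).
The mean of a noncentral-t statistic exceeds its noncentrality by a factor
≈ 1 + 3/(4·df), so the 200-seed mean Welch t is expected near 5.02 against
a generating noncentrality of 4.884; the ±0.2 acceptance band absorbs most
but not all of this, which is why that check is the tightest in the suite.

## Known limitations

* Per-epoch generation makes adjacent epochs spectrally independent;
  straddling analysis windows mix neighbors, slightly biasing state means
  near transitions (cancels in day-difference gains).
* The EDF writer is minimal (single channel, 16-bit, whole records only;
  a trailing partial record is dropped); TSV is the lossless format.
* Clipping rails are removed by zeroing plus tapering rather than by
  splicing the signal; epochs containing rails are excluded anyway.
* The ANOVA layer targets the 2×2 genotype × treatment design; higher
  factor cardinalities fit but pairwise output enumerates the first two
  levels per factor.
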