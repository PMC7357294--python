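# Methods

This note documents the models implemented in `cerebroflow`, the defaults
and their rationale, the numerical choices, what the synthetic generators
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## CVR model

The CVR fit regresses a BOLD time series on three terms — intercept,
delayed EtCO2 regressor, and scan number — by ordinary least squares,
repeated over a grid of candidate delays; the delay with minimal residual
sum of squares wins, with ties broken toward the smallest delay. The
scan-number term absorbs linear scanner drift. Implementation detail: one
QR decomposition per candidate delay is shared by all voxels, so the
voxel-wise map fit is a handful of matrix products per delay (a
20×20×10×240 volume with 31 candidate delays fits in well under a second).

Choices the acquisition literature leaves open, and what this package does:

- **Percent normalisation.** CVR = 100·β_EtCO2 / mean(series), the standard
  BOLD percent-change convention. The denominator is the whole-series mean
  (not an air-block baseline): it is scale-invariant and needs no block
  labelling at analysis time. Consequence: adding a constant c to a series
  rescales CVR by mean/(mean+c); multiplying by k > 0 leaves it unchanged.
- **Delay grid.** Default 0–30 s in 1 s steps, configurable, negatives
  allowed. Delay resolution is therefore the grid step, and the reported
  delay is always a grid point.
- **Instrument offset.** The EtCO2 sample-line transit time (default 4 s)
  is a fixed offset added to every candidate delay and reported separately
  from the fitted delay (`CVRResult.total_delay` = fitted + offset).
- **Regressor resampling.** The breath-sampled EtCO2 trace is linearly
  interpolated at shifted volume times; times outside the trace hold the
  nearest edge value. Generator and fitter share this code path, which is
  what makes the noiseless round trip exact to float precision.
- **Failed voxels** (zero mean signal) propagate as NaN and are counted,
  never silently zeroed; ROI means ignore them.
- Inputs are assumed motion-realigned and co-registered; realignment is
  out of scope.

ROI values fit one model to the ROI-mean time series (after removing
excluded voxels — large vessels, stroke lesions); combined white/gray
matter values are unweighted means of the constituent ROI CVR values.

## Pulsatility, CBF and CSF dynamics

PI = (Fmax − Fmin)/Fmean and RI = (Fmax − Fmin)/Fmax are computed on flow
waveforms (mL/s), after summing bilateral structures phase-wise and after
background correction (background velocity × ROI area subtracted from each
phase — a constant phase-error flow). PI is undefined (raises) for
zero-mean pulsatile waveforms such as CSF cycles; all-constant waveforms
return PI = RI = 0. Total CBF = 60·(mean ICA-L + ICA-R + VA-L + VA-R flow)
/ brain volume × 100, in mL/min/100 mL.

CSF dynamics integrate the positive (cranial) and caudal (negative) parts
of the cycle separately with the cyclic trapezoidal rule (the cycle closes
from the last phase back to the first). Net flow = (V⁺ − V⁻)·60/T mL/min;
stroke volume = (V⁺ + V⁻)/2, the mean of the two directional volumes —
read as the volume shuttled per beat, equal to either directional volume
when net flow is zero (the composite-cycle reading of "averaging the
absolute cranial and caudal flow"). At 32 phases the trapezoidal rule is
within 0.5% of the closed form A·T/π for a sinusoid of amplitude A
(relative error ≈ π²/(12·16²) ≈ 0.3%); the suite asserts this against a
dense Riemann oracle.

Orientation convention: cranial flow is positive everywhere; waveform CSV
files declare `orientation=` and caudal-positive files are sign-flipped on
read.

## WMH segmentation

Single-channel FLAIR z-scoring: z = (FLAIR − mean_WM)/sd_WM within the
white matter mask; candidate voxels are z ≥ 1.5; the binary candidate map
is Gaussian-smoothed and re-thresholded at 0.5 (partial-volume / noise
suppression); stroke-lesion voxels are subtracted; volume = voxel count ×
voxel volume, log10-transformed downstream (non-positive volumes raise
rather than silently offsetting). The two-channel (FLAIR+T1) probability
mapping used in practice is deliberately simplified to the z ≥ 1.5 core
rule; multi-channel fusion is out of scope.

**Smoothing width.** The kernel is config-exposed; the default is
σ = 0.75 voxels. Rationale (measured on implanted-lesion simulations over
20 seeds): at lesion contrast z = 3 each lesion voxel independently passes
the 1.5 threshold with probability Φ(1.5) ≈ 0.933, so some smoothing is
needed to fill isolated misses and delete isolated background false
positives (tail probability ≈ 0.067). σ = 1 erodes roughly one voxel shell
from curved lesion rims and caps voxel recovery near 88–92%; σ = 0.5 lets
single-voxel false positives survive the 0.5 re-threshold (false positive
rate up to ~1.4%). σ = 0.75 gives ≥95% recovery with ≤0.1% false positives
on ~2 mL spherical lesions. A strictly constant image raises a
degenerate-image error (zero within-mask SD) rather than returning an
empty mask.

The total SVD score (0–4) awards one point each for: any lacune; any
microbleed; basal ganglia PVS score ≥ 2; and WMH burden (deep Fazekas ≥ 2
or periventricular Fazekas = 3). Visual scores are inputs only. Sex is
coded male = 1 / female = 0, recorded in output metadata.

## Association models

Plain OLS per (outcome, predictor, adjustment) triple; adjustment sets
supported: none, {age, sex, sbp}, {age, sex, pulse_pressure}, and any of
these plus log10 WMH volume as a confound check. 95% CIs use the t
distribution with residual degrees of freedom; no robust variance, no
multiple-testing correction (all p-values are reported so users may apply
their own). Complete-case analysis with the dropped-row count recorded.
BP covariates are means of the visit's 7 readings (fewer warns); pulse
pressure is the difference of the means. VIF_j = 1/(1 − R²_j) per design
column, flagged above 2; perfect collinearity reports infinity rather than
crashing. Residual diagnostics are emitted as data (residual-vs-fitted
pairs, normal QQ quantile pairs, Breusch–Pagan LM test), not figures.

## Synthetic generators: what they emulate, and what a green test means

- **EtCO2**: the 12-minute block paradigm (2 min air / 3 min 6% CO2 / 2 min
  air / 3 min CO2 / 2 min air), baseline 40 mmHg, hypercapnic rise
  10 mmHg, one sample per 4 s breath plus Gaussian measurement noise.
  Capnograph rate and noise are not reported for the source acquisition;
  these defaults are stated here, not inferred. Breath-level sampling
  deliberately exercises the regressor-resampling path.
- **BOLD**: per voxel, baseline × (1 + gain/100 × (EtCO2(t − delay) −
  mean)) + drift·volume + Gaussian noise, tissues as labelled regions. The
  EtCO2 term is mean-centred so that "gain" is percent change per mmHg
  *relative to the voxel's mean signal* — exactly the quantity the CVR fit
  estimates; this makes noiseless recovery exact rather than biased by the
  factor 1/(1 + gain·mean(EtCO2)/100) ≈ 0.987. No MR physics: no k-space,
  motion, or cardiorespiratory aliasing.
- **Waveforms**: sinusoids, because PI, RI, net flow and stroke volume
  have closed forms there; an optional systolic-peaked von Mises shape is
  provided for realism and validated only against brute-force numerical
  oracles.
- **FLAIR**: Gaussian white matter (mean 100, SD 10) with lesion voxels
  drawn at a mean shifted by z·SD under the same noise. The acceptance
  fixture implants a radius-8-voxel ball (~2.1 mL at 1 mm³ voxels), a
  moderate confluent WMH burden.
- **Cohorts**: covariates drawn independently (age ~ N(68, 8.8),
  sex ~ Bernoulli(0.74), SBP ~ N(140, 15), matching the study population;
  SBP spread chosen as typical for a treated hypertensive stroke cohort),
  outcomes linear with Gaussian residuals. Independence makes marginal and
  adjusted slopes coincide, so recovery targets are unambiguous — real
  cohorts have correlated covariates, and a green recovery test does not
  establish robustness to confounding, only correctness of the estimator.
- The residual SD for recovery experiments is calibrated from a published
  univariate CI half-width h via σ = h·sd_x·√(n−1)/t₀.₉₇₅,ₙ₋₂.
- All generators take an explicit integer seed (one `default_rng` per
  call); fixing the seed fixes every generated value, and changing it
  never changes the ground-truth record.

## Numerical choices and degenerate inputs

- Delay ties → smallest delay (ascending strict-improvement scan).
- Constant BOLD series → CVR 0, R² defined as 0 (zero total sum of squares).
- Flat EtCO2 at every candidate delay → degenerate-design error; flat at
  some delays only (edge-held shifts) → those delays are skipped.
- RSS clamped at 0 against float round-off; R² clipped to [0, 1].
- Zero-mean pulsatile waveform → PI error; the zero-mean test is relative
  (|mean| < 1e−12 × spread) so analytically-zero-mean sinusoids are caught.
- Pipeline per-stage seeds are spawned from the master seed via
  `SeedSequence.spawn`, so stage reruns are reproducible in isolation;
  every stage writes a provenance sidecar (config hash, seeds, version).

## Known limitations

- No BOLD autocorrelation modelling (no pre-whitening): OLS p-values for
  CVR fits are optimistic on real data; the package reports fit R²/RSS
  rather than per-voxel inference.
- Single-channel WMH segmentation understates the specificity of
  multi-channel probability mapping on real FLAIR/T1 pairs.
- No registration, brain extraction, tissue priors, vessel segmentation,
  or visual-rating simulation; masks and scores are inputs.
- Association models are plain OLS: no mixed effects, robust variance, or
  mediation analysis.
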