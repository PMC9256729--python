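# Methods

This note records the models, assumptions and numerical choices behind
`ppgage`, and what its validation on synthetic cohorts does and does not
establish.

## The synthetic aging-PPG generator

### Pulse model

Each beat is the sum of two Gaussian waves on a zero baseline:

- an **incident (systolic) wave** of amplitude `systolic_amp` (default
  1 a.u.), centre `systolic_time` (0.17 s after the onset) and width
  `systolic_width` (0.09 s);
- a **reflected (diastolic) wave** delayed by `reflected_delay` (ΔT) with
  amplitude `reflected_amp_ratio × systolic_amp` and width
  `reflected_width` (0.14 s);
- minus a narrow **notch term** between the two crests (depth
  `notch_depth`, disabled when the reflected wave is absent), giving a
  dicrotic-notch-like inflection.

A linear baseline through the waveform's endpoint values is subtracted so
consecutive beats join continuously at zero, and the small late-diastolic
undershoot is clipped at zero.  The pulse therefore starts and ends at its
minimum — the onset-to-onset segmentation convention — and is nonnegative.

This two-wave abstraction reproduces the morphological feature that
matters for vascular aging (the incident/reflected wave relationship) but
it is **not** a hemodynamic simulation: no Windkessel dynamics, no
pathology-specific morphology, no sensor or optics model.

### Age encoding

Pulse parameters are affine functions of age plus seeded between-subject
Gaussian jitter, clamped to physiological ranges:

| parameter | mean at age a | jitter SD | rationale |
|---|---|---|---|
| reflected_delay (s) | 0.36 − 0.0022·a | 0.010 | stiffer arteries → faster wave return; strictly decreasing |
| reflected_amp_ratio | 0.35 + 0.004·a | 0.02 | stronger reflection with stiffening; non-decreasing |
| others | constant | small | not used as age signals |

The coefficients are package choices (they produce ΔT ≈ 0.32 s at age 20
vs ≈ 0.18 s at age 80, in the range reported for peripheral pulses), not
fitted to any dataset.  With jitter disabled the age → parameter map is
deterministic, which many tests exploit.

### Recording assembly

Beats with Gaussian pulse-interval jitter (mean PPI 0.9 s, SD 0.03 s) are
concatenated for 180 s at 125 Hz (both values configurable; 250 Hz
supported).  On top of the beat train the generator adds:

- a 0.25 Hz respiratory sinusoid (amplitude 0.05 a.u.), placed near the
  analysis band's lower edge so baseline removal is genuinely exercised;
- white Gaussian noise (SD 0.01 a.u.);
- motion-artifact bursts: 0.3–1 s of 3–15 Hz band-limited noise at 3×
  pulse amplitude, Poisson-arriving at 0.5/min — inside the passband, so
  the downstream median template (not the filter) must absorb them;
- ectopic beats: with probability 0.02 per beat the interval is scaled by
  0.5 or 1.8, creating exactly the PPI outliers the quality gate rejects.

Every recording carries a ground-truth event log (onsets, intervals,
ectopic indices, artifact windows) used as the oracle in tests.  Cohorts
draw ages decade-stratified uniform over [20, 89]; covariate flags
(hypertension 27 %, diabetes 9 %, alcohol 29 %, smoking 15 %) are
independent Bernoulli draws, deliberately uncorrelated with the waveform
so subgroup analyses have a known null.  All randomness derives from the
cohort seed via `numpy.random.SeedSequence`.

## Preprocessing

Stage order: FIR bandpass → 50 ms moving average → onset detection →
segmentation → PPI outlier gate → median template → smoothing → resize to
144 → min–max normalization.  Choices where the procedure was open:

- **FIR design**: windowed-sinc (Hamming), taps = sampling rate,
  band edges 0.5/10 Hz at the window method's half-amplitude convention.
  With a one-second impulse response the lower transition band is ~3 Hz
  wide, so the beat fundamental (~1.1 Hz) is partly attenuated; this is
  inherent to the tap-count constraint and is shared by any window choice.
  Group delay is compensated by an integer shift of (taps−1)//2 (a half
  sample residual remains for even tap counts).
- **Onset detector**: the detection threshold on the first difference
  decays exponentially (time constant 1.5 s) from half the last accepted
  upstroke's peak slope toward a floor of 10 % of the 90th percentile of
  all rising slopes (the 90th, not an extreme percentile, so short
  high-slope artifact bursts do not poison the floor).  After a threshold
  crossing, the onset is the signal minimum in a 0.2 s backward window,
  advanced to the upstroke foot past any flat run where the slope is
  below 25 % of the upstroke peak; a 0.3 s refractory period separates
  detections.  On clean synthetic recordings detected onsets sit within
  ±2 samples of the generator's beat boundaries at 125 Hz.
- **Quantiles**: linear interpolation between order statistics.  The
  interval gate uses QD = (Q3 − Q1)/2 by default; a config switch
  (`iqr` mode) substitutes the full interquartile range, which can only
  widen the bounds.  Bounds are closed (boundary intervals retained).
- **Order of resize and normalization**: resize to 144 first, min–max
  normalize last, so the output range is exactly [0, 1].
- **Degenerate inputs**: fewer than 4 intervals → no gating, warning;
  fewer than 2 onsets, a flat template, or a beat rate below 20/min →
  the recording is reported unusable rather than producing a silent
  garbage template.

On jitter-free, noise-free input the representative pulse correlates
≥ 0.996 with the generator's template resampled to 144 samples; the
residual comes from the declared filtering, not from the templating.

## The age regressor

Architecture and optimizer hyperparameters are fixed by the defaults
listed in the README (two conv layers 16×10 and 32×8, two 1024-node FC
layers, dropout 0.2, Adam 10⁻⁴, batch 50).  Design points:

- no pooling and no padding (valid convolutions): 144 → 135 → 128
  positions, 5,250,257 parameters in total;
- early stopping monitors validation MSE; patience is counted in epochs
  (100 by default, configurable to optimizer steps); the best-validation
  weights are restored on stop;
- one representative pulse per subject is the training unit;
- fold plans deal subjects to folds round-robin within each age decade
  with the pointer carried across decades, so fold sizes differ by at
  most one and each fold's decade histogram is within one subject of the
  proportional share; the validation subset is drawn decade-stratified
  from the training portion by largest-remainder allocation;
- every training run is a pure function of (data, seed): parameter
  initialization, batch shuffling and dropout masks all derive from the
  config seed, and cross-validation derives per-fold seeds from the
  global one.  Reruns produce byte-identical prediction files.
- hyperparameter search is a grid (conv depth 2–6, FC depth 1–2, widths
  512/1024/2048, dropout 0–0.5, learning rate 10⁻³/10⁻⁴) ranked by
  validation MSE.

The neural-network core is a ~200-line numpy implementation with manual
backpropagation, checked against central finite differences to < 10⁻⁴
relative error in the tests.  This was a deliberate choice: the model is
small enough that a framework buys nothing, and exact seeded determinism
across platforms is worth more here than GPU support.

### Benchmark problem sizes

The standard validation cohort is 600 subjects (3-minute recordings).
For it, a single stratified fold of the default architecture is trained
with a 45-epoch budget and patience 15 — the validation loss plateaus
well inside that budget on this cohort — giving held-out R ≈ 0.96 and
MAE ≈ 4.8 years against a cohort age SD of ≈ 20 years.  These numbers
measure **parameter recovery on synthetic data with a strong, clean age
encoding**; they say nothing about clinical accuracy, where vascular age
genuinely diverges from chronological age and waveform variability is far
larger.  On real data this class of model reports MAE around 8 years and
R around 0.6.

## Grad-CAM for regression

The gradient source is the single output neuron (no class score exists).
Channel weights are positional averages of the output's gradient with
respect to the last conv layer's activations; the rectified weighted sum
is linearly upsampled from 128 positions to the 144 input samples and
max-normalized per map (all-zero maps stay zero), so maps are comparable
within a pulse but not across subjects in absolute scale.

**Known limitation — localization is not identifiable here.**  On the
synthetic cohort, equally accurate models trained from different seeds
place their saliency mass in different pulse regions (one run attends to
the late reflected-wave/diastolic half, another to the systolic half).
The age information in the generator is spread across the whole waveform
(reflected-wave timing shifts everything after the systolic peak, and
normalization propagates it further), so "which half matters" is not a
stable property of the data, only of one trained model.  The package
therefore validates Grad-CAM against analytic oracles (closed-form maps
on toy networks, invariance to positive head rescaling, nonnegativity)
plus two robust empirical properties: maps are concentrated rather than
uniform, and one model's per-decade mean maps agree with each other.
Claims that a particular landmark (e.g. the systolic peak) dominates are
data-dependent and should only be made for the dataset at hand.

## Statistics

- R² defaults to the squared Pearson correlation (so R and R² stay
  mutually consistent in reports); `r2_mode="variance"` gives the
  1 − SSE/SST form, which can be negative for biased predictors.
- Bland–Altman differences are estimated − actual; limits use the sample
  (n−1) SD and ±1.96.
- Subgroup dispatch: independent t-test iff both groups pass Shapiro–Wilk
  and the pair passes Levene at α = 0.05 (all two-sided); otherwise
  Mann–Whitney U.  No multiple-testing correction is applied across
  subgroup rows.
- Degenerate cases (constant series, groups smaller than 3) are reported
  as missing with warnings instead of raising.

## What passing the suite shows — and what it does not

The tests establish that every pipeline stage meets its contract exactly
on data with known ground truth: onset detection finds the true beat
boundaries, the outlier gate equals its formula, the template recovers
the true pulse, the CNN can extract an age signal that is genuinely
present, Grad-CAM equals its closed form, and the statistics match hand
calculations.  They do **not** establish clinical validity: the synthetic
cohort has no vascular/chronological age discrepancy, no pathology-driven
waveform change, no sensor drift, and covariates independent of the
waveform.  Any use on real recordings needs its own clinical validation.
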