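# Methods

`facemimic` is a validation pipeline for automated facial action coding
(FACS) of spontaneous facial mimicry, with facial EMG as the reference
measurement. This note documents the models, the synthetic data generator,
the numerical choices, and the limitations of what the test suite can show.

## The measurement problem

Spontaneous facial mimicry during passive viewing is a low-amplitude,
involuntary response: zygomaticus major (ZM) activation to smiles and
corrugator supercilii (CS) activation to frowns. Surface EMG detects it
reliably; AU-estimation software operating on frontal video (AU12 lip corner
puller, AU4 brow lowerer) may or may not. The pipeline quantifies agreement
at four levels: trial-response sign congruence, mimicry detection (confusion
matrix against the EMG-defined ground truth), trial-response correlation, and
time-series latency.

## Session design

A 2 x 2 within-subject design: emotion (positive / negative) x presentation
(live performance / prerecorded video), 15 passive-viewing trials per cell at
defaults, 50 participants. Each trial is 3 s: a neutral face, a gradual ramp
starting at 1.0 s, and a maximal expression from 2.5 s held to the end. EMG
is sampled at 1000 Hz with a 3 s pre-stimulus pad; AU intensities arrive at
the 29.97 fps video frame rate, 90 frames per trial
(`floor(3 * 29.97 + 0.5)`).

## Synthetic session generator

The generator emulates the output characteristics of the measurement chain,
not faces or video. Its defaults are the study conditions every test runs
under.

**Expression drive.** `drive(t)` is a raised-cosine ramp: 0 before 1.0 s,
1 after 2.5 s, smooth and monotone in between. The raised cosine is one
plug-in choice for a "gradual" dynamic change; the parameterization accepts
alternatives.

**Latent mimicry strength.** Each trial draws a latent strength for the
ZM/AU12 pair

    s = g(e, p) + g_ref * (u0 + u1 * [positive] + eps_trial)

with fixed gain `g(e, p)` equal to `zm_gain_pos_video` (default 1.0) in
positive trials, multiplied by `live_amplification` (default 1.5) when live,
and 0 in negative trials. `u0, u1` are subject random effects (intercept and
emotion slope) and `eps_trial` is trial noise, all scaled by the reference
gain `g_ref = zm_gain_pos_video` so a fully null generator produces exactly
null latent strengths. Their SDs default to 0.5 — 50% of the emotion fixed
effect on the gain scale — stated explicitly because no variance components
are available to copy from real data. The CS/AU4 pair mirrors this with
`cs_gain_neg` in negative trials and independent trial noise, without subject
random effects. Sharing one latent strength between an EMG channel and its
paired AU series is what produces a within-subject correlation between the
trial responses, so repeated-measures-correlation recovery is testable.

**EMG channels.** Gaussian white noise band-passed to 20-450 Hz (the surface
EMG band; scaled to 45% of Nyquist for reduced-rate designs), then amplitude
modulated: instantaneous SD is `emg_baseline_sd * max(1 + s * drive(t),
0.05)`. The carrier occupies the preprocessing passband, so the filters are
near-transparent to the signal of interest. Amplitude units are arbitrary
(defaults set `emg_baseline_sd = 1`); no published amplitude scale exists to
match, and the log transform makes response magnitudes unit-dependent, which
is documented at the config surface.

**AU series.** `au_scale * s * drive(t - k/fps)` with integer frame latency
`k` (default 5), plus per-frame drift (default 0) and Gaussian frame noise
(SD 0.05) smoothed with a 3-frame moving average; a heavier exponential
smoothing preset emulates FaceReader-style temporally smoothed output.
Quality scores sit near 1 with rare dips (rate 0.001/frame) into 0.2-0.55.
`openface_like` trials are replaced by a whole-trial zero AU12 series with
probability 0.454, emulating the observed zero-output pathology; a positive
drift preset accompanies it.

**What the generator does not emulate:** visual occlusion by electrodes,
head pose and viewpoint change, asymmetric facial actions, software-specific
intensity calibration, cross-trial serial dependence, or non-Gaussian EMG
artifacts. Passing tests therefore demonstrate that the *analysis chain* is
correct and well calibrated under the assumed signal structure — not that any
particular software is valid on real video.

## EMG preprocessing

Fixed order: (1) zero-phase second-order IIR notches (Q = 30) at 60 Hz and
multiples up to the low-pass cutoff, plus a 4th-order Butterworth band-pass
20-450 Hz, both applied forward-backward; (2) per-trial linear least-squares
detrend and baseline correction by the mean over onset-3 s to onset+1 s;
(3) rectification; (4) `ln(1 + |x|)`. The nominal 500 Hz low-pass equals
Nyquist at 1000 Hz sampling, so the implemented default is 450 Hz;
`PreprocParams.for_rate` derives safe cutoffs for other rates. Artifact
screening (a threshold on |sample| / SD) is off by default, standing in for
manual screening only when enabled.

## Trial responses and detection metrics

The trial response is the mean over the maximal phase (2.5-3.0 s) minus the
mean over the neutral phase (0-1.0 s), half-open windows, for EMG log
amplitude and AU intensity alike. Sign congruence treats zero AU responses as
negative ("null or negative" is a non-response). Mimicry detection on
positive-condition trials takes ZM contraction as ground truth and AU12
activation as prediction (`single_channel`); `compound` mode additionally
requires CS/AU4 relaxation on each side. The compound taxonomy does not
exhaust the 2x2x2 response space; uncovered combinations (e.g. AU12 and AU4
both positive) count as non-detection. The AU4 analogue runs on
negative-condition trials against CS. OpenFace-style runs are tallied both
including and excluding zero-output trials. Undefined metric ratios are
reported as missing, never as zero.

## Repeated-measures correlation

`RepeatedMeasuresCorr` fits y on subject-specific intercepts plus a common
slope (subject-dummy OLS), with r = sign(slope) * sqrt(SS_slope / (SS_slope +
SS_error)) and df = N - k - 1 for N observations from k subjects; p comes
from the slope's F test on (1, df). The estimate equals the Pearson
correlation of subject-mean-centered variables (an algebraic identity the
tests verify to 1e-10, with pingouin as an independent cross-check). The 95%
CI is a percentile interval over subject-level (cluster) bootstrap resamples
— resampling subjects with replacement, trials kept intact — which respects
the repeated-measures structure; 10,000 resamples is the default. Degenerate
resamples are redrawn and counted. Subjects with fewer than two observations
are dropped with a warning.

## Condition contrasts (mixed model)

`ConditionContrastModel` fits `response ~ emo * pres` by REML (statsmodels
MixedLM) with treatment coding against the Negative / Video reference cells
and subject as the grouping factor. The random structure grows forward
through intercept; + emotion slope; + presentation slope; + interaction
slope, comparing successive fits by likelihood-ratio test at alpha = 0.05 and
stopping at non-superiority, non-convergence, or a singular fit. A singular
*base* fit (zero intercept variance) is accepted but not grown, since a null
generator legitimately produces it. Optimizer fallbacks (lbfgs, bfgs,
powell) guard against spurious non-convergence.

Fixed-effect and simple-effect p-values use t with residual df (N - 4); the
fitter does not expose Satterthwaite df, and for trial-level effects at these
sample sizes the residual-df t is a close, slightly conservative stand-in.
Simple effects are linear combinations of the fixed effects: cell means PL,
PV, NL, NV and contrasts PL-PV, NL-NV (live effect within emotion), PL-NL,
PV-NV (emotion effect within presentation). No multiplicity correction is
applied.

**Influence exclusion.** Trial-level: standardized conditional residuals
(conditional residual / residual SD) with threshold 3, and Cook's distances
for the fixed effects computed from the GLS-whitened representation under the
estimated covariance (V_j = Z_j G Z_j' + sigma^2 I per subject), flagged above
Q3 + 1.5 IQR. Subject-level: leave-one-subject-out refits give per-subject
Cook's distances, flagged by the same boxplot rule. Flagged trials and
subjects are removed and the model refitted once under the selected random
structure. The boxplot rule always flags the tail of a right-skewed Cook's
distance distribution, so a clean Gaussian cohort still loses a few percent
of trials — the rule trades a little efficiency for robustness, and the
exclusion counts are logged. Exclusion of more than half the data aborts
with a diagnostic.

**Power by simulation.** For each candidate subject count, whole cohorts are
generated through the signal-level pipeline, responses extracted, and the
interaction tested in a model with the generator's known random structure
(intercept + emotion slope) — selection is skipped inside the replicate loop
for tractability. Power is the significant fraction; the smallest n reaching
80% is reported with Monte-Carlo standard errors.

## Latency analysis

ZM log-amplitude traces are resampled to the frame rate by bin means over
half-open bins [i/fps, (i+1)/fps) (interpolation is available behind a
flag). AU frames below the software-specific confidence threshold (0.6
FaceReader-like, 0.75 Py-Feat-like and OpenFace-like) become missing; a trial
with any missing frame is excluded by default (a fractional policy exists for
sensitivity analysis), and openface-like all-zero AU12 trials are excluded
outright. For visualization, trials are anchored to start at zero and
averaged per condition, measurement and frame with standard errors.

Trial-wise cross-correlation r(k) pairs ZM[t] with AU12[t+k] for k in
[-45, 45] (1.5 s at ~30 fps); positive peak lag means the AU series trails
the EMG. Curves are averaged trials-to-subject, then subjects-to-group, and
the group peak is searched over non-negative lags by default (the directional
hypothesis); ties at 3-decimal rounding are reported as a plateau range.
Latency in ms is `round(lag * 1000 / fps)`, which maps lags 1/2/3/5/6/9 to
33/67/100/167/200/300 ms at 29.97 fps.

**Normalization choice.** Two conventions are implemented. The per-lag
Pearson correlation (default) standardizes each overlapping segment and is
unbiased for locating the alignment lag. The fixed-length convention used by
the common numerical-environment `crosscorr` routine (standardize once by the
full-series moments, divide lagged sums by the series length) shrinks |r|
as |lag| grows; for a sustained ramp-plateau response the samples truncation
removes are exactly the well-aligned plateau samples, so the peak of even a
noise-free shifted drive collapses to lag 0. It is kept behind
`method="full_series"` for reproducing r-magnitudes, and deliberately not
used for latency estimation. A residual caveat applies to any convention
here: the log transform makes expected EMG log amplitude a concave function
of the drive, which distorts the EMG waveform shape slightly and can bias
the apparent latency by a frame or two at large modulation gains.

## Numerical and interface conventions

Stimulus onset is t = 0; EMG sample indices are 0-based; window and frame
intervals are half-open. All tabular interchange is long-format CSV with
headers and empty fields for missing values. Every stochastic operation
accepts a seed and is bit-reproducible given it; pipeline stages log their
seeds, exclusion counts and the selected random structure to a JSON-lines
run log. Config files are YAML; unknown keys are rejected by name.

## Desk-scale test sizes

The simulation-heavy checks run on reduced cohorts chosen as the package's
own test-size policy: 8-10 subjects with 4 trials per condition, EMG at
500 Hz with cutoffs scaled via `PreprocParams.for_rate`, 50 cohorts for
latency recovery, 200 null and 100 effect cohorts for calibration, and 100
replicates per grid point for power. Effect sizes, noise levels and rates
stay at generator defaults throughout.

## Known limitations

- Validity claims transfer to real data only insofar as the generator's
  signal structure holds; none of the occlusion/pose pathologies of real
  video are modeled.
- Mixed-model inference uses residual-df t rather than Satterthwaite;
  subject-level df for cell means are therefore not reproduced.
- The latent-strength coupling yields cleaner EMG-AU agreement than real
  software output; absolute congruence/F1 levels from synthetic runs are not
  comparable to field performance.
- Cross-correlation latency inherits a small nonlinearity-induced bias at
  high modulation gain (see above); recovery is exact only to about one
  frame.
- No statistical test of live-vs-video latency differences is provided.
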