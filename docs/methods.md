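# Methods

`alphalat` implements a complete analysis chain for left/right covert
visual spatial attention experiments with whole-head MEG-like recordings:
synthetic data generation, trial rejection, sliding-window alpha power on
synthetic planar gradients, hemispheric lateralization statistics with
cluster-based permutation inference, and single-trial decoding.  Because
no recordings ship with the package, every stage is validated on
simulated sessions whose effect structure is known exactly.

## The measurement model

During covert attention to one visual hemifield, posterior alpha
oscillations (8–14 Hz) desynchronize in the hemisphere contralateral to
the attended side and synchronize ipsilaterally.  The package quantifies
this with two statistics:

* **Alpha modulation (AM)**, per sensor:
  `AM = (P_L − P_R) / (P_L + P_R)`, where `P_L` / `P_R` are the mean alpha
  powers over attend-left / attend-right trials.  AM is scale-free,
  bounded in [−1, 1] and antisymmetric in its arguments.
* **Alpha lateralization (AL)**, per subject and condition:
  `AL = mean(AM over the left-hemisphere ROI) − mean(AM over the
  right-hemisphere ROI)`.  With the expected physiology the left ROI has
  AM > 0 and the right ROI AM < 0, so stronger attentional modulation
  gives larger AL.

The hemispheric ROIs are the sensors whose condition-averaged AM deviates
from zero in a within-subject cluster-based sign-flip permutation test,
split by hemisphere.

## Synthetic sessions

The generator emulates the trial structure of a 2 × 2 design (task
difficulty easy/difficult × target eccentricity 3.5°/7°) with left/right
attended hemifields balanced 50/50 and interleaved within condition (so
sequential cross-validation folds always contain both classes).  Each
trial spans −1 s (pre-cue baseline) to `pre_target + 1` s around cue
onset at 300 Hz.

* **Pre-target periods** come from a 90/10 mixture of range-limited
  decaying exponentials: 90% on [2, 3] s and 10% on [0.5, 2] s with mean
  0.8 s.  A strictly decaying density on [2, 3] cannot have the nominal
  mean of 2.5 s (any decaying truncated exponential has mean < 2.5), so
  the long component's rate defaults to the uniform limit, whose mean is
  2.5 s; the rate is a config parameter for users who prefer a visibly
  decaying shape.  The short component's rate is solved numerically so
  its truncated mean is exactly 0.8 s.
* **Signal**: posterior sensors (the lower third of each hemisphere's
  grid rows) carry a 10 Hz oscillation of unit base amplitude whose
  envelope is scaled by `1 + m·r(t)`: `r(t)` ramps linearly from 0.2 s
  after cue onset to a plateau at 0.6 s (onset and plateau configurable;
  the physiological literature gives an onset "shortly after cue" but no
  waveform, so a linear ramp is the simplest shape consistent with it).
  The modulation `m` is `+ipsi_increase` ipsilateral and
  `−contra_decrease` contralateral to the attended hemifield, per
  difficulty level, times a per-subject lognormal scale (σ = 0.25) and a
  left-hemisphere boost (×1.3) during right-hemifield attention that
  reproduces the hemispheric asymmetry reported for attention shifts.
  Defaults (`contra = 0.04/0.08`, `ipsi = 0.02/0.04` for easy/difficult)
  were calibrated once so that the full pipeline recovers grand-average
  AL near 0.1–0.2 with a roughly twofold difficulty ratio — the regime
  the statistic operates in empirically; sensor-space effect sizes are
  not published quantities, so these are modeling choices, not copied
  values.
* **Noise**: 1/f (exponent 1) background plus white sensor noise
  (SD 0.4) everywhere; synthesized in the frequency domain with an
  analytic variance normalization so datasets are bit-reproducible from
  the seed.
* **Behavior**: correctness follows a 2AFC Weibull psychometric function
  `p(c) = 1 − 0.5·2^−(c/θ)^β` (floor 0.5, exactly 0.75 at threshold);
  the easy preset uses full contrast against a threshold chosen to sit
  near 96% correct, the difficult preset sits at threshold.  Response
  times are shifted lognormals with means 0.571 s (easy) and 0.763 s
  (difficult); only means are published, so the family and its σ = 0.35
  are modeling choices (σ = 0 degenerates to a point mass, used in
  tests).
* **Stimulus geometry**: placeholder diameters follow an inverse-linear
  cortical magnification law `M(E) ∝ 1/(E + e2)`; the two free parameters
  are calibrated to the printed diameters (1.04° at 3.5°, 1.40° at 7°)
  and exposed in config.  The eccentricity effect on alpha defaults to
  zero, matching the empirical null finding.
* **Not emulated**: cortical dipoles and head geometry (effects are
  planted at sensor level), eye-movement physiology beyond fixational
  jitter plus a constant drift, cue-evoked transients (available but off
  by default), trial-order effects and fatigue.  Passing tests therefore
  demonstrate correctness of the estimators under the assumed effect
  structure, not robustness to every property of real MEG.

## Preprocessing

Rules run in a fixed cascade so the per-rule fractions are comparable:
pre-target ≥ 2 s (inclusive; guarantees 1.5 s of cue-free attention and a
full 1–2.5 s analysis window) and per-channel demeaning; response times
rejected when < 0.3 s or > 2 s (strict, boundary values kept); gaze
rejected when the radial deviation from the pre-cue-mean-corrected
fixation exceeds 2° for a continuous run strictly longer than 0.05 s
within 1–2.5 s after cue; broadband power rejected beyond 3 SD of the
subject's across-trial mean in that window (zero SD removes nothing —
no trial "deviates").  Whether the outlier rule should use broadband or
band-limited power is unspecified in the literature this follows;
broadband is used, catching muscle and sensor artifacts regardless of
band.

The synthetic planar gradient at each sensor is the weighted
least-squares plane fit through the differences with its neighbours
(inverse-distance weights), giving two orthogonal derivative components;
the transform is linear, maps uniform fields to zero and linear ramps to
their exact gradient, and requires two non-collinear neighbours per
sensor.  Alpha power is computed per component and summed — the standard
convention for combining planar channels.

## Spectral estimation

Power is estimated in 0.5 s Hann-tapered windows advanced in 0.05 s
steps.  A 0.5 s window has 2 Hz native resolution, so the band "8–14 Hz
in 2 Hz bins" is realized as the native bin centers {8, 10, 12, 14} Hz,
averaged with equal weights; requesting non-native centers raises an
error rather than silently leaking.  Power is normalized by the squared
sum of the taper, making a unit tone's power 1/2 independent of window
length.  Time stamps refer to window centers, aligning power estimates
symmetrically on the attention epoch; windows touching a trial's padding
are NaN.  Window averages (1–2.5 s after cue, closed interval on the
centers) feed the scalar analyses; the baseline standardization for
time-resolved plots applies one affine transform per subject (mean/SD
pooled over trials, both hemispheric ROI series and the −0.75 to −0.25 s
baseline steps), which removes between-subject power scale without
distorting within-subject dynamics.

## Inference

The cluster test forms clusters of adjacent suprathreshold one-sample t
statistics (two-sided threshold at p < 0.05 with N−1 df — the field's
default; the threshold is exposed), separately for positive and negative
deviations.  The cluster statistic is the absolute sum of member t values
("cluster mass"); the null records the maximum mass per sign-flip
assignment, controlling the familywise error over clusters.  All 2^N
assignments are enumerated when 2^N ≤ 4096, otherwise `n_perm` random
assignments are drawn with the identity forced into the null — so
p ≥ 1/n_permutations and the test is exact-conservative.  The observed t
map is taken from the identity row of the same vectorized computation,
guaranteeing the identity's cluster masses compare bitwise-equal against
the observed ones.  Elements with zero variance across subjects get
t = ±10^6 (consistent nonzero effect) or 0 (all zeros); they only arise
in degenerate synthetic inputs.  Temporal contrasts reuse the machinery
with contiguity as adjacency.

The 2 × 2 repeated-measures ANOVA is computed from within-subject
contrast scores, so each effect's F is exactly the squared paired t with
(1, N−1) df.  Published F statistics in this literature sometimes carry
(1, N) df with N subjects; the package reports the standard N−1 and no
numeric F equality with any specific report should be expected.  The
Wilcoxon signed-rank test drops zero differences, uses mid-ranks, and
switches from the exact null (≤ 25 effective pairs, no rank ties) to the
continuity-corrected normal approximation.  Binomial intervals are
Clopper–Pearson.

## Decoding

Features are natural logs of the window-averaged planar-combined alpha
power in a sensor subset selected by a leave-subject-out ROI definition:
the held-out subject's data never touches their own selection (verified
by a perturbation test).  If the reduced cohort yields no significant
cluster — guaranteed for small cohorts, where the sign-flip null cannot
reach p < 0.05 (minimum p is 2^−(N−1) per tail) — the selection falls
back to all sensors, flagged, mirroring the all-sensor feature variant.
Classification is a linear max-margin classifier (liblinear dual solver)
with features standardized by each training fold's mean/SD.  Trials stay
in chronological order and are cut into ten sequential outer folds; an
inner five-fold sequential cross-validation on each training set picks
the regularization strength from a 7-point logarithmic grid
(10^−3 … 10^3), ties resolved toward stronger regularization.  The inner
fold count and grid are package choices (unpublished in the source
literature) and configurable.

## Calibration experiments and problem sizes

`alphalat.experiments` runs the replication protocols the tests and
`scripts/acceptance.py` execute; cohort sizes were chosen once as the
smallest that leave the statistical questions clearly answerable:

* type-I calibration: 200 null datasets of 14 subjects × 30 sensors, 500
  randomizations each — rejection rate within 2 Monte-Carlo SEs of 5%;
* chance-level decoding: 50 null-preset datasets, 4 subjects × 160
  trials, full feature/nested-CV path — grand mean inside the pooled
  exact binomial 99% interval.  Per-run means are slightly
  overdispersed relative to a pure binomial because predictions within a
  subject × condition share training data; the per-run calibration check
  therefore tolerates a handful of 99%-band exceedances rather than
  none;
* effect recovery: a 4-point effect grid × 20 seeds at 5 subjects × 64
  trials, with ROIs fixed to the generator's posterior bands (the grid
  includes the zero-effect point, where a data-driven ROI is undefined
  by construction), plus 50 replicates of the full data-driven pipeline
  at 14 subjects × 64 trials for the difficulty-detection and
  eccentricity-null rates.

## Known limitations

* Effects are planted directly at sensor level; no forward model, so
  field-spread geometry is only caricatured by the planar transform.
* The generator's alpha amplitude is stationary within the plateau; slow
  drifts, bursts, and cross-frequency structure are absent.
* The cluster test's sensor adjacency derives from the synthetic grid;
  real sensor nets need their own neighbour definitions.
* Decoding accuracies on synthetic data exceed empirically typical
  values at equal AL because the noise model is benign; only ordinal
  comparisons (difficult > easy, monotonicity in effect size) are
  meaningful.
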