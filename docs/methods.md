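# Methods

## The problem

When a grating is flashed at one visual-field location, how quickly does the
EEG carry enough information to classify its spatial frequency (SF, 0.33 vs
1 c/dva) — and how does that latency change when the classifier is tested at
*other* locations, or when the observer is about to make a ~20 dva saccade?
The analysis answers this with time-resolved multivariate decoding: one
linear classifier per post-stimulus timepoint, trained on fixation trials at
a single location and cross-tested across locations and saccade conditions,
with the onset of above-chance decoding estimated by Bayes-factor inference
across subjects. Real recordings of this kind are not publicly deposited, so
the package is built around a synthetic-session generator whose embedded
ground-truth latencies make every stage of the pipeline objectively
verifiable.

## Synthetic sessions

**Design.** A session comprises blocks of randomly interleaved fixation,
saccade (central/peripheral) and control trials; the full-scale default is
5 blocks x 480 trials = 2,400 trials (224 fixation + 224 saccade + 32
control per block). Catch trials (oddball orientation, to be ignored by the
analysis) are flagged every 11–20 trials on top of scheduled trials rather
than added, so the design counts stay exact. Two fixation points sit 20.08
dva apart; four stimulus locations surround each at 5.05 dva (a square, the
right cluster a pure translation of the left so that retinotopic congruence
across a saccade is exact for the pairs 1–5, 2–6, 3–7, 4–8). Saccade trials
draw their stimulus-to-saccade latency from a truncated normal (mean 200 ms,
sd 60 ms, clipped to [100, 400] ms), emulating an online staircase that
targets ~200 ms.

**Geometry and eccentricity groups.** The exact angular layout of the eight
locations is configuration, not dogma: with two fixation points 20 dva apart
and stimuli within ~5 dva of a fixation point, test locations fall at ~5 dva
(own cluster), ~16.9 dva (inner opposite pair) and ~23.9 dva (outer opposite
pair) from the current fixation point under the default square. Eccentricity
groups near/mid/far are defined by configurable cut-points on that distance,
default (7.5, 20) dva. A consequence worth knowing: the retinotopically
congruent partners of half the training locations fall in the *mid* bin, so
a condition that aggregates congruent-location control trials over all
training locations mixes two embedded latencies; its group-level onset is
the earliest of them.

**Gaze.** 1000 Hz traces: Ornstein–Uhlenbeck fixational drift (sd 0.05 dva,
tau 20 ms), Poisson microsaccades (< 1 dva raised-cosine jumps with bounded
cumulative offset), cued saccades as 50 ms raised-cosine displacements of
20.08 dva (peak speed pi·A/2T ≈ 630 dva/s), landing noise (sd 0.3 dva)
followed ~250 ms later by a corrective saccade back onto the point — without
the correction, landing errors masquerade as fixation violations on later
trials — plus occasional blinks written as NaN spans. A configurable
fraction of trials receives an injected violation (> 2.5 dva excursion
during the stimulus, or a 3.2 dva landing error), with bookkeeping so the
exclusion stage can be audited.

**EEG.** 64 channels (62 scalp + 2 mastoids). Background noise is spatially
mixed with a power spectrum (1 − w)/f + w band-limited to 0.3–80 Hz with
white fraction w = 0.5 and channel RMS 10 µV. The broadband floor is the
realistic counterpart of sensor/amplifier noise, and it matters statistically:
with purely 1/f noise the per-timepoint accuracies are so strongly
autocorrelated (lag-1 ≈ 0.5) that the three-consecutive-timepoints onset
rule false-fires on chance excursions under a true null; with the floor the
rule is calibrated (see null study).

**Embedded signal.** Every non-catch trial adds a class-signed (+ high SF,
− low SF) pattern with two components:

* a location-specific topography u(location) from 80 ms after stimulus
  onset — the substrate of same-location decoding;
* a location-invariant topography w shared across locations, whose onset
  depends on the trial: own-cluster trials 145 ms, mid-eccentricity control
  trials 205 ms, far 295 ms, and *any* saccade trial 140 ms regardless of
  eccentricity — the predictive, spatially coarse acceleration that saccade
  preparation produces.

Cross-location decoding succeeds only through components present in both
training and test trials, so the recoverable onsets are max(training
availability, test availability): 80/145/205/295 ms for same/near/mid/far
under fixation, and ~145 ms for saccade trials at every eccentricity.
Topographies are orthonormalized per subject (no leakage through chance
overlap); subjects differ by topography perturbation (0.15), ±1-sample onset
jitter, and ±15% amplitude scaling. Onset envelopes are raised-cosine ramps
of 8 ms, sustained to the end of the epoch.

**Signal-to-noise and scale.** Effect amplitude is 9 µV against 10 µV noise
(per-trial discriminability d ≈ 2 along the pattern). This is deliberately
stronger than a real single trial because desk-scale sessions are far
smaller than real ones: the emulated experiment trains on ~1,345 trials per
location, the desk-scale default on ~16–20 per location/side. The pipeline
is therefore exercised in the same *decoding-accuracy regime* (single-subject
accuracies ~0.7–0.9 post-onset) while cohorts stay cheap. Desk-scale session:
448 trials (256 fixation / 96 saccade / 96 control), 10 subjects per cohort.
Passing recovery tests show the pipeline recovers onset geometry faithfully
in this regime; they do not certify power for weak real-world effect sizes.

Two generation routes share this signal model: a continuous recording
(512 Hz, with event markers, optional saccade-locked ocular artifact) that
exercises downsampling/filtering/epoching, and a direct epoch synthesizer
used by the multi-cohort studies, where generating and filtering hundreds of
continuous sessions would dominate runtime for no extra verification value —
the continuous route is itself validated end-to-end at small scale
(`pipeline.run_all`) and stage-by-stage in the unit tests.

## Eye events and exclusions

Velocity is the 5-sample moving-window estimate
v_n = (p_{n+2} + p_{n+1} − p_{n−1} − p_{n−2})/(6Δt) per axis, NaN near
blinks. A per-axis median-based robust SD, sigma = sqrt(med(v²) − med(v)²),
sets an elliptical threshold at lambda = 5; samples above it for ≥ 15 ms
form an event; events starting < 50 ms after the previous one are discarded
(first kept — postsaccadic oscillation guard); amplitude is endpoint
displacement, and events are flagged valid above 15 dva (cued-saccade
validation; microsaccades stay in the list for the artifact criterion).
Low thresholds keep 1 dva movements detectable: the recovery study injects
saccades of 1–20 dva with main-sequence-like durations and requires ≥ 95%
recovery with ≤ 2 ms onset error.

Trial exclusion applies, in fixed order: gaze deviation > 2.5 dva from the
current fixation point while the stimulus is on screen (for saccade trials,
evaluated only up to saccade onset — the commanded saccade is not a fixation
violation); no valid cued saccade; landing > 2.5 dva from target; eyes
arriving before stimulus offset; stimulus-to-saccade latency outside
[100, 400] ms. One reason per excluded trial, first failing rule wins. Note
that a very short-latency saccade is claimed by the stimulus-visibility rule
(the eyes necessarily arrive while the 100 ms stimulus is still on) before
the latency-window rule can see it.

## Preprocessing

Downsampling to 256 Hz uses a zero-phase FIR low-pass whose passband ends at
the 80 Hz analysis band (≥ 20 dB at 100 Hz) before decimation; all channels
are re-expressed against the mastoid average. The main filter is a 4th-order
Butterworth 0.1–80 Hz applied forward–backward plus a Q = 35 notch at 50 Hz,
all zero-phase — filter delay would bias onset latencies, the analysis's
readout. Epochs span −200..+500 ms around stimulus onset (grid includes
t = 0 at 1/256 s spacing) with the −100..0 ms mean subtracted per
trial/channel; catch and excluded trials are dropped.

Ocular-component rejection follows the variance-ratio criterion: for each
component of a (pluggable) linear decomposition, the mean variance in
−20..+10 ms windows around saccade onsets is divided by the mean variance
over fixation spans (all detected-event spans excised, microsaccades
included); components with ratio strictly > 1.1 are removed. The
decomposition itself is standard and out of scope: pass an unmixing matrix,
or FastICA is fit on a 2 Hz high-passed copy and its weights applied back to
the 0.1 Hz data. The window specification is read in seconds (−0.02 to
0.01 s); a literal millisecond reading would be physically meaningless.
Artifact-subspace cleaning and bad-channel interpolation are omitted —
synthetic data has no gross artifacts — but the pipeline is staged so a
cleaning hook can slot in before ICA.

## Decoding

At each timepoint an LDA discriminant is fit on the 64-channel amplitude
vector of one location's fixation trials. The pooled covariance is shrunk
toward a scaled identity with the analytic Ledoit–Wolf intensity computed
per timepoint (64 dims vs tens of trials makes the unregularized estimate
singular; the estimator matches `sklearn.covariance.LedoitWolf` on centered
data, which the tests assert). Classes are balanced by seeded subsampling of
the majority class before any fit; decision ties resolve to "low".
Evaluation is strictly diagonal — train time t is only ever tested at
time t; temporal generalization matrices are a non-goal.

Schemes: (1) same-location, stratified five-fold cross-validation;
(2) cross-location testing on fixation/control trials labeled by the test
location's eccentricity group; (3) congruent/incongruent testing on
peripheral saccade trials inside the 100–400 ms latency window;
(4) control-trial testing at the congruent location (the no-saccade
contrast); (5) saccade-latency bins (default 100 ms wide). Accuracy
(fraction correct, chance 0.5) is the metric. Aggregation is an unweighted
mean over (train, test) pairs within a condition, then over fixation sides,
yielding one series per subject per condition; inference consumes
subject-level series.

## Inference

Evidence at each timepoint is a one-sample JZS Bayes factor across subjects:
point null delta = 0 (accuracy at 0.5, or paired difference at 0) against a
two-sided Cauchy(0, r = 0.707) prior on the standardized effect —
"half-Cauchy" naming notwithstanding, both above- and below-chance decoding
must count, so the prior is symmetric. BF10 is computed by adaptive
quadrature of the Zellner–Siow g-integral; an independent
noncentral-t x Cauchy numerical-integration oracle agrees to better than
1e-4 relative (observed ~4e-10). Timepoints where all subjects report the
identical accuracy (possible with few subjects and quantized accuracies)
yield BF = NaN, which never counts as evidence.

Onset is the first timepoint of the earliest run of ≥ 3 consecutive
BF10 > 3 inside 0–500 ms. Confidence intervals are leave-two-out jackknives:
the onset is recomputed over all C(n, 2) subject subsets (45 for n = 10) and
the interval is the 2.5th–97.5th percentile span of the defined onsets,
widened if necessary to contain the full-sample estimate; subsets with no
onset are excluded from the percentiles but their count is reported. The
percentile convention behind the original two-sided intervals is not fully
specified anywhere; this symmetric convention is the documented default.

## Numerical and degenerate-input conventions

Onsets lie on the 256 Hz grid (3.90625 ms steps); an embedded latency
between grid points is detectable at the next grid sample at the earliest,
and the 8 ms ramp plus subject onset jitter adds ~1 sample of detection lag,
so recovered onsets sit systematically ~1–2 samples late. Zero-variance
samples error in `bf_ttest` (degenerate input) but are tolerated per
timepoint in time courses. A constant gaze trace yields no saccades with a
warning rather than an error. The scheduler's per-cell feasibility check is
opt-in (`min_trials_per_cell`), since tiny degenerate sessions are
legitimate for testing; the decoding layer independently refuses
single-class or sub-fold cells.

## What the tests do and do not show

The generator embeds exactly the structure the pipeline is designed to
detect: linearly decodable, stationary topographies with step-on latencies
and Gaussian-ish mixed noise. Passing recovery therefore demonstrates
correctness of the machinery (scheduling, detection, exclusion, filtering,
decoding, inference) and its calibration under the null — it does not
demonstrate that real cortical SF representations behave this way, nor does
it test robustness to non-stationary artifacts, drifting electrodes, or
oscillatory confounds, none of which the generator emulates. Exclusion
fractions in the synthetic sessions are configuration-driven (default
violation rate 8%, chosen to be of the same order as published human
numbers), not fitted to any reported value.

## Verification studies (what `scripts/acceptance.py` recomputes)

* full-scale design counts (2,400; 480; 224/224/32) from a fresh schedule;
* jackknife subset count for 10 subjects (45) by running the estimator;
* max relative disagreement between the BF quadrature and the oracle over
  n ∈ {5, 10, 20} x 17 effect sizes in [0, 3];
* median recovered onsets per condition, pooled median |onset error|,
  fixation-ordering fraction and saccade-vs-control fraction over
  10-subject recovery cohorts;
* false-onset rate over zero-effect cohorts;
* detector recovery rate (≤ 2 ms onset error) and false-event rate over 500
  injected saccades;
* the fixation exclusion fraction under a configured 8% violation rate.
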