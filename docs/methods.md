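# Methods

## Problem and model

`gaitclass` classifies walking trials into three groups — healthy elderly
(EL), post-stroke hemiparetic (PS) and Huntington's disease (HD) — from the
signals of three inertial measurement units (IMUs): one on each shank and one
over the lumbar spine, sampled at 128 Hz.  Each traversal of a walkway (a
*passage*) is observed twice, once per shank, so the atomic classification
unit is a (passage, side) stream.

The pipeline has four stages.

### 1. Gait-phase HMMs

The gait cycle is modelled per group as a hidden Markov model with two states
paired to the stance and swing phases, which are delimited by the
gold-standard foot-strike (FS) and toe-off (TO) annotations (stance =
`[FS, TO)`, swing = `[TO, next FS)`, half-open, 0-based).  The observation
vector has seven channels derived from the low-pass-filtered signals: shank
ML angular velocity and its approximated derivative, shank AP acceleration
and its approximated derivative, the approximated derivatives of the shank ML
and VT accelerations, and the waist ML acceleration.  The waist channel's
sign is flipped for left-side streams so both sides share one sign
convention.  Emissions are per-state Gaussian mixtures with three modes and
diagonal covariances.

Because the state sequence is known at training time, training is fully
supervised: the initial distribution π and transition matrix A are empirical
frequencies over the annotated state sequences, and each state's mixture is
fitted by EM on the frames assigned to that state.  Although gait's
periodicity suggests a strictly cyclic ("left-right") chain, a chain that
cannot revisit states cannot represent more than one stride; we therefore
estimate a full ergodic 2×2 transition matrix from counts, and stance-swing
cycling emerges empirically.

Likelihood evaluation uses the forward recursion with per-step scaling
(normalising the forward vector to sum 1 and accumulating the log scale
factors), plus a second exact rescaling: per-sample emission densities are
evaluated in log space and shifted by their per-sample maximum before
exponentiation.  Both transformations are exact, so the result equals the
naive sum over state paths up to floating-point error; the test suite checks
this against exhaustive path enumeration (T ≤ 6), against a log-sum-exp
implementation of the same recursion, against a backward-recursion total,
and against an independent HMM library.  A single pass also yields the
log-likelihood of every prefix, which the feature stage exploits.

Max-likelihood classification assigns a stream to the group whose model
yields the highest log-likelihood over the first 2 s (256 samples), a fixed
window that makes likelihoods comparable across passages; ties break by the
fixed class order (EL, PS, HD).

### 2. Hybrid features (90 per stream)

* **H1–H3**: log-likelihoods of the EL, PS and HD models over the first 2 s.
* **H4–H6**: pairwise log-likelihood differences (EL−PS, EL−HD, PS−HD)
  over the *whole* passage.  Since a log-likelihood scales with sequence
  length, differencing between models removes the shared length dependence
  and captures relative fit.
* **T1–T6 per channel** (42): mean, standard deviation (population),
  variance, maximum, minimum, range.
* **F1–F6 per channel** (42): from a single-taper (boxcar) periodogram of
  the mean-removed channel — power at the dominant frequency P1, power at
  the second dominant frequency, the two frequencies themselves, total power
  PT over (0, fs/2], and P1/PT.  The second peak must be a local maximum at
  least 0.2 Hz away from the first, so a shoulder bin of the main lobe is
  never reported as a second rhythm.  DC is excluded everywhere (the mean is
  already removed).  A spectrally empty (constant) channel returns six zeros
  and logs a warning.

### 3. SVM with max-min class accuracy selection

An RBF-kernel SVC (one-vs-one multiclass) is trained on z-scored features
(training-set statistics only).  `C` and `γ` are selected by grid search —
defaults `C ∈ {2⁻⁵,2⁻³,…,2¹⁵}`, `γ ∈ {2⁻¹⁵,2⁻¹³,…,2³}` — scored by
*subject-grouped* inner k-fold cross-validation (default 5 folds): candidate
scores are the minimum class-specific accuracy over pooled inner-fold
predictions, so no group is sacrificed for aggregate accuracy.  Ties prefer
smaller `C`, then smaller `γ` (least complex model).  Inner folds whose
training partition loses a class entirely are dropped with a warning.

### 4. Leave-one-subject-out evaluation and majority voting

For each held-out subject, the three HMMs and the SVM are retrained from
scratch on the remaining subjects; four prediction streams are produced
(HMM max-likelihood, SVM on HMM features, SVM on time/frequency features,
SVM on all 90).  Majority voting pools the (passage, side) votes: one poll
per EL/HD subject (sides summed), two polls per PS subject (impaired and
non-impaired side separately, a clinically meaningful split).  Vote ties
break toward the class with more votes over all of that subject's passages,
then by fixed class order.  Splitting PS polls by side — and by impaired
side — uses the true labels; this is an evaluation/reporting convention,
not an inference-time capability.  Confusion matrices use four rows (EL,
PS-not-impaired, PS-impaired, HD) against three predicted classes.

## Preprocessing

All IMU channels pass through a zero-phase low-pass filter: a second-order
Butterworth (5 Hz cut-off) applied forward and backward, with odd-reflection
edge padding of 3·(order+1) = 9 samples.  The double pass squares the
magnitude response and cancels phase, so in-band waveform timing (and hence
the event-locked state labelling) is undistorted.  The approximated
derivative is the forward first difference scaled by fs, last value
repeated; for a tone of frequency f its worst-case error is ≈ π·f/fs of the
analytic derivative's amplitude (half-sample phase shift), about 2.5 % at
1 Hz / 128 Hz.

## Synthetic cohorts

No public recordings exist for this three-group setting, so the generator
produces labelled cohorts with the statistical structure the framework
relies on.  Per raw channel, a stride-locked template (a sum of 2–4 Gaussian
bumps on the normalised stride phase, stance occupying the first 60 %) is
time-warped by per-stride stance/swing durations sampled from truncated
normals (±3 SD), scaled per class, per subject and (for PS) per side, plus
white sensor noise, then filtered exactly like real data.  FS/TO indices are
recorded from the construction, so annotations are exact.

Default study conditions: 10 EL / 15 PS / 17 HD subjects; 2–16 passages per
subject (uniform, matching the observed range and roughly the observed
mean); 3–6 strides per passage (mean 4.5); 128 Hz.  Class defaults encode
the qualitative orderings reported for these populations: PS walks slowest
(1.40 s stride), with attenuated amplitudes and a marked impaired-side
asymmetry (stance fraction ×1.10, shank ML angular velocity ×0.55); HD has
the highest stride-to-stride variability (CV 0.16); EL is the reference
(1.10 s, CV 0.03).  Between-subject variability (5 % amplitude, 4 % timing)
makes held-out subjects genuinely new.  A `separation` knob interpolates all
class parameters toward the EL reference: `separation=0` is an exact null
cohort (chance-level control), 1 the default.

What the generator does **not** emulate: biomechanically realistic
kinematics, the half-cycle phase offset between the two shanks (sides are
drawn independently), instrumented-mat measurement error, clinical severity
scores, and any within-session drift.  Passing tests therefore demonstrate
that the pipeline recovers class structure of this statistical kind — not
that it reproduces the accuracies attainable on real patients.

## Numerical choices and degenerate inputs

* GMM fits: k-means initialisation, ≤ 200 EM iterations, tolerance 1e-6,
  fixed seed 0, diagonal covariances floored at 1e-6 of the per-channel
  training variance.  Frames per state are capped at 20 000 (deterministic
  subsample) for the EM step only; transition counts always use all frames.
* A state observed with fewer than 3·7 frames, or never left, is an error;
  so are non-finite emissions or features, empty datasets, non-interleaving
  FS/TO lists, trials shorter than 2 s, PS trials without an impaired side,
  and LOSO folds that would leave a class with fewer than two training
  subjects.
* Trial CSVs are written with `%.17g` and read with round-trip float
  parsing, so save/load preserves float64 exactly.
* Truncated-normal stride sampling degenerates to the mean when a CV is 0,
  giving exactly periodic cohorts for zero-variance checks.

## Problem sizes used by tests and the acceptance script

Simulation sizes are the package's own choices: the end-to-end LOSO check
uses the full 10/15/17 subject structure with 2–8 passages per subject and a
compact SVM grid (C ∈ {1, 8, 128}, γ ∈ {2⁻⁹, 2⁻⁶, 2⁻³}, 3 inner folds); the
20-seed ablation comparison uses 4/4/4-subject cohorts with 2–4 passages;
the chance-level control uses 5/5/5 subjects at `separation=0`.  For the
chance control, passages of one subject are strongly correlated, so the
95 % binomial band around 1/3 is computed with the number of *subjects* as
the effective sample size.  Supervised-training recovery samples ~500
stance-swing cycles from a known two-state model with single-mode Gaussian
emissions; the recovered mixture mean is compared through the EM fixed-point
identity (the weighted mixture mean equals the sample mean).

## Known limitations

* The two-shank independence and stylised bump morphology make the synthetic
  task easier than real pathological gait; default separation yields
  near-ceiling accuracies, which is intended for verifying the machinery,
  not for benchmarking clinical performance.
* Likelihood features depend on passage length for H1–H3 only through the
  fixed 2-s window; passages shorter than 2 s are rejected rather than
  padded.
* The left-side waist sign flip assumes the ML axis convention described
  above; data recorded with other axis conventions must be remapped before
  loading.
* Viterbi decoding, probability-calibrated (weighted) voting and
  spatio-temporal gait parameters as features are out of scope.
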