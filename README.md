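# gaitclass

Probabilistic classification of pathological gait from wearable inertial
sensors.  Given shank- and waist-mounted IMU recordings (tri-axial
accelerometer + gyroscope, 128 Hz) of walking passages annotated with
foot-strike/toe-off events, `gaitclass` distinguishes healthy elderly (EL),
post-stroke hemiparetic (PS) and Huntington's disease (HD) gait.  It is
aimed at researchers in wearable-sensor gait analysis who need a tested,
end-to-end reference pipeline — and, since clinical recordings of this kind
are rarely shareable, it ships a synthetic cohort generator with exact
event annotations so every stage is verifiable.

## Method

1. **Gait-phase HMMs.**  Per class c, a two-state hidden Markov model
   λ_c = (π, A, {w_sm, μ_sm, Σ_sm}) with states paired to stance and swing
   and three-mode diagonal-Gaussian-mixture emissions over seven channels
   (shank ML angular velocity, shank AP acceleration, four approximated
   derivatives, waist ML acceleration — sign-flipped for the left side).
   Training is supervised from the event annotations; log P(O | λ_c) is
   computed by the scaled forward recursion.
2. **Hybrid features (90-dim).**  H1–H3: log-likelihoods of the three class
   models on the first 2 s; H4–H6: pairwise log-likelihood differences over
   the whole passage; plus mean/SD/variance/max/min/range and six
   periodogram features (P1, P2, f1, f2, PT, P1/PT) per channel.
3. **SVM.**  RBF-kernel SVC on z-scored features; C and γ chosen by grid
   search maximising the *minimum* class-specific accuracy under
   subject-grouped inner cross-validation.
4. **Majority voting.**  Per-(passage, side) predictions are pooled per
   subject (per side for PS, where the impaired/non-impaired distinction is
   clinically relevant).

Evaluation is leave-one-subject-out throughout: all models are retrained
for every held-out subject.  See `docs/methods.md` for assumptions,
parameter defaults and numerical details.

## Worked example

```python
import gaitclass as gc

config = gc.three_class_config(            # synthetic study conditions
    n_subjects={"EL": 3, "PS": 3, "HD": 3},
    passages_per_subject=(2, 3),
    strides_per_passage=(3, 5),
    seed=1,
)
cohort = gc.generate_cohort(config)
print(f"{len(cohort.trials)} observation streams from {len(cohort.subjects)} subjects")

svm = gc.SVMConfig(C_grid=(1.0, 8.0, 128.0),
                   gamma_grid=(2**-9, 2**-6, 2**-3), inner_folds=3)
result = gc.run_full_evaluation(cohort, svm_config=svm)
for stream, cm in result.confusion_matrices.items():
    mv = result.subject_confusion_matrices[stream]
    print(f"{stream:13s} per-passage {cm.overall_accuracy:6.1%}"
          f"  subject-level {mv.overall_accuracy:6.1%}")
print(result.subject_confusion_matrices["svm_full"].counts)
```

Output:

```
46 observation streams from 9 subjects
hmm_ll        per-passage 100.0%  subject-level 100.0%
svm_hmm       per-passage 100.0%  subject-level 100.0%
svm_timefreq  per-passage 100.0%  subject-level 100.0%
svm_full      per-passage 100.0%  subject-level 100.0%
[[3 0 0]
 [0 3 0]
 [0 3 0]
 [0 0 3]]
```

The four rows report the four prediction strategies: max-likelihood over
the class HMMs, and the SVM on the HMM features, the time/frequency
features, and the full 90-dimensional set.  Per-passage accuracy scores
every (passage, side) stream; subject-level accuracy scores each voting
unit after majority voting.  The final matrix has rows EL / PS-not-impaired
/ PS-impaired / HD versus predicted class — at this (deliberately strong)
class separation every voting unit of the synthetic cohort is recovered,
including both sides of every PS subject.  On real patient data, accuracies
are of course far from this ceiling; the synthetic cohort verifies the
machinery, not clinical performance.

The same pipeline is available from the shell:

```bash
gaitclass simulate --out data/ --seed 42
gaitclass evaluate --data data/manifest.json --out results/
gaitclass features --data data/manifest.json --out features.csv
gaitclass train-svm --features features.csv --out model.joblib
```

`data/` uses a plain layout: one CSV of nine signal columns per
(passage, side) plus a JSON manifest with sampling rate, labels,
impaired-side flags and FS/TO sample indices (see `gaitclass/io.py`).

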