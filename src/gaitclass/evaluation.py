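"""Leave-one-subject-out evaluation and majority-vote post-processing.

For every held-out subject the three class-specific gait-phase HMMs and the
SVM are retrained from scratch on the remaining subjects, and every
(passage, side) stream of the held-out subject is predicted by four
strategies:

* ``hmm_ll`` — max-likelihood over the class HMMs (2-s window);
* ``svm_hmm`` — SVM on the six HMM-based features only;
* ``svm_timefreq`` — SVM on the 84 time/frequency features only;
* ``svm_full`` — SVM on the full 90-dimensional vector.

Majority voting then pools the per-(passage, side) votes into subject-level
decisions: one poll per EL/HD subject (both sides summed), two polls per PS
subject (impaired and non-impaired side separately, since the distinction is
clinically relevant).  Splitting PS polls by side uses the true group label —
an evaluation convention for reporting, not an inference-time capability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .datamodel import GROUP_LABELS, Dataset, IMUTrial
from .features import (
    FEATURE_SUBSETS,
    HybridFeatureTransformer,
    train_class_models,
)
from .hmm import build_emission_matrix, classify_max_likelihood
from .svm import SVMConfig

STREAMS = ("hmm_ll", "svm_hmm", "svm_timefreq", "svm_full")

#: Confusion-matrix rows: PS is split by impaired side, mirroring the
#: clinically-relevant reporting layout.
ROW_LABELS = ("EL", "PS-not-imp", "PS-imp", "HD")

PREDICTION_COLUMNS = (
    "subject_id",
    "trial_id",
    "side",
    "impaired_side",
    "true_label",
    "predicted_label",
)


def _row_label(true_label: str, side: str, impaired_side: str | None) -> str:
    if true_label == "PS":
        return "PS-imp" if side == impaired_side else "PS-not-imp"
    return true_label


@dataclass
class ConfusionMatrix:
    """Integer confusion counts with PS split by side, plus accuracies."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ROW_LABELS
    col_labels: tuple[str, ...] = GROUP_LABELS

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        expected = (len(self.row_labels), len(self.col_labels))
        if self.counts.shape != expected:
            raise ValueError(f"counts must have shape {expected}")

    @staticmethod
    def _correct_col(row_label: str) -> str:
        return "PS" if row_label.startswith("PS") else row_label

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        correct = sum(
            self.counts[i, self.col_labels.index(self._correct_col(row))]
            for i, row in enumerate(self.row_labels)
        )
        return correct / self.n_total if self.n_total else float("nan")

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for i, row in enumerate(self.row_labels):
            total = self.counts[i].sum()
            correct = self.counts[i, self.col_labels.index(self._correct_col(row))]
            out[row] = correct / total if total else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "counts": self.counts.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
        }

    @classmethod
    def from_predictions(cls, predictions: pd.DataFrame) -> "ConfusionMatrix":
        counts = np.zeros((len(ROW_LABELS), len(GROUP_LABELS)), dtype=int)
        for _, rec in predictions.iterrows():
            row = _row_label(rec["true_label"], rec["side"], rec["impaired_side"])
            counts[ROW_LABELS.index(row), GROUP_LABELS.index(rec["predicted_label"])] += 1
        return cls(counts)


@dataclass
class EvaluationResult:
    """All outputs of a LOSO run: per-passage predictions and confusion
    matrices per strategy, plus (after majority voting) vote tallies and
    subject-level confusion matrices."""

    predictions: dict[str, pd.DataFrame]
    confusion_matrices: dict[str, ConfusionMatrix]
    tallies: pd.DataFrame | None = None
    subject_confusion_matrices: dict[str, ConfusionMatrix] = field(default_factory=dict)


def _check_loso_feasible(dataset: Dataset) -> None:
    counts = dataset.class_counts()
    for label in GROUP_LABELS:
        if counts.get(label, 0) < 3:
            raise ValueError(
                f"LOSO infeasible: holding out a subject would leave class "
                f"{label} with fewer than 2 training subjects "
                f"({counts.get(label, 0)} in the dataset)"
            )


def loso_evaluate(
    dataset: Dataset,
    svm_config: SVMConfig | None = None,
    hmm_kwargs: dict | None = None,
    window_s: float = 2.0,
    streams: tuple[str, ...] = STREAMS,
) -> EvaluationResult:
    """Run the full leave-one-subject-out evaluation.

    Returns per-(passage, side) predictions and confusion matrices for every
    requested strategy.  Majority voting is applied separately via
    :func:`majority_vote` (or use :func:`run_full_evaluation`).
    """
    dataset.validate()
    _check_loso_feasible(dataset)
    if svm_config is None:
        svm_config = SVMConfig()
    hmm_kwargs = dict(hmm_kwargs or {})
    unknown = set(streams) - set(STREAMS)
    if unknown:
        raise ValueError(f"unknown prediction streams: {sorted(unknown)}")

    records: dict[str, list[dict]] = {s: [] for s in streams}
    subjects = sorted(dataset.subjects)
    for held_out in subjects:
        train_trials = [t for t in dataset.trials if t.subject_id != held_out]
        test_trials = [t for t in dataset.trials if t.subject_id == held_out]
        models = train_class_models(train_trials, **hmm_kwargs)

        def _record(stream: str, trial: IMUTrial, pred: str) -> None:
            records[stream].append(
                {
                    "subject_id": trial.subject_id,
                    "trial_id": trial.trial_id,
                    "side": trial.side,
                    "impaired_side": trial.impaired_side,
                    "true_label": trial.group_label,
                    "predicted_label": pred,
                }
            )

        if "hmm_ll" in streams:
            for trial in test_trials:
                pred = classify_max_likelihood(
                    models,
                    build_emission_matrix(trial),
                    window_samples=int(round(window_s * trial.fs)),
                )
                _record("hmm_ll", trial, pred)

        svm_streams = [s for s in streams if s.startswith("svm_")]
        if svm_streams:
            transformer = HybridFeatureTransformer(**hmm_kwargs)
            transformer.models_ = models  # reuse the fold's HMMs
            F_train = transformer.transform(train_trials)
            F_test = transformer.transform(test_trials)
            y_train = [t.group_label for t in train_trials]
            groups = [t.subject_id for t in train_trials]
            for stream in svm_streams:
                subset = FEATURE_SUBSETS[stream.removeprefix("svm_")]
                clf = svm_config.make().fit(F_train[:, subset], y_train, groups=groups)
                preds = clf.predict(F_test[:, subset])
                for trial, pred in zip(test_trials, preds):
                    _record(stream, trial, pred)

    predictions = {
        s: pd.DataFrame(records[s], columns=list(PREDICTION_COLUMNS)) for s in streams
    }
    confusion = {s: ConfusionMatrix.from_predictions(p) for s, p in predictions.items()}
    return EvaluationResult(predictions=predictions, confusion_matrices=confusion)


def _tally_winner(
    unit_counts: dict[str, int], subject_counts: dict[str, int]
) -> str:
    best = max(unit_counts.values())
    candidates = [g for g in GROUP_LABELS if unit_counts[g] == best]
    if len(candidates) > 1:
        best_subj = max(subject_counts[g] for g in candidates)
        candidates = [g for g in candidates if subject_counts[g] == best_subj]
    return candidates[0]  # fixed class order breaks any remaining tie


def majority_vote(
    predictions: pd.DataFrame, dataset: Dataset
) -> tuple[pd.DataFrame, ConfusionMatrix]:
    """Pool per-(passage, side) votes into subject-level decisions.

    EL and HD subjects get one poll over both sides; PS subjects get two
    polls, one per side (impaired / non-impaired).  Ties break toward the
    class with more votes over all the subject's passages, then by the fixed
    class order EL, PS, HD.
    """
    rows = []
    counts = np.zeros((len(ROW_LABELS), len(GROUP_LABELS)), dtype=int)
    for subject_id, label in sorted(dataset.subject_labels.items()):
        votes = predictions[predictions["subject_id"] == subject_id]
        if not len(votes):
            raise ValueError(f"no votes for subject {subject_id}")
        subject_counts = {
            g: int((votes["predicted_label"] == g).sum()) for g in GROUP_LABELS
        }
        if label == "PS":
            impaired_side = dataset.subjects[subject_id][0].impaired_side
            units = [
                ("PS-imp", votes[votes["side"] == impaired_side]),
                ("PS-not-imp", votes[votes["side"] != impaired_side]),
            ]
        else:
            units = [(label, votes)]
        for row_label, unit_votes in units:
            if not len(unit_votes):
                raise ValueError(
                    f"empty vote set for unit {subject_id}/{row_label}"
                )
            unit_counts = {
                g: int((unit_votes["predicted_label"] == g).sum())
                for g in GROUP_LABELS
            }
            winner = _tally_winner(unit_counts, subject_counts)
            rows.append(
                {
                    "subject_id": subject_id,
                    "unit": row_label,
                    "true_label": label,
                    **{f"votes_{g}": unit_counts[g] for g in GROUP_LABELS},
                    "winner": winner,
                }
            )
            counts[ROW_LABELS.index(row_label), GROUP_LABELS.index(winner)] += 1
    return pd.DataFrame(rows), ConfusionMatrix(counts)


def run_full_evaluation(
    dataset: Dataset,
    svm_config: SVMConfig | None = None,
    hmm_kwargs: dict | None = None,
    streams: tuple[str, ...] = STREAMS,
) -> EvaluationResult:
    """LOSO evaluation followed by majority voting for every strategy."""
    result = loso_evaluate(
        dataset, svm_config=svm_config, hmm_kwargs=hmm_kwargs, streams=streams
    )
    tally_frames = []
    for stream, preds in result.predictions.items():
        tallies, cm = majority_vote(preds, dataset)
        tallies.insert(0, "stream", stream)
        tally_frames.append(tallies)
        result.subject_confusion_matrices[stream] = cm
    result.tallies = pd.concat(tally_frames, ignore_index=True)
    return result


class GaitClassifierPipeline(BaseEstimator, ClassifierMixin):
    """End-to-end trial classifier: class HMMs -> features -> tuned SVM.

    A convenience estimator for applying the trained framework to new trials;
    evaluation studies should use :func:`loso_evaluate`, which retrains this
    whole chain for every held-out subject.
    """

    def __init__(
        self,
        feature_subset: str = "full",
        svm_config: SVMConfig | None = None,
        n_mixtures: int = 3,
        random_state: int = 0,
    ):
        self.feature_subset = feature_subset
        self.svm_config = svm_config
        self.n_mixtures = n_mixtures
        self.random_state = random_state

    def fit(self, trials: list[IMUTrial], y=None, groups=None):
        subset = FEATURE_SUBSETS[self.feature_subset]
        self.transformer_ = HybridFeatureTransformer(
            n_mixtures=self.n_mixtures, random_state=self.random_state
        ).fit(trials, y)
        F = self.transformer_.transform(trials)
        labels = list(y) if y is not None else [t.group_label for t in trials]
        if groups is None:
            groups = [t.subject_id for t in trials]
        config = self.svm_config or SVMConfig(random_state=self.random_state)
        self.classifier_ = config.make().fit(F[:, subset], labels, groups=groups)
        self.classes_ = np.array(GROUP_LABELS)
        return self

    def predict(self, trials: list[IMUTrial]) -> np.ndarray:
        subset = FEATURE_SUBSETS[self.feature_subset]
        return self.classifier_.predict(self.transformer_.transform(trials)[:, subset])
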