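"""RBF-kernel SVM with a max-min class-accuracy grid search.

Model selection deliberately optimises the *minimum* class-specific accuracy
over the grid of ``(C, gamma)`` pairs rather than the overall accuracy, so
that no group is sacrificed for aggregate performance.  Candidate pairs are
scored by subject-grouped inner cross-validation: all trials of a subject
stay on one side of every inner split, preventing subject-identity leakage
into the selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datamodel import GROUP_LABELS

DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 2))


def _encode(y) -> np.ndarray:
    y = np.asarray(y)
    codes = np.empty(len(y), dtype=int)
    for i, lab in enumerate(y):
        if lab not in GROUP_LABELS:
            raise ValueError(f"unknown class label {lab!r}")
        codes[i] = GROUP_LABELS.index(lab)
    return codes


class MinClassAccuracySVC(BaseEstimator, ClassifierMixin):
    """RBF SVC tuned by maximising the minimum class-specific accuracy.

    Parameters
    ----------
    C_grid, gamma_grid : candidate values for the soft-margin bound ``C`` and
        kernel width ``gamma`` (defaults follow the libSVM-guide powers of
        two).
    inner_folds : number of subject-grouped folds used to score candidates.
    normalization : "zscore" (per-feature standardisation with training-set
        statistics) or "none".
    random_state : seed for the stratified fallback when no groups are given.

    Attributes
    ----------
    best_params_ : selected ``{"C": ..., "gamma": ...}`` (ties resolved
        toward smaller ``C``, then smaller ``gamma``).
    best_min_class_accuracy_ : the selection criterion at the chosen pair.
    cv_results_ : per-candidate records of the grid search.
    """

    def __init__(
        self,
        C_grid=DEFAULT_C_GRID,
        gamma_grid=DEFAULT_GAMMA_GRID,
        inner_folds: int = 5,
        normalization: str = "zscore",
        random_state: int = 0,
    ):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.inner_folds = inner_folds
        self.normalization = normalization
        self.random_state = random_state

    def _make_pipeline(self, C: float, gamma: float) -> Pipeline:
        steps = []
        if self.normalization == "zscore":
            steps.append(("scale", StandardScaler()))
        elif self.normalization != "none":
            raise ValueError("normalization must be 'zscore' or 'none'")
        steps.append(("svc", SVC(kernel="rbf", C=C, gamma=gamma)))
        return Pipeline(steps)

    def _inner_splits(self, X, y, groups):
        if groups is not None:
            groups = np.asarray(groups)
            n_groups = len(np.unique(groups))
            n_splits = min(self.inner_folds, n_groups)
            if n_splits < 2:
                raise ValueError("need at least 2 subject groups for the inner CV")
            return list(GroupKFold(n_splits=n_splits).split(X, y, groups))
        cv = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True, random_state=self.random_state
        )
        return list(cv.split(X, y))

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("training features contain non-finite values")
        codes = _encode(y)
        present = np.unique(codes)
        if len(present) < len(GROUP_LABELS):
            absent = [g for i, g in enumerate(GROUP_LABELS) if i not in present]
            raise ValueError(f"classes absent from training data: {absent}")
        if not len(self.C_grid) or not len(self.gamma_grid):
            raise ValueError("parameter grids must be nonempty")

        splits = self._inner_splits(X, codes, groups)
        usable = [
            (tr, te)
            for tr, te in splits
            if len(np.unique(codes[tr])) == len(GROUP_LABELS)
        ]
        if len(usable) < len(splits):
            warnings.warn(
                "dropping inner folds whose training partition lacks a class",
                stacklevel=2,
            )
        if not usable:
            raise ValueError("no inner fold keeps all classes in its training part")

        self.cv_results_ = []
        best = None  # (score, C, gamma)
        for C in sorted(self.C_grid):
            for gamma in sorted(self.gamma_grid):
                y_true, y_pred = [], []
                for tr, te in usable:
                    clf = self._make_pipeline(C, gamma).fit(X[tr], codes[tr])
                    y_true.append(codes[te])
                    y_pred.append(clf.predict(X[te]))
                y_true = np.concatenate(y_true)
                y_pred = np.concatenate(y_pred)
                class_acc = [
                    float(np.mean(y_pred[y_true == c] == c))
                    for c in range(len(GROUP_LABELS))
                    if np.any(y_true == c)
                ]
                score = min(class_acc)
                self.cv_results_.append(
                    {"C": C, "gamma": gamma, "min_class_accuracy": score,
                     "class_accuracies": class_acc}
                )
                if best is None or score > best[0]:
                    best = (score, C, gamma)

        self.best_min_class_accuracy_ = best[0]
        self.best_params_ = {"C": best[1], "gamma": best[2]}
        self.estimator_ = self._make_pipeline(best[1], best[2]).fit(X, codes)
        self.classes_ = np.array(GROUP_LABELS)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        codes = self.estimator_.predict(X)
        return np.asarray(GROUP_LABELS, dtype=object)[codes].astype(str)


@dataclass(frozen=True)
class SVMConfig:
    """Plain-value bundle of grid-search settings (CLI / YAML friendly)."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_folds: int = 5
    normalization: str = "zscore"
    random_state: int = 0

    def make(self) -> MinClassAccuracySVC:
        return MinClassAccuracySVC(
            C_grid=tuple(self.C_grid),
            gamma_grid=tuple(self.gamma_grid),
            inner_folds=self.inner_folds,
            normalization=self.normalization,
            random_state=self.random_state,
        )


def grid_search_train(features, labels, config: SVMConfig | None = None, groups=None):
    """Functional wrapper: fit a :class:`MinClassAccuracySVC` on a feature
    matrix (rows may also be :class:`~gaitclass.features.FeatureVector`)."""
    if config is None:
        config = SVMConfig()
    rows = [f.values if hasattr(f, "values") else np.asarray(f) for f in features]
    return config.make().fit(np.vstack(rows), labels, groups=groups)


def predict(classifier: MinClassAccuracySVC, feature) -> str:
    """Predict the class of a single feature vector."""
    row = feature.values if hasattr(feature, "values") else np.asarray(feature)
    return str(classifier.predict(row.reshape(1, -1))[0])
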