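"""Two-state gait-phase HMM with Gaussian-mixture emissions.

The gait cycle is modelled as a hidden two-state process — stance (0) and
swing (1), delimited by foot-strike (FS) and toe-off (TO) events — emitting a
seven-channel observation vector at every sample.  One model is trained per
subject group; training is *supervised*: the state sequence is known from the
gold-standard event annotations, so the initial and transition probabilities
are empirical frequencies and each state's three-mode diagonal Gaussian
mixture is fitted by EM on the frames assigned to that state.  Classification
evaluates the scaled forward recursion under each group's model and picks the
highest log-likelihood.

Although the gait cycle suggests a strictly cyclic ("left-right") topology, a
chain that never revisits a state cannot represent multiple strides; the
transition matrix here is a full 2 x 2 ergodic matrix estimated from counts,
from which stance-swing cycling emerges empirically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import log as _log
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture

from .datamodel import GROUP_LABELS, GaitEvents, IMUTrial

#: Fixed emission-channel order.  Channels 1-6 come from one shank sensor
#: (ML angular velocity and its derivative, AP acceleration and its
#: derivative, derivatives of the ML and VT accelerations); channel 7 is the
#: waist ML acceleration, sign-flipped for left-side matrices so that the
#: waist is represented with the same sign for both sides.
CHANNEL_NAMES = (
    "gyro_ml",
    "d_gyro_ml",
    "acc_ap",
    "d_acc_ap",
    "d_acc_ml",
    "d_acc_vt",
    "waist_acc_ml",
)
N_CHANNELS = len(CHANNEL_NAMES)

STANCE, SWING = 0, 1
N_STATES = 2


def approx_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """First-difference derivative estimate, scaled to physical units.

    The forward difference ``(x[t+1] - x[t]) * fs`` is used, with the last
    value repeated so the output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("approx_derivative requires a 1-D signal of length >= 2")
    d = np.empty_like(x)
    d[:-1] = np.diff(x) * fs
    d[-1] = d[-2]
    return d


@dataclass
class EmissionMatrix:
    """T x 7 observation sequence fed to the HMMs, with trial metadata."""

    data: np.ndarray
    side: str
    subject_id: str = ""
    trial_id: str = ""
    group_label: str | None = None
    impaired_side: str | None = None
    fs: float = 128.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != N_CHANNELS:
            raise ValueError(
                f"emission matrix must be T x {N_CHANNELS}, got {self.data.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def build_emission_matrix(trial: IMUTrial) -> EmissionMatrix:
    """Assemble the seven-channel observation matrix for one trial.

    Column 7 (waist ML acceleration) is negated for left-side trials so both
    sides share one sign convention in the waist channel.
    """
    VT, AP, ML = 0, 1, 2
    gyro_ml = trial.shank_gyro[:, ML]
    acc_ap = trial.shank_acc[:, AP]
    waist_ml = trial.waist_acc[:, ML].copy()
    if trial.side == "left":
        waist_ml = -waist_ml
    data = np.column_stack(
        [
            gyro_ml,
            approx_derivative(gyro_ml, trial.fs),
            acc_ap,
            approx_derivative(acc_ap, trial.fs),
            approx_derivative(trial.shank_acc[:, ML], trial.fs),
            approx_derivative(trial.shank_acc[:, VT], trial.fs),
            waist_ml,
        ]
    )
    return EmissionMatrix(
        data=data,
        side=trial.side,
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        group_label=trial.group_label,
        impaired_side=trial.impaired_side,
        fs=trial.fs,
    )


def events_to_states(events: GaitEvents, n_samples: int) -> np.ndarray:
    """Label every sample stance (0) or swing (1) from the FS/TO annotations.

    Stance covers the half-open intervals ``[FS_k, TO_k)``, swing covers
    ``[TO_k, FS_{k+1})``.  Samples before the first event or after the last
    one extend the adjacent phase (swing precedes an FS; stance precedes a
    TO).
    """
    events.validate(n_samples)
    states = np.empty(n_samples, dtype=np.int8)
    fs_idx, to_idx = events.foot_strikes, events.toe_offs
    # swing before the first foot strike
    states[: fs_idx[0]] = SWING
    for k, fs_k in enumerate(fs_idx):
        if k < len(to_idx):
            states[fs_k : to_idx[k]] = STANCE
            end = fs_idx[k + 1] if k + 1 < len(fs_idx) else n_samples
            states[to_idx[k] : end] = SWING
        else:  # trailing FS without TO: stance extends to the end
            states[fs_k:] = STANCE
    return states


def _validate_stochastic(name: str, arr: np.ndarray, axis: int | None) -> None:
    sums = arr.sum(axis=axis)
    if not np.allclose(sums, 1.0, atol=1e-12):
        raise ValueError(f"{name} rows must sum to 1, got sums {sums}")


class GaitPhaseHMM(BaseEstimator):
    """Supervised two-state HMM with per-state Gaussian-mixture emissions.

    Parameters
    ----------
    n_mixtures : int
        Number of Gaussian modes per state (default 3).
    var_floor_frac : float
        Diagonal covariance floor, as a fraction of the per-channel training
        variance.
    max_iter, tol : EM stopping controls for the per-state mixture fits.
    random_state : seed for the k-means initialisation of the mixtures.
    max_frames_per_state : int or None
        Cap on frames used per state in the EM fit; frames beyond the cap are
        subsampled deterministically.  Transition counts always use all data.

    Attributes
    ----------
    startprob_ : (2,) empirical initial state distribution.
    transmat_ : (2, 2) empirical transition matrix.
    weights_, means_, covars_ : mixture parameters per state, with shapes
        (2, M), (2, M, 7) and (2, M, 7) (diagonal covariances).
    class_label_ : the group label this model was trained for, if given.
    """

    def __init__(
        self,
        n_mixtures: int = 3,
        var_floor_frac: float = 1e-6,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state: int = 0,
        max_frames_per_state: int | None = 20000,
    ):
        self.n_mixtures = n_mixtures
        self.var_floor_frac = var_floor_frac
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.max_frames_per_state = max_frames_per_state

    # -- construction -----------------------------------------------------

    @classmethod
    def from_params(
        cls,
        startprob: np.ndarray,
        transmat: np.ndarray,
        weights: np.ndarray,
        means: np.ndarray,
        covars: np.ndarray,
        class_label: str | None = None,
    ) -> "GaitPhaseHMM":
        """Build a model directly from explicit parameters (no fitting)."""
        model = cls(n_mixtures=np.asarray(weights).shape[1])
        model.startprob_ = np.asarray(startprob, dtype=float)
        model.transmat_ = np.asarray(transmat, dtype=float)
        model.weights_ = np.asarray(weights, dtype=float)
        model.means_ = np.asarray(means, dtype=float)
        model.covars_ = np.asarray(covars, dtype=float)
        model.class_label_ = class_label
        model._check_fitted_params()
        return model

    def _check_fitted_params(self) -> None:
        if self.startprob_.shape != (N_STATES,):
            raise ValueError("startprob_ must have shape (2,)")
        if self.transmat_.shape != (N_STATES, N_STATES):
            raise ValueError("transmat_ must have shape (2, 2)")
        _validate_stochastic("startprob_", self.startprob_, axis=None)
        _validate_stochastic("transmat_", self.transmat_, axis=1)
        _validate_stochastic("weights_", self.weights_, axis=1)
        if np.any(self.covars_ <= 0):
            raise ValueError("covariances must be strictly positive")

    # -- supervised training ----------------------------------------------

    def fit(self, X: list, states: list, class_label: str | None = None):
        """Fit from emission matrices paired with known state sequences.

        ``X`` is a list of ``T_i x 7`` arrays (or :class:`EmissionMatrix`);
        ``states`` the matching list of per-sample 0/1 labels.
        """
        mats = [x.data if isinstance(x, EmissionMatrix) else np.asarray(x, float) for x in X]
        seqs = [np.asarray(s, dtype=int) for s in states]
        if not mats:
            raise ValueError("training set is empty")
        if len(mats) != len(seqs):
            raise ValueError("each emission matrix needs a state sequence")
        for m, s in zip(mats, seqs):
            if m.shape[0] != s.shape[0]:
                raise ValueError("emission matrix and state sequence lengths differ")
            if not np.all((s == STANCE) | (s == SWING)):
                raise ValueError("state sequences must be over {0, 1}")
        n_channels = mats[0].shape[1]

        frames = np.vstack(mats)
        labels = np.concatenate(seqs)
        for s in (STANCE, SWING):
            if int(np.sum(labels == s)) < self.n_mixtures * n_channels:
                name = "stance" if s == STANCE else "swing"
                raise ValueError(
                    f"insufficient frames for {self.n_mixtures}-mode GMM in "
                    f"{name} state: {int(np.sum(labels == s))} < "
                    f"{self.n_mixtures * n_channels}"
                )

        start_counts = np.zeros(N_STATES)
        trans_counts = np.zeros((N_STATES, N_STATES))
        for s in seqs:
            start_counts[s[0]] += 1
            np.add.at(trans_counts, (s[:-1], s[1:]), 1)
        self.startprob_ = start_counts / start_counts.sum()
        row_sums = trans_counts.sum(axis=1)
        if np.any(row_sums == 0):
            missing = "stance" if row_sums[STANCE] == 0 else "swing"
            raise ValueError(f"no transitions observed out of the {missing} state")
        self.transmat_ = trans_counts / row_sums[:, None]

        M = self.n_mixtures
        weights = np.zeros((N_STATES, M))
        means = np.zeros((N_STATES, M, n_channels))
        covars = np.zeros((N_STATES, M, n_channels))
        rng = np.random.default_rng(self.random_state)
        for s in (STANCE, SWING):
            Xs = frames[labels == s]
            if (
                self.max_frames_per_state is not None
                and Xs.shape[0] > self.max_frames_per_state
            ):
                keep = rng.choice(Xs.shape[0], self.max_frames_per_state, replace=False)
                Xs = Xs[np.sort(keep)]
            gmm = GaussianMixture(
                n_components=M,
                covariance_type="diag",
                max_iter=self.max_iter,
                tol=self.tol,
                reg_covar=1e-10,
                random_state=self.random_state,
                n_init=1,
            ).fit(Xs)
            floor = self.var_floor_frac * np.maximum(Xs.var(axis=0), 1e-300)
            weights[s] = gmm.weights_
            means[s] = gmm.means_
            covars[s] = np.maximum(gmm.covariances_, floor)
        self.weights_, self.means_, self.covars_ = weights, means, covars
        self.class_label_ = class_label
        self._check_fitted_params()
        return self

    # -- likelihood evaluation --------------------------------------------

    def _log_emission_probs(self, X: np.ndarray) -> np.ndarray:
        """Per-sample log density under each state's mixture: T x 2."""
        T, d = X.shape
        out = np.empty((T, N_STATES))
        for s in range(N_STATES):
            # component log densities: T x M
            diff = X[:, None, :] - self.means_[s][None, :, :]  # T x M x d
            maha = np.sum(diff * diff / self.covars_[s][None, :, :], axis=2)
            logdet = np.sum(np.log(self.covars_[s]), axis=1)  # M
            logcomp = (
                np.log(self.weights_[s])[None, :]
                - 0.5 * (maha + logdet[None, :] + d * np.log(2 * np.pi))
            )
            out[:, s] = logsumexp(logcomp, axis=1)
        return out

    @staticmethod
    def _as_array(X) -> np.ndarray:
        X = X.data if isinstance(X, EmissionMatrix) else np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("emissions must be a T x n_channels array")
        return X

    def _forward_cumulative(self, logB: np.ndarray) -> np.ndarray:
        """Scaled forward recursion returning log P(x_1..x_t) for every t.

        Per-sample rescaling keeps the recursion in floating range while
        remaining exact: emissions are used as ``b'_t = b_t * exp(-m_t)`` with
        ``m_t = max_s log b_t(s)``, and the removed factors are restored as a
        cumulative sum of the ``m_t``.
        """
        m = logB.max(axis=1)
        B = np.exp(logB - m[:, None])
        (a00, a01), (a10, a11) = self.transmat_
        p0, p1 = self.startprob_
        T = B.shape[0]
        cum = np.empty(T)
        b = B.tolist()  # scalar float arithmetic: ~10x faster than tiny ndarray ops
        b0, b1 = b[0]
        f0, f1 = p0 * b0, p1 * b1
        c = f0 + f1
        if c <= 0.0:
            cum[:] = -np.inf
            return cum
        f0, f1 = f0 / c, f1 / c
        total = _log(c)
        cum[0] = total
        for t in range(1, T):
            b0, b1 = b[t]
            g0 = (f0 * a00 + f1 * a10) * b0
            g1 = (f0 * a01 + f1 * a11) * b1
            c = g0 + g1
            if c <= 0.0:
                cum[t:] = -np.inf
                return cum
            f0, f1 = g0 / c, g1 / c
            total += _log(c)
            cum[t] = total
        return cum + np.cumsum(m)

    def log_likelihood_prefixes(self, X) -> np.ndarray:
        """Log-likelihood of every prefix ``x_1..x_t`` in a single forward
        pass; entry ``t-1`` equals ``log_likelihood(X[:t])``."""
        X = self._as_array(X)
        if not np.all(np.isfinite(X)):
            raise ValueError("emissions contain non-finite values")
        return self._forward_cumulative(self._log_emission_probs(X))

    def log_likelihood(self, X, window_samples: int | None = None) -> float:
        """Total observation log-probability by the scaled forward recursion.

        If ``window_samples`` is given, only the first that many samples are
        evaluated (the sequence must be at least that long).
        """
        X = self._as_array(X)
        if window_samples is not None:
            if X.shape[0] < window_samples:
                raise ValueError(
                    f"sequence of {X.shape[0]} samples shorter than the requested "
                    f"window of {window_samples}"
                )
            X = X[:window_samples]
        if not np.all(np.isfinite(X)):
            raise ValueError("emissions contain non-finite values")
        return float(self._forward_cumulative(self._log_emission_probs(X))[-1])

    def _log_likelihood_logdomain(self, X, window_samples: int | None = None) -> float:
        """Log-sum-exp forward recursion; cross-check for the scaled version."""
        X = self._as_array(X)
        if window_samples is not None:
            X = X[:window_samples]
        logB = self._log_emission_probs(X)
        with np.errstate(divide="ignore"):
            log_pi = np.log(self.startprob_)
            log_A = np.log(self.transmat_)
        log_alpha = log_pi + logB[0]
        for t in range(1, X.shape[0]):
            log_alpha = logsumexp(log_alpha[:, None] + log_A, axis=0) + logB[t]
        return float(logsumexp(log_alpha))

    def _log_likelihood_backward(self, X, window_samples: int | None = None) -> float:
        """Backward-recursion total likelihood; must agree with the forward."""
        X = self._as_array(X)
        if window_samples is not None:
            X = X[:window_samples]
        logB = self._log_emission_probs(X)
        with np.errstate(divide="ignore"):
            log_pi = np.log(self.startprob_)
            log_A = np.log(self.transmat_)
        log_beta = np.zeros(N_STATES)
        for t in range(X.shape[0] - 1, 0, -1):
            log_beta = logsumexp(log_A + (logB[t] + log_beta)[None, :], axis=1)
        return float(logsumexp(log_pi + logB[0] + log_beta))

    # -- sampling -----------------------------------------------------------

    def sample(self, n_samples: int, random_state: int | np.random.Generator = 0):
        """Draw ``(X, states)`` from the model's generative process."""
        rng = (
            random_state
            if isinstance(random_state, np.random.Generator)
            else np.random.default_rng(random_state)
        )
        d = self.means_.shape[2]
        states = np.empty(n_samples, dtype=int)
        X = np.empty((n_samples, d))
        states[0] = rng.choice(N_STATES, p=self.startprob_)
        for t in range(1, n_samples):
            states[t] = rng.choice(N_STATES, p=self.transmat_[states[t - 1]])
        for t in range(n_samples):
            s = states[t]
            m = rng.choice(self.weights_.shape[1], p=self.weights_[s])
            X[t] = rng.normal(self.means_[s, m], np.sqrt(self.covars_[s, m]))
        return X, states

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "class_label": getattr(self, "class_label_", None),
            "channel_names": list(CHANNEL_NAMES),
            "startprob": self.startprob_.tolist(),
            "transmat": self.transmat_.tolist(),
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "covars": self.covars_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitPhaseHMM":
        return cls.from_params(
            np.array(d["startprob"]),
            np.array(d["transmat"]),
            np.array(d["weights"]),
            np.array(d["means"]),
            np.array(d["covars"]),
            class_label=d.get("class_label"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GaitPhaseHMM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_hmm_supervised(
    emissions: list, states: list, class_label: str | None = None, **kwargs
) -> GaitPhaseHMM:
    """Functional wrapper over :meth:`GaitPhaseHMM.fit`."""
    return GaitPhaseHMM(**kwargs).fit(emissions, states, class_label=class_label)


def log_likelihood(model: GaitPhaseHMM, emissions, window_samples: int | None = None) -> float:
    """Functional wrapper over :meth:`GaitPhaseHMM.log_likelihood`."""
    return model.log_likelihood(emissions, window_samples=window_samples)


def classify_max_likelihood(
    models: dict[str, GaitPhaseHMM], emissions, window_samples: int | None = 256
) -> str:
    """Assign the class whose model gives the highest log-likelihood.

    The default 256-sample window is the first 2 s at 128 Hz.  Ties break by
    the fixed class order EL, PS, HD.
    """
    missing = [g for g in GROUP_LABELS if g not in models]
    if missing:
        raise ValueError(f"missing class models: {missing}")
    best_label, best_ll = None, -np.inf
    for label in GROUP_LABELS:
        ll = models[label].log_likelihood(emissions, window_samples=window_samples)
        if ll > best_ll:
            best_label, best_ll = label, ll
    return best_label


class HMMLikelihoodClassifier(BaseEstimator, ClassifierMixin):
    """Max-likelihood gait classifier over class-specific gait-phase HMMs.

    ``fit`` takes a list of :class:`~gaitclass.datamodel.IMUTrial` (labels
    from the trials, or an explicit ``y``) and trains one
    :class:`GaitPhaseHMM` per group from the gold-standard FS/TO annotations.
    ``predict`` evaluates each trial over the first ``window_s`` seconds.
    """

    def __init__(
        self,
        window_s: float | None = 2.0,
        n_mixtures: int = 3,
        random_state: int = 0,
        max_frames_per_state: int | None = 20000,
    ):
        self.window_s = window_s
        self.n_mixtures = n_mixtures
        self.random_state = random_state
        self.max_frames_per_state = max_frames_per_state

    def fit(self, trials: list[IMUTrial], y=None):
        labels = list(y) if y is not None else [t.group_label for t in trials]
        if any(lab is None for lab in labels):
            raise ValueError("all training trials must be labelled")
        groups: dict[str, tuple[list, list]] = {g: ([], []) for g in GROUP_LABELS}
        for trial, lab in zip(trials, labels):
            if lab not in groups:
                raise ValueError(f"unknown group label {lab!r}")
            em = build_emission_matrix(trial)
            groups[lab][0].append(em.data)
            groups[lab][1].append(events_to_states(trial.events, trial.n_samples))
        absent = [g for g, (mats, _) in groups.items() if not mats]
        if absent:
            raise ValueError(f"classes absent from training data: {absent}")
        self.models_ = {
            g: GaitPhaseHMM(
                n_mixtures=self.n_mixtures,
                random_state=self.random_state,
                max_frames_per_state=self.max_frames_per_state,
            ).fit(mats, states, class_label=g)
            for g, (mats, states) in groups.items()
        }
        self.classes_ = np.array(GROUP_LABELS)
        return self

    def _window_samples(self, trial: IMUTrial) -> int | None:
        return None if self.window_s is None else int(round(self.window_s * trial.fs))

    def predict(self, trials: list[IMUTrial]) -> np.ndarray:
        return np.array(
            [
                classify_max_likelihood(
                    self.models_,
                    build_emission_matrix(t),
                    window_samples=self._window_samples(t),
                )
                for t in trials
            ]
        )
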