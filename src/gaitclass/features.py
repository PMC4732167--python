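"""The 90-dimensional hybrid feature vector.

Per (passage, side) observation stream the vector stacks, in fixed order:

* ``H1-H6`` — HMM-based features: log-likelihoods of the EL, PS and HD
  gait-phase models over the first 2 s of the passage (H1-H3), and the three
  pairwise log-likelihood differences EL-PS, EL-HD, PS-HD evaluated over the
  whole passage (H4-H6).  Differencing removes the sequence-length dependence
  of a log-likelihood, so H4-H6 are comparable across passages of different
  duration.
* ``T1-T6`` per emission channel (42 values) — mean, standard deviation,
  variance, maximum, minimum, range.
* ``F1-F6`` per emission channel (42 values) — power at the first dominant
  frequency (P1), power at the second dominant frequency, the two dominant
  frequencies themselves, total power (PT) and the ratio P1/PT, from a
  periodogram of the mean-removed channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import GROUP_LABELS, IMUTrial
from .hmm import (
    CHANNEL_NAMES,
    EmissionMatrix,
    GaitPhaseHMM,
    build_emission_matrix,
    events_to_states,
)

logger = logging.getLogger(__name__)

TIME_FEATURE_NAMES = ("T1", "T2", "T3", "T4", "T5", "T6")
FREQ_FEATURE_NAMES = ("F1", "F2", "F3", "F4", "F5", "F6")
HMM_FEATURE_NAMES = ("H1", "H2", "H3", "H4", "H5", "H6")

#: Fixed layout of the 90-entry vector: H1-H6, then T1-T6 channel-major for
#: the seven emission channels, then F1-F6 channel-major.
FEATURE_NAMES: tuple[str, ...] = (
    HMM_FEATURE_NAMES
    + tuple(f"{f}_ch{c + 1}" for c in range(len(CHANNEL_NAMES)) for f in TIME_FEATURE_NAMES)
    + tuple(f"{f}_ch{c + 1}" for c in range(len(CHANNEL_NAMES)) for f in FREQ_FEATURE_NAMES)
)
N_FEATURES = len(FEATURE_NAMES)

#: Index ranges of the feature subsets compared in the ablation analysis.
FEATURE_SUBSETS: dict[str, slice] = {
    "hmm": slice(0, 6),
    "timefreq": slice(6, N_FEATURES),
    "full": slice(0, N_FEATURES),
}

#: Minimum peak separation when searching for the second dominant frequency,
#: so the shoulder bin of the main peak is never selected.
MIN_PEAK_SEPARATION_HZ = 0.2


def time_features(channel: np.ndarray) -> np.ndarray:
    """T1-T6: mean, sd, variance, max, min, range of one channel."""
    x = np.asarray(channel, dtype=float)
    if x.size < 2:
        raise ValueError("time features require at least 2 samples")
    sd = x.std()
    return np.array([x.mean(), sd, sd * sd, x.max(), x.min(), x.max() - x.min()])


def freq_features(channel: np.ndarray, fs: float) -> np.ndarray:
    """F1-F6 from the periodogram of the mean-removed channel.

    F3 is the frequency of the global spectral maximum (DC excluded), F1 the
    power there; F4 is the second-highest local maximum at least
    ``MIN_PEAK_SEPARATION_HZ`` away from F3 and F2 its power; F5 is the total
    power over (0, fs/2]; F6 = F1/F5.  A spectrally empty (constant) channel
    yields all zeros with a logged warning.
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 32:
        raise ValueError("frequency features require at least 32 samples")
    freqs, power = periodogram(
        x - x.mean(), fs=fs, window="boxcar", scaling="spectrum", detrend=False
    )
    freqs, power = freqs[1:], power[1:]  # exclude DC
    total = power.sum()
    if total <= 0:
        logger.warning("constant channel: frequency features undefined, returning 0")
        return np.zeros(6)
    i1 = int(np.argmax(power))
    f1, p1 = freqs[i1], power[i1]

    # local maxima (ends count when they dominate their single neighbour)
    left = np.r_[power[0] + 1, power[:-1]] if power.size > 1 else power
    right = np.r_[power[1:], 0.0]
    is_peak = (power >= left) & (power >= right)
    is_peak[i1] = False
    is_peak &= np.abs(freqs - f1) >= MIN_PEAK_SEPARATION_HZ
    if np.any(is_peak):
        cand = np.where(is_peak)[0]
        i2 = cand[np.argmax(power[cand])]
        f2, p2 = freqs[i2], power[i2]
    else:
        f2, p2 = 0.0, 0.0
    return np.array([p1, p2, f1, f2, total, p1 / total])


def hmm_features(
    models: dict[str, GaitPhaseHMM], emissions: EmissionMatrix | np.ndarray, fs: float
) -> np.ndarray:
    """H1-H6 for one observation stream under the three class models."""
    window = int(round(2 * fs))
    data = emissions.data if isinstance(emissions, EmissionMatrix) else np.asarray(emissions)
    if data.shape[0] < window:
        raise ValueError(
            f"passage of {data.shape[0]} samples shorter than the 2-s window ({window})"
        )
    ll_win, ll_all = {}, {}
    for g in GROUP_LABELS:
        prefixes = models[g].log_likelihood_prefixes(data)
        ll_win[g], ll_all[g] = prefixes[window - 1], prefixes[-1]
    return np.array(
        [
            ll_win["EL"],
            ll_win["PS"],
            ll_win["HD"],
            ll_all["EL"] - ll_all["PS"],
            ll_all["EL"] - ll_all["HD"],
            ll_all["PS"] - ll_all["HD"],
        ]
    )


@dataclass
class FeatureVector:
    """One 90-entry feature vector with its trial metadata."""

    values: np.ndarray
    subject_id: str = ""
    trial_id: str = ""
    side: str = ""
    group_label: str | None = None
    names: tuple[str, ...] = field(default=FEATURE_NAMES, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def assemble_features(trial: IMUTrial, models: dict[str, GaitPhaseHMM]) -> FeatureVector:
    """Compute the full 90-entry vector for one trial."""
    em = build_emission_matrix(trial)
    h = hmm_features(models, em, trial.fs)
    t = np.concatenate([time_features(em.data[:, c]) for c in range(em.data.shape[1])])
    f = np.concatenate(
        [freq_features(em.data[:, c], trial.fs) for c in range(em.data.shape[1])]
    )
    return FeatureVector(
        np.concatenate([h, t, f]),
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        side=trial.side,
        group_label=trial.group_label,
    )


def train_class_models(
    trials: list[IMUTrial], labels=None, **hmm_kwargs
) -> dict[str, GaitPhaseHMM]:
    """Train one supervised gait-phase HMM per group from labelled trials."""
    labels = list(labels) if labels is not None else [t.group_label for t in trials]
    groups: dict[str, tuple[list, list]] = {g: ([], []) for g in GROUP_LABELS}
    for trial, lab in zip(trials, labels):
        if lab not in groups:
            raise ValueError(f"unknown or missing group label {lab!r}")
        groups[lab][0].append(build_emission_matrix(trial).data)
        groups[lab][1].append(events_to_states(trial.events, trial.n_samples))
    absent = [g for g, (mats, _) in groups.items() if not mats]
    if absent:
        raise ValueError(f"classes absent from training data: {absent}")
    return {
        g: GaitPhaseHMM(**hmm_kwargs).fit(mats, states, class_label=g)
        for g, (mats, states) in groups.items()
    }


class HybridFeatureTransformer(BaseEstimator, TransformerMixin):
    """Trials -> 90-dimensional feature matrix.

    ``fit`` trains the three class-specific gait-phase HMMs on labelled
    trials (labels from the trials themselves or an explicit ``y``);
    ``transform`` maps a list of trials to an ``(n, 90)`` array in the fixed
    :data:`FEATURE_NAMES` layout.
    """

    def __init__(
        self,
        n_mixtures: int = 3,
        random_state: int = 0,
        max_frames_per_state: int | None = 20000,
    ):
        self.n_mixtures = n_mixtures
        self.random_state = random_state
        self.max_frames_per_state = max_frames_per_state

    def fit(self, X: list[IMUTrial], y=None):
        self.models_ = train_class_models(
            X,
            y,
            n_mixtures=self.n_mixtures,
            random_state=self.random_state,
            max_frames_per_state=self.max_frames_per_state,
        )
        return self

    def transform(self, X: list[IMUTrial]) -> np.ndarray:
        return np.vstack([assemble_features(t, self.models_).values for t in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)

    def feature_frame(self, X: list[IMUTrial]) -> pd.DataFrame:
        """Feature table with metadata columns, one row per (trial, side)."""
        meta = pd.DataFrame(
            {
                "subject_id": [t.subject_id for t in X],
                "trial_id": [t.trial_id for t in X],
                "side": [t.side for t in X],
                "group_label": [t.group_label for t in X],
            }
        )
        values = pd.DataFrame(self.transform(X), columns=list(FEATURE_NAMES))
        return pd.concat([meta, values], axis=1)
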