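"""Domain types for IMU gait trials and the zero-phase preprocessing filter.

A recording session consists of *passages* (one traversal of a walkway); each
passage yields two observation streams, one per shank sensor, so the atomic
unit handled here is an :class:`IMUTrial` identified by ``(subject_id,
trial_id, side)``.  All signal arrays use the fixed anatomical axis order
(VT, AP, ML) = (vertical, antero-posterior, medio-lateral).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

#: Class labels: healthy elderly, post-stroke, Huntington's disease.
GROUP_LABELS = ("EL", "PS", "HD")
SIDES = ("left", "right")
AXES = ("vt", "ap", "ml")

DEFAULT_FS = 128.0
FILTER_CUTOFF_HZ = 5.0
FILTER_ORDER = 2


class ValidationError(ValueError):
    """Raised when a trial or dataset violates a structural invariant."""


def lowpass_filter(
    x: np.ndarray,
    fs: float,
    cutoff: float = FILTER_CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward double pass).

    A second-order Butterworth filter applied forwards then backwards, which
    squares the magnitude response and cancels the phase response.  Edges are
    handled by odd reflection of length ``3 * (order + 1)`` samples.

    Parameters
    ----------
    x : 1-D array
        Signal to filter.
    fs : float
        Sampling rate in Hz.
    cutoff : float
        Cut-off frequency in Hz; must lie strictly below the Nyquist rate.
    order : int
        Order of the underlying (single-pass) Butterworth filter.

    Returns
    -------
    1-D array of the same length as ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {x.shape}")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if not 0 < cutoff < fs / 2:
        raise ValueError(
            f"cutoff must satisfy 0 < cutoff < fs/2 (got {cutoff} Hz at fs={fs} Hz)"
        )
    padlen = 3 * (order + 1)
    if len(x) <= padlen:
        raise ValueError(
            f"signal too short for a stable double pass: need > {padlen} samples, "
            f"got {len(x)}"
        )
    b, a = _sig.butter(order, cutoff, btype="low", fs=fs)
    return _sig.filtfilt(b, a, x, padtype="odd", padlen=padlen)


@dataclass(frozen=True)
class GaitEvents:
    """Foot-strike (FS) and toe-off (TO) sample indices of one trial.

    Stance runs from each FS to the following TO; swing from each TO to the
    next FS.  Indices are 0-based samples into the trial's signal arrays.
    """

    foot_strikes: tuple[int, ...]
    toe_offs: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "foot_strikes", tuple(int(i) for i in self.foot_strikes))
        object.__setattr__(self, "toe_offs", tuple(int(i) for i in self.toe_offs))

    @property
    def n_strides(self) -> int:
        return len(self.foot_strikes)

    def validate(self, n_samples: int) -> None:
        fs_idx, to_idx = self.foot_strikes, self.toe_offs
        if len(fs_idx) < 1 or len(to_idx) < 1:
            raise ValidationError("at least one FS-TO pair is required")
        if len(to_idx) not in (len(fs_idx), len(fs_idx) - 1):
            raise ValidationError(
                f"event counts cannot interleave: {len(fs_idx)} FS vs {len(to_idx)} TO"
            )
        merged = []
        for k in range(len(fs_idx)):
            merged.append(fs_idx[k])
            if k < len(to_idx):
                merged.append(to_idx[k])
        arr = np.asarray(merged)
        if np.any(np.diff(arr) <= 0):
            raise ValidationError("events must strictly interleave as FS < TO < FS < ...")
        if arr[0] < 0 or arr[-1] >= n_samples:
            raise ValidationError(
                f"event index out of range [0, {n_samples}): {arr.min()}..{arr.max()}"
            )


@dataclass
class IMUTrial:
    """One passage of one subject, observed from one shank plus the waist.

    Signals are ``T x 3`` arrays in axis order (VT, AP, ML): accelerations in
    m/s^2, angular velocities in rad/s.  ``group_label`` may be ``None`` at
    prediction time; ``impaired_side`` is required exactly for labelled
    post-stroke (PS) trials.
    """

    subject_id: str
    trial_id: str
    side: str
    fs: float
    shank_acc: np.ndarray
    shank_gyro: np.ndarray
    waist_acc: np.ndarray
    events: GaitEvents
    group_label: str | None = None
    impaired_side: str | None = None

    def __post_init__(self):
        self.shank_acc = np.asarray(self.shank_acc, dtype=float)
        self.shank_gyro = np.asarray(self.shank_gyro, dtype=float)
        self.waist_acc = np.asarray(self.waist_acc, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.shank_acc.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        ctx = f"trial {self.subject_id}/{self.trial_id}/{self.side}"
        if self.side not in SIDES:
            raise ValidationError(f"{ctx}: side must be one of {SIDES}")
        if self.fs <= 0:
            raise ValidationError(f"{ctx}: sampling rate must be positive")
        if self.group_label is not None and self.group_label not in GROUP_LABELS:
            raise ValidationError(f"{ctx}: unknown group label {self.group_label!r}")
        for name, arr in (
            ("shank_acc", self.shank_acc),
            ("shank_gyro", self.shank_gyro),
            ("waist_acc", self.waist_acc),
        ):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"{ctx}: {name} must be T x 3, got {arr.shape}")
            if arr.shape[0] != self.n_samples:
                raise ValidationError(
                    f"{ctx}: {name} length {arr.shape[0]} != {self.n_samples}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{ctx}: {name} contains non-finite values")
        if self.n_samples < 2 * self.fs:
            raise ValidationError(
                f"{ctx}: trial shorter than 2 s ({self.n_samples} samples at "
                f"{self.fs} Hz); a 2-s window is required downstream"
            )
        if self.group_label == "PS":
            if self.impaired_side not in SIDES:
                raise ValidationError(f"{ctx}: PS trials require impaired_side")
        elif self.group_label is not None and self.impaired_side is not None:
            raise ValidationError(f"{ctx}: impaired_side only applies to PS trials")
        try:
            self.events.validate(self.n_samples)
        except ValidationError as exc:
            raise ValidationError(f"{ctx}: {exc}") from exc


@dataclass
class Dataset:
    """A cohort of trials, indexed by subject."""

    trials: list[IMUTrial] = field(default_factory=list)

    @property
    def subjects(self) -> dict[str, list[IMUTrial]]:
        index: dict[str, list[IMUTrial]] = {}
        for t in self.trials:
            index.setdefault(t.subject_id, []).append(t)
        return index

    @property
    def subject_labels(self) -> dict[str, str | None]:
        return {sid: trials[0].group_label for sid, trials in self.subjects.items()}

    def class_counts(self) -> dict[str, int]:
        """Number of subjects per group label."""
        counts: dict[str, int] = {}
        for label in self.subject_labels.values():
            counts[label] = counts.get(label, 0) + 1
        return counts

    def validate(self) -> None:
        if not self.trials:
            raise ValidationError("empty dataset")
        for t in self.trials:
            t.validate()
        for sid, trials in self.subjects.items():
            labels = {t.group_label for t in trials}
            if len(labels) > 1:
                raise ValidationError(
                    f"subject {sid} has inconsistent group labels: {sorted(map(str, labels))}"
                )
        keys = [(t.subject_id, t.trial_id, t.side) for t in self.trials]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (subject, trial, side) keys in dataset")
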