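"""Synthetic IMU gait cohort generator.

Real recordings of the three study groups (healthy elderly EL, post-stroke PS,
Huntington's disease HD) are not publicly deposited, so this module generates
labelled cohorts carrying the statistical structure the classification
framework relies on:

* class-specific stride timing (mean stride time and stride-to-stride
  coefficient of variation), stance fraction and signal amplitudes;
* PS-specific left/right asymmetry: the impaired side walks with a longer
  stance fraction and attenuated shank ML angular velocity;
* HD-specific inflated stride-time variability;
* between-subject variability in timing and amplitude, so that held-out
  subjects are genuinely new;
* exact foot-strike / toe-off annotations, recorded from the construction.

Each raw channel is a stride-locked smooth template (a sum of Gaussian bumps
positioned within stance and swing), time-warped by per-stride sampled
stance/swing durations, plus white sensor noise, then passed through the same
5 Hz zero-phase low-pass filter applied to real recordings.  The waist ML
channel flips sign between sides, mirroring the fixed ML axis convention.
The generator makes no claim to biomechanical fidelity — the two shanks of a
passage are drawn independently rather than half a cycle apart, and bump
shapes are stylised — it provides class-consistent morphology and timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .datamodel import Dataset, GaitEvents, IMUTrial, lowpass_filter

RAW_CHANNELS = (
    "shank_acc_vt",
    "shank_acc_ap",
    "shank_acc_ml",
    "shank_gyro_vt",
    "shank_gyro_ap",
    "shank_gyro_ml",
    "waist_acc_vt",
    "waist_acc_ap",
    "waist_acc_ml",
)

#: Template anchor: fraction of the normalised stride phase occupied by stance.
PHASE_STANCE = 0.6

#: Stride templates: channel -> list of (phase centre, phase width, amplitude).
#: Phases live on the circle [0, 1); stance occupies [0, PHASE_STANCE).
#: Amplitudes are m/s^2 for accelerometers, rad/s for gyroscopes; a constant
#: baseline (gravity on the vertical accelerometers) is added separately.
TEMPLATES: dict[str, list[tuple[float, float, float]]] = {
    "shank_acc_vt": [(0.02, 0.02, 4.0), (0.55, 0.04, -1.5), (0.80, 0.06, 1.0)],
    "shank_acc_ap": [(0.02, 0.02, 3.0), (0.58, 0.05, -2.0), (0.85, 0.05, 1.5)],
    "shank_acc_ml": [(0.03, 0.03, 1.0), (0.70, 0.08, -0.8)],
    "shank_gyro_vt": [(0.10, 0.06, 0.5), (0.80, 0.08, -0.6)],
    "shank_gyro_ap": [(0.05, 0.04, 0.6), (0.75, 0.08, 0.5)],
    "shank_gyro_ml": [(0.05, 0.04, -1.0), (0.55, 0.05, -0.9), (0.80, 0.08, 4.0)],
    "waist_acc_vt": [(0.02, 0.03, 1.5), (0.52, 0.03, 1.4)],
    "waist_acc_ap": [(0.05, 0.04, 1.0), (0.60, 0.05, -0.8)],
    "waist_acc_ml": [(0.30, 0.10, 1.2), (0.80, 0.08, -0.5)],
}

BASELINES = {"shank_acc_vt": 9.81, "waist_acc_vt": 9.81}

GRAVITY_CHANNELS = tuple(BASELINES)


@dataclass(frozen=True)
class ClassParams:
    """Per-class gait parameters of the generator.

    ``stride_time_s`` and ``stance_fraction`` set the mean timing;
    ``stride_time_cv`` / ``stance_fraction_cv`` the within-subject
    stride-to-stride coefficients of variation.  ``acc_scale`` / ``gyro_scale``
    multiply the template amplitudes.  For the PS class,
    ``impaired_stance_ratio`` multiplies the stance fraction on the impaired
    side and ``impaired_gyro_ml_scale`` attenuates that side's shank ML
    angular velocity.
    """

    stride_time_s: float = 1.10
    stride_time_cv: float = 0.03
    stance_fraction: float = 0.62
    stance_fraction_cv: float = 0.02
    acc_scale: float = 1.0
    gyro_scale: float = 1.0
    impaired_stance_ratio: float = 1.0
    impaired_gyro_ml_scale: float = 1.0


#: Default class parameters.  EL is the reference; PS walks slower with
#: attenuated amplitudes and a marked side asymmetry; HD shows the highest
#: stride-to-stride variability and larger, more erratic amplitudes.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "EL": ClassParams(),
    "PS": ClassParams(
        stride_time_s=1.40,
        stride_time_cv=0.07,
        stance_fraction=0.66,
        stance_fraction_cv=0.04,
        acc_scale=0.85,
        gyro_scale=0.65,
        impaired_stance_ratio=1.10,
        impaired_gyro_ml_scale=0.55,
    ),
    "HD": ClassParams(
        stride_time_s=1.20,
        stride_time_cv=0.16,
        stance_fraction=0.58,
        stance_fraction_cv=0.06,
        acc_scale=1.25,
        gyro_scale=1.35,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition configuration of a synthetic cohort.

    Defaults mirror the study population: 10 EL / 15 PS / 17 HD subjects,
    2-16 walkway passages per subject, and 3-6 strides per passage (mean 4.5)
    at 128 Hz.
    """

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"EL": 10, "PS": 15, "HD": 17}
    )
    passages_per_subject: tuple[int, int] = (2, 16)
    strides_per_passage: tuple[int, int] = (3, 6)
    fs: float = 128.0
    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    acc_noise_sd: float = 0.25
    gyro_noise_sd: float = 0.08
    subject_amp_sd: float = 0.05
    subject_timing_sd: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        for grp, p in self.class_params.items():
            if not 0 < p.stance_fraction < 1:
                raise ValueError(f"{grp}: stance fraction must lie in (0, 1)")
            if not 0 < p.stance_fraction * p.impaired_stance_ratio < 1:
                raise ValueError(f"{grp}: impaired stance fraction leaves (0, 1)")
            if p.stride_time_cv < 0 or p.stance_fraction_cv < 0:
                raise ValueError(f"{grp}: coefficients of variation must be >= 0")
            if p.stride_time_s * self.fs < 4:
                raise ValueError(
                    f"{grp}: stride of {p.stride_time_s}s is shorter than 4 samples "
                    f"at {self.fs} Hz"
                )
        lo, hi = self.passages_per_subject
        if not 1 <= lo <= hi:
            raise ValueError("invalid passage range")
        lo, hi = self.strides_per_passage
        if not 1 <= lo <= hi:
            raise ValueError("invalid stride range")


def three_class_config(separation: float = 1.0, seed: int = 0, **overrides) -> CohortConfig:
    """Default three-class cohort, with a class-separation interpolation knob.

    ``separation=1`` gives the default class parameters; ``separation=0``
    collapses every class onto the EL reference (and removes the PS
    asymmetry), a null cohort on which classifiers should perform at chance.
    Intermediate values interpolate every class parameter linearly.
    """
    base = DEFAULT_CLASS_PARAMS["EL"]
    params = {}
    for grp, p in DEFAULT_CLASS_PARAMS.items():
        params[grp] = ClassParams(
            **{
                name: getattr(base, name)
                + separation * (getattr(p, name) - getattr(base, name))
                for name in ClassParams.__dataclass_fields__
            }
        )
    return CohortConfig(class_params=params, seed=seed, **overrides)


def _truncated_normal(rng, mean, sd, size=None):
    """Normal truncated at +/- 3 SD (degenerate at sd = 0)."""
    if sd == 0:
        return np.full(size, mean, dtype=float) if size is not None else float(mean)
    return truncnorm.rvs(-3, 3, loc=mean, scale=sd, size=size, random_state=rng)


def _bump_profile(phase: np.ndarray, bumps, scale: float) -> np.ndarray:
    out = np.zeros_like(phase)
    for centre, width, amp in bumps:
        dist = np.abs(phase - centre)
        dist = np.minimum(dist, 1.0 - dist)  # periodic phase distance
        out += amp * np.exp(-0.5 * (dist / width) ** 2)
    return out * scale


def _generate_trial(
    rng: np.random.Generator,
    config: CohortConfig,
    params: ClassParams,
    group: str,
    subject_id: str,
    trial_id: str,
    side: str,
    impaired_side: str | None,
    n_strides: int,
    subj_amp: float,
    subj_timing: float,
) -> IMUTrial:
    fs = config.fs
    impaired = side == impaired_side
    stance_frac = params.stance_fraction * (
        params.impaired_stance_ratio if impaired else 1.0
    )

    stride_times = _truncated_normal(
        rng,
        params.stride_time_s * subj_timing,
        params.stride_time_cv * params.stride_time_s,
        size=n_strides,
    )
    stance_fracs = np.clip(
        _truncated_normal(
            rng, stance_frac, params.stance_fraction_cv * stance_frac, size=n_strides
        ),
        0.05,
        0.95,
    )
    stride_samples = np.maximum(np.rint(stride_times * fs).astype(int), 4)
    stance_samples = np.clip(
        np.rint(stride_samples * stance_fracs).astype(int), 2, stride_samples - 2
    )
    if np.any(stride_samples < 4):
        raise ValueError("infeasible config: stride shorter than 4 samples")

    T = int(stride_samples.sum())
    phase = np.empty(T)
    foot_strikes, toe_offs = [], []
    pos = 0
    for n_str, n_sta in zip(stride_samples, stance_samples):
        n_swi = n_str - n_sta
        foot_strikes.append(pos)
        toe_offs.append(pos + n_sta)
        phase[pos : pos + n_sta] = PHASE_STANCE * np.arange(n_sta) / n_sta
        phase[pos + n_sta : pos + n_str] = PHASE_STANCE + (1 - PHASE_STANCE) * (
            np.arange(n_swi) / n_swi
        )
        pos += n_str

    signals = {}
    for name in RAW_CHANNELS:
        scale = params.gyro_scale if "gyro" in name else params.acc_scale
        scale *= subj_amp
        if name == "shank_gyro_ml" and impaired:
            scale *= params.impaired_gyro_ml_scale
        if name == "waist_acc_ml" and side == "left":
            scale = -scale
        noise_sd = config.gyro_noise_sd if "gyro" in name else config.acc_noise_sd
        x = _bump_profile(phase, TEMPLATES[name], scale)
        x += BASELINES.get(name, 0.0)
        x += rng.normal(0.0, noise_sd, size=T)
        signals[name] = lowpass_filter(x, fs)

    stack = lambda sensor: np.column_stack(
        [signals[f"{sensor}_{ax}"] for ax in ("vt", "ap", "ml")]
    )
    return IMUTrial(
        subject_id=subject_id,
        trial_id=trial_id,
        side=side,
        fs=fs,
        shank_acc=stack("shank_acc"),
        shank_gyro=stack("shank_gyro"),
        waist_acc=stack("waist_acc"),
        events=GaitEvents(foot_strikes, toe_offs),
        group_label=group,
        impaired_side=impaired_side,
    )


def generate_cohort(config: CohortConfig) -> Dataset:
    """Generate a labelled synthetic cohort; deterministic in ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials: list[IMUTrial] = []
    for group in ("EL", "PS", "HD"):
        n_subj = config.n_subjects.get(group, 0)
        params = config.class_params[group]
        for i in range(n_subj):
            subject_id = f"{group}{i + 1:02d}"
            impaired_side = (
                ("left", "right")[rng.integers(2)] if group == "PS" else None
            )
            subj_amp = _truncated_normal(rng, 1.0, config.subject_amp_sd)
            subj_timing = _truncated_normal(rng, 1.0, config.subject_timing_sd)
            n_passages = int(
                rng.integers(
                    config.passages_per_subject[0], config.passages_per_subject[1] + 1
                )
            )
            for p in range(n_passages):
                n_strides = int(
                    rng.integers(
                        config.strides_per_passage[0], config.strides_per_passage[1] + 1
                    )
                )
                for side in ("left", "right"):
                    trials.append(
                        _generate_trial(
                            rng,
                            config,
                            params,
                            group,
                            subject_id,
                            f"P{p + 1:02d}",
                            side,
                            impaired_side,
                            n_strides,
                            subj_amp,
                            subj_timing,
                        )
                    )
    dataset = Dataset(trials)
    dataset.validate()
    return dataset


def event_truth_table(dataset: Dataset) -> pd.DataFrame:
    """Per-stride stance/swing durations (in samples) derived from the events.

    For cohorts produced by :func:`generate_cohort` each trial ends exactly at
    the end of its last swing, so the final swing duration is measured to the
    end of the signal.
    """
    rows = []
    for trial in dataset.trials:
        fs_idx = trial.events.foot_strikes
        to_idx = trial.events.toe_offs
        for k in range(len(to_idx)):
            stance = to_idx[k] - fs_idx[k]
            end = fs_idx[k + 1] if k + 1 < len(fs_idx) else trial.n_samples
            swing = end - to_idx[k]
            rows.append(
                {
                    "subject_id": trial.subject_id,
                    "trial_id": trial.trial_id,
                    "side": trial.side,
                    "group_label": trial.group_label,
                    "impaired": trial.side == trial.impaired_side,
                    "stride": k,
                    "stance_samples": stance,
                    "swing_samples": swing,
                    "stride_samples": stance + swing,
                }
            )
    return pd.DataFrame(rows)
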