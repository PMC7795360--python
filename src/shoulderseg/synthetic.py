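"""Synthetic two-IMU shoulder-task recordings with labeled sub-task phases.

The study design being emulated: subjects (healthy controls and frozen-shoulder
patients) each perform five functional shoulder tasks once, wearing one IMU on
the wrist and one on the arm, sampled at 128 Hz. Every task decomposes into
three contiguous sub-task phases — A (lifting), B (hold / washing motion),
C (lowering) — whose durations are group- and task-specific (see
:data:`DURATION_TABLE`).

Each sub-task is rendered as a smooth parametric motif on a latent elevation
profile theta(t) in [0, 1]:

* A — raised-cosine ramp 0 -> 1,
* B — hold near 1 with a low-amplitude oscillation (the repetitive washing /
  holding motion),
* C — mirrored raised-cosine ramp 1 -> 0.

Gyroscope channels follow d(theta)/dt (deg/s), accelerometer channels follow
theta itself (gravity re-orientation plus motion, in g), with fixed per-task
channel gain directions so the five tasks are mutually distinguishable and
arm amplitudes a fixed fraction of wrist amplitudes. Frozen-shoulder profiles
move with reduced amplitude and slower tempo, and draw their durations from
the patient column of the duration table. Motif shapes are deliberately
simple templates: what matters downstream is that phases and tasks are
*relatively* distinguishable, not biomechanical fidelity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats

from .constants import CHANNELS, FS_HZ, SUBTASKS, TASKS

__all__ = [
    "DURATION_TABLE",
    "DurationModel",
    "SubjectProfile",
    "TaskSequence",
    "generate_sequence",
    "generate_dataset",
]


#: Mean +/- SD sub-task durations in seconds per (task, sub-task, group),
#: as reported for healthy subjects and frozen-shoulder (fs) patients.
DURATION_TABLE: dict[tuple[str, str, str], tuple[float, float]] = {
    ("T1", "A", "healthy"): (0.86, 0.15), ("T1", "A", "fs"): (1.60, 0.73),
    ("T1", "B", "healthy"): (3.13, 1.18), ("T1", "B", "fs"): (5.66, 2.00),
    ("T1", "C", "healthy"): (0.90, 0.20), ("T1", "C", "fs"): (1.18, 0.16),
    ("T2", "A", "healthy"): (1.16, 0.25), ("T2", "A", "fs"): (1.82, 0.85),
    ("T2", "B", "healthy"): (2.58, 0.75), ("T2", "B", "fs"): (7.81, 3.75),
    ("T2", "C", "healthy"): (1.18, 0.20), ("T2", "C", "fs"): (1.35, 0.21),
    ("T3", "A", "healthy"): (0.78, 0.12), ("T3", "A", "fs"): (1.10, 0.44),
    ("T3", "B", "healthy"): (3.09, 1.15), ("T3", "B", "fs"): (6.32, 4.19),
    ("T3", "C", "healthy"): (0.99, 0.21), ("T3", "C", "fs"): (0.94, 0.25),
    ("T4", "A", "healthy"): (1.53, 0.35), ("T4", "A", "fs"): (2.02, 0.65),
    ("T4", "B", "healthy"): (0.97, 0.49), ("T4", "B", "fs"): (1.98, 0.53),
    ("T4", "C", "healthy"): (1.52, 0.41), ("T4", "C", "fs"): (1.25, 0.45),
    ("T5", "A", "healthy"): (1.47, 0.46), ("T5", "A", "fs"): (1.79, 0.75),
    ("T5", "B", "healthy"): (0.90, 0.65), ("T5", "B", "fs"): (0.89, 0.68),
    ("T5", "C", "healthy"): (2.42, 2.44), ("T5", "C", "fs"): (1.37, 0.35),
}

_GROUPS = ("healthy", "fs")

# Generator amplitude constants (free parameters of the simulator; the study
# reports no signal-amplitude statistics). Units: g for accelerometers,
# degrees for the latent elevation span (so gyro = span * dtheta/dt, deg/s).
_ACC_SPAN_G = 0.5
_GYRO_SPAN_DEG = 90.0
_ARM_FACTOR = 0.6
_HOLD_OSC_AMP = 0.06
_TASK_PARAM_SEED = 20201226  # fixed: task signatures must not vary per run


@dataclass(frozen=True)
class DurationModel:
    """Truncated-normal sub-task duration distributions per task and group.

    ``table[(task, sub_task, group)] = (mean_s, sd_s)``. Draws are truncated
    below at ``min_s``; the underlying location parameter is solved so that
    the *truncated* mean equals ``mean_s`` (mean-preserving truncation), so
    empirical averages converge to the tabulated means.
    """

    table: dict[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DURATION_TABLE)
    )
    min_s: float = 0.2

    def __post_init__(self) -> None:
        if self.min_s <= 0:
            raise ValueError("min_s must be positive")
        for key, (mean_s, sd_s) in self.table.items():
            if mean_s <= 0:
                raise ValueError(f"non-positive mean duration for {key}")
            if sd_s < 0:
                raise ValueError(f"negative duration SD for {key}")
            if mean_s <= self.min_s:
                raise ValueError(f"mean duration for {key} not above min_s")

    def params(self, task_id: str, sub_task: str, group: str) -> tuple[float, float]:
        try:
            return self.table[(task_id, sub_task, group)]
        except KeyError:
            raise KeyError(
                f"no duration entry for task={task_id!r} sub_task={sub_task!r} "
                f"group={group!r}"
            ) from None

    def _location(self, mean_s: float, sd_s: float) -> float:
        """Location mu such that a normal(mu, sd) truncated at min_s has mean mean_s."""
        if sd_s == 0:
            return mean_s

        def excess(mu: float) -> float:
            a = (self.min_s - mu) / sd_s
            # normal hazard phi(a)/sf(a) via erfcx, stable for any a
            hazard = np.sqrt(2.0 / np.pi) / special.erfcx(a / np.sqrt(2.0))
            return mu + sd_s * hazard - mean_s

        # E[trunc] >= mean at mu = mean_s and -> min_s as mu -> -inf.
        lo = mean_s - 40.0 * sd_s
        return optimize.brentq(excess, lo, mean_s, xtol=1e-10)

    def sample(
        self, task_id: str, sub_task: str, group: str, rng: np.random.Generator
    ) -> float:
        """Draw one duration in seconds."""
        mean_s, sd_s = self.params(task_id, sub_task, group)
        if sd_s == 0:
            return mean_s
        mu = _location_cached(self, mean_s, sd_s)
        a = (self.min_s - mu) / sd_s
        return float(
            stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd_s, random_state=rng)
        )


_LOCATION_CACHE: dict[tuple[float, float, float], float] = {}


def _location_cached(model: DurationModel, mean_s: float, sd_s: float) -> float:
    key = (model.min_s, mean_s, sd_s)
    if key not in _LOCATION_CACHE:
        _LOCATION_CACHE[key] = model._location(mean_s, sd_s)
    return _LOCATION_CACHE[key]


@dataclass(frozen=True)
class SubjectProfile:
    """How one simulated subject moves.

    ``amplitude_scale`` multiplies all motion amplitudes (frozen-shoulder
    patients move through a limited range, so fs < healthy); ``tempo_scale``
    multiplies the oscillation frequency of the hold phase; noise SDs are the
    white measurement noise per channel class.
    """

    subject_id: str
    group: str
    amplitude_scale: float = 1.0
    tempo_scale: float = 1.0
    noise_sd_accel: float = 0.02  # g
    noise_sd_gyro: float = 2.0  # deg/s

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.amplitude_scale <= 0 or self.tempo_scale <= 0:
            raise ValueError("amplitude_scale and tempo_scale must be positive")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValueError("noise SDs must be non-negative")

    @classmethod
    def default(cls, group: str, subject_id: str = "S01") -> "SubjectProfile":
        """Group-default profile: healthy full-range, fs reduced and slower."""
        if group == "healthy":
            return cls(subject_id, group, amplitude_scale=1.0, tempo_scale=1.0)
        return cls(subject_id, group, amplitude_scale=0.6, tempo_scale=0.8)


@dataclass
class TaskSequence:
    """One recorded or simulated shoulder-task trial.

    ``signal`` is (n, 12) in the :data:`~shoulderseg.constants.CHANNELS`
    order; ``gt_labels`` is the per-sample sub-task label array (``'A'``,
    ``'B'``, ``'C'`` forming exactly three contiguous runs in that order);
    ``boundaries`` holds the 1-based sample indices of the first B sample
    (A->B) and the first C sample (B->C).
    """

    signal: np.ndarray
    fs_hz: int
    subject_id: str
    group: str
    task_id: str
    gt_labels: np.ndarray
    boundaries: tuple[int, int]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.gt_labels = np.asarray(self.gt_labels, dtype="U1")
        if self.signal.ndim != 2 or self.signal.shape[1] != len(CHANNELS):
            raise ValueError(
                f"signal must be (n, {len(CHANNELS)}), got {self.signal.shape}"
            )
        if self.task_id not in TASKS:
            raise ValueError(f"unknown task_id {self.task_id!r}")
        if self.group not in _GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if len(self.gt_labels) != self.n_samples:
            raise ValueError("gt_labels length must match signal length")
        runs = label_runs(self.gt_labels)
        if [r[0] for r in runs] != list(SUBTASKS):
            raise ValueError(
                "gt_labels must form exactly three contiguous runs A, B, C "
                f"(got runs {[r[0] for r in runs]})"
            )
        n_a, n_b = runs[0][1], runs[1][1]
        self.boundaries = (int(self.boundaries[0]), int(self.boundaries[1]))
        if self.boundaries != (n_a + 1, n_a + n_b + 1):
            raise ValueError("boundaries inconsistent with gt_labels")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def subtask_durations_s(self) -> dict[str, float]:
        """Seconds spent in each sub-task, from the ground-truth labels."""
        return {
            lab: n / self.fs_hz for lab, n in label_runs(self.gt_labels)
        }


def label_runs(labels: np.ndarray | list) -> list[tuple[str, int]]:
    """Run-length encode a label sequence: [(label, run_length), ...]."""
    labels = list(labels)
    if not labels:
        return []
    runs: list[tuple[str, int]] = []
    cur, count = labels[0], 1
    for lab in labels[1:]:
        if lab == cur:
            count += 1
        else:
            runs.append((cur, count))
            cur, count = lab, 1
    runs.append((cur, count))
    return runs


def _task_params(task_id: str) -> dict:
    """Fixed per-task channel signature (gain directions, hold frequency).

    Drawn once from a constant seed offset by the task index so that every
    run of the simulator gives the same five mutually distinct tasks.
    """
    idx = TASKS.index(task_id)
    rng = np.random.default_rng(_TASK_PARAM_SEED + idx)

    def unit(n: int) -> np.ndarray:
        v = rng.uniform(-1.0, 1.0, size=n)
        return v / np.linalg.norm(v)

    return {
        "acc_dir_wrist": unit(3),
        "gyro_dir_wrist": unit(3),
        "acc_dir_arm": unit(3),
        "gyro_dir_arm": unit(3),
        "acc_offset_wrist": rng.uniform(-0.5, 0.5, size=3),
        "acc_offset_arm": rng.uniform(-0.5, 0.5, size=3),
        "hold_freq_hz": rng.uniform(1.5, 3.0),
    }


def _elevation_profile(
    n_a: int, n_b: int, n_c: int, hold_freq_hz: float, fs_hz: int
) -> np.ndarray:
    """Latent elevation theta(t): ramp up, oscillating hold, ramp down."""
    tau_a = np.arange(n_a) / max(n_a - 1, 1)
    tau_c = np.arange(n_c) / max(n_c - 1, 1)
    t_b = np.arange(n_b) / fs_hz
    theta_a = 0.5 * (1.0 - np.cos(np.pi * tau_a))
    theta_b = 1.0 + _HOLD_OSC_AMP * np.sin(2.0 * np.pi * hold_freq_hz * t_b)
    theta_c = 0.5 * (1.0 + np.cos(np.pi * tau_c))
    return np.concatenate([theta_a, theta_b, theta_c])


def generate_sequence(
    profile: SubjectProfile,
    task_id: str,
    durations: DurationModel | None = None,
    seed: int | np.random.Generator = 0,
) -> TaskSequence:
    """Simulate one labeled shoulder-task trial for one subject.

    Sub-task durations are drawn from the group's truncated-normal duration
    model; the 12 channels are rendered from the latent elevation profile
    with the task's fixed gain signature, scaled by the subject's amplitude,
    plus white Gaussian measurement noise. Identical seed, identical output.
    """
    if task_id not in TASKS:
        raise ValueError(f"unknown task_id {task_id!r}")
    durations = durations if durations is not None else DurationModel()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    par = _task_params(task_id)

    n_sub = {
        st: max(1, int(round(durations.sample(task_id, st, profile.group, rng) * FS_HZ)))
        for st in SUBTASKS
    }
    n_a, n_b, n_c = n_sub["A"], n_sub["B"], n_sub["C"]
    theta = _elevation_profile(
        n_a, n_b, n_c, par["hold_freq_hz"] * profile.tempo_scale, FS_HZ
    )
    dtheta = np.gradient(theta) * FS_HZ  # per second

    amp = profile.amplitude_scale
    sig = np.empty((theta.size, len(CHANNELS)))
    # wrist accel / gyro, then arm at a fixed reduced amplitude
    sig[:, 0:3] = par["acc_offset_wrist"] + _ACC_SPAN_G * amp * np.outer(
        theta, par["acc_dir_wrist"]
    )
    sig[:, 3:6] = _GYRO_SPAN_DEG * amp * np.outer(dtheta, par["gyro_dir_wrist"])
    sig[:, 6:9] = par["acc_offset_arm"] + _ACC_SPAN_G * _ARM_FACTOR * amp * np.outer(
        theta, par["acc_dir_arm"]
    )
    sig[:, 9:12] = _GYRO_SPAN_DEG * _ARM_FACTOR * amp * np.outer(
        dtheta, par["gyro_dir_arm"]
    )

    sig[:, 0:3] += rng.normal(0.0, profile.noise_sd_accel, size=(theta.size, 3))
    sig[:, 3:6] += rng.normal(0.0, profile.noise_sd_gyro, size=(theta.size, 3))
    sig[:, 6:9] += rng.normal(0.0, profile.noise_sd_accel, size=(theta.size, 3))
    sig[:, 9:12] += rng.normal(0.0, profile.noise_sd_gyro, size=(theta.size, 3))

    gt = np.concatenate(
        [np.full(n_a, "A"), np.full(n_b, "B"), np.full(n_c, "C")]
    ).astype("U1")
    return TaskSequence(
        signal=sig,
        fs_hz=FS_HZ,
        subject_id=profile.subject_id,
        group=profile.group,
        task_id=task_id,
        gt_labels=gt,
        boundaries=(n_a + 1, n_a + n_b + 1),
    )


def generate_dataset(
    n_healthy: int,
    n_fs: int,
    tasks: list[str] | tuple[str, ...] = TASKS,
    seed: int = 0,
    durations: DurationModel | None = None,
) -> list[TaskSequence]:
    """Simulate a cohort: one sequence per (subject, task) pair.

    Subject profiles start from the group defaults and get mild reproducible
    inter-subject variation (amplitude and tempo jitter). The study-scale
    call is ``generate_dataset(9, 9)`` -> 18 subjects x 5 tasks = 90
    sequences.
    """
    if n_healthy < 0 or n_fs < 0:
        raise ValueError("subject counts must be non-negative")
    tasks = list(tasks)
    if not tasks:
        raise ValueError("task list must not be empty")
    for t in tasks:
        if t not in TASKS:
            raise ValueError(f"unknown task_id {t!r}")
    durations = durations if durations is not None else DurationModel()

    subjects = [("healthy", f"H{i + 1:02d}") for i in range(n_healthy)]
    subjects += [("fs", f"P{i + 1:02d}") for i in range(n_fs)]

    root = np.random.SeedSequence(seed)
    sequences: list[TaskSequence] = []
    for child, (group, subject_id) in zip(root.spawn(len(subjects)), subjects):
        rng = np.random.default_rng(child)
        base = SubjectProfile.default(group, subject_id)
        profile = replace(
            base,
            amplitude_scale=base.amplitude_scale * rng.uniform(0.9, 1.1),
            tempo_scale=base.tempo_scale * rng.uniform(0.9, 1.1),
        )
        for task_id in tasks:
            sequences.append(generate_sequence(profile, task_id, durations, rng))
    return sequences
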