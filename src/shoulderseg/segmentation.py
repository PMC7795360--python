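"""Window-level sub-task segmentation with rule-based label repair.

Pipeline per sequence: fixed-stride sliding windows over the pre-processed
12-channel signal -> 144 features per window -> per-model PCA -> 3-class
window classification (labels A/B/C) -> single-pass rule-based repair of
isolated window labels -> expansion of window labels back to a per-sample
label stream.

Window bookkeeping follows the 1-based inclusive convention: window j spans
samples [sp, ep] with sp starting at 1 and advancing by the stride ``ss``
until ep would pass the end of the sequence, giving
``n_S = floor((n_seq - ws) / ss) + 1`` windows; a trailing residue shorter
than ``ss`` is dropped. The sample-label stream assigns the first
``n_S - 1`` window labels to ``ss`` samples each and the last window label
to ``ws`` samples, so its total length is ``n_g = ws + ss * (n_S - 1)``.

The repair rule: an interior window label that differs from both temporal
neighbors, while those neighbors agree with each other, is a fragmentation
error and is replaced by the neighbor label. The pass reads the *original*
label sequence only, so one application is exhaustive (idempotent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import FS_HZ, SUBTASKS, TASKS
from .features import PcaTransform, apply_pca, fit_pca, sequence_features
from .preprocessing import SwmaConfig, swma_filter
from .task_id import LabelClassifier, TaskClassifierSpec

__all__ = [
    "WindowConfig",
    "LabelStream",
    "SubtaskModelSet",
    "sliding_window",
    "window_majority_label",
    "train_subtask_models",
    "classify_windows",
    "rule_modify",
    "generate_sample_labels",
    "segment_sequence",
]

logger = logging.getLogger(__name__)

_SCOPES = ("per_task", "global")
_GLOBAL_KEY = "global"


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry in samples: length ``ws`` and stride ``ss``."""

    ws: int
    ss: int

    def __post_init__(self) -> None:
        if self.ws < 1:
            raise ValueError("ws must be >= 1")
        if not (1 <= self.ss <= self.ws):
            raise ValueError("ss must satisfy 1 <= ss <= ws")

    @property
    def os(self) -> int:
        """Overlapping samples between consecutive windows."""
        return self.ws - self.ss

    @property
    def op(self) -> float:
        """Overlap fraction os / ws."""
        return self.os / self.ws

    @classmethod
    def from_seconds(
        cls, window_s: float, overlap_frac: float = 0.5, fs_hz: int = FS_HZ
    ) -> "WindowConfig":
        """Build from a window length in seconds and an overlap fraction."""
        if window_s <= 0:
            raise ValueError("window_s must be positive")
        if not (0.0 <= overlap_frac < 1.0):
            raise ValueError("overlap_frac must be in [0, 1)")
        ws = max(1, int(round(window_s * fs_hz)))
        ss = max(1, ws - int(round(overlap_frac * ws)))
        return cls(ws=ws, ss=ss)


def sliding_window(
    seq_signal: np.ndarray, cfg: WindowConfig
) -> list[tuple[int, int, np.ndarray]]:
    """Cut a sequence into fixed-length windows.

    Returns ``(sp, ep, segment)`` triples with 1-based inclusive sample
    positions; ``segment`` is the (ws, channels) view of the signal.
    """
    sig = np.asarray(seq_signal)
    n_seq = sig.shape[0]
    if n_seq < cfg.ws:
        raise ValueError(
            f"sequence shorter than window (n_seq={n_seq}, ws={cfg.ws})"
        )
    out: list[tuple[int, int, np.ndarray]] = []
    sp = 1
    ep = cfg.ws
    while ep <= n_seq:
        out.append((sp, ep, sig[sp - 1 : ep]))
        sp += cfg.ss
        ep = sp + cfg.ws - 1
    residue = n_seq - out[-1][1]
    if residue:
        logger.debug("dropping trailing residue of %d samples (< ss)", residue)
    return out


def window_majority_label(
    gt_labels: np.ndarray, sp: int, ep: int
) -> str:
    """Ground-truth label of a training window = majority sample label.

    Ties (e.g. an exact 50/50 straddle) resolve to the earlier sub-task in
    temporal order A < B < C.
    """
    seg = np.asarray(gt_labels)[sp - 1 : ep]
    counts = [(np.sum(seg == c), -i) for i, c in enumerate(SUBTASKS)]
    best = max(range(len(SUBTASKS)), key=lambda i: counts[i])
    return SUBTASKS[best]


@dataclass
class LabelStream:
    """Window labels before/after repair plus the expanded sample labels."""

    d_ml: list[str]
    d_r: list[str]
    d_g: np.ndarray
    cfg: WindowConfig

    @property
    def n_s(self) -> int:
        return len(self.d_ml)

    @property
    def n_g(self) -> int:
        return len(self.d_g)


@dataclass
class SubtaskModelSet:
    """Fitted 3-class window classifiers, one per task or one global."""

    scope: str
    models: dict[str, LabelClassifier]

    def for_task(self, task_label: str) -> LabelClassifier:
        key = task_label if self.scope == "per_task" else _GLOBAL_KEY
        if key not in self.models:
            raise KeyError(f"no sub-task model for task {task_label!r}")
        return self.models[key]


def train_subtask_models(
    window_features: np.ndarray,
    window_labels: Sequence[str],
    window_tasks: Sequence[str],
    spec: TaskClassifierSpec,
    scope: str = "per_task",
    pca_thres: float = 0.99,
) -> SubtaskModelSet:
    """Fit the window-level A/B/C classifier(s) with their own PCA.

    ``window_features`` is the (n, 144) raw feature matrix of all training
    windows, ``window_labels`` their majority ground-truth sub-task labels
    and ``window_tasks`` the shoulder task each window came from. With
    ``scope='per_task'`` one classifier is fitted per shoulder task
    (hierarchical routing); with ``'global'`` a single classifier serves all
    tasks. Each classifier standardizes and reduces its own training
    windows, so no statistics cross model boundaries.
    """
    if scope not in _SCOPES:
        raise ValueError(f"scope must be one of {_SCOPES}, got {scope!r}")
    F = np.asarray(window_features, dtype=float)
    labels = np.asarray(window_labels, dtype="U1")
    tasks = np.asarray(window_tasks, dtype="U8")
    if not (F.shape[0] == labels.shape[0] == tasks.shape[0]):
        raise ValueError("features, labels and tasks must align row-wise")

    groups = (
        [(t, tasks == t) for t in TASKS if np.any(tasks == t)]
        if scope == "per_task"
        else [(_GLOBAL_KEY, np.ones(len(labels), dtype=bool))]
    )
    models: dict[str, LabelClassifier] = {}
    for key, mask in groups:
        got = set(labels[mask])
        missing = [c for c in SUBTASKS if c not in got]
        if missing:
            raise ValueError(
                f"training windows for {key!r} lack sub-task class(es) {missing}"
            )
        pca = fit_pca(F[mask], thres=pca_thres)
        X = apply_pca(pca, F[mask])
        models[key] = LabelClassifier(spec, SUBTASKS, pca=pca).fit(X, labels[mask])
    return SubtaskModelSet(scope=scope, models=models)


def classify_windows(
    model: LabelClassifier, window_features: np.ndarray
) -> list[str]:
    """Raw window labels ``d_ml``: one A/B/C label per window, in order."""
    F = np.asarray(window_features, dtype=float)
    if model.pca is not None and F.shape[-1] == model.pca.k:
        F = apply_pca(model.pca, F)
    return [str(c) for c in model.predict(F)]


def rule_modify(d_ml: Sequence) -> list:
    """Repair isolated window labels whose two neighbors agree.

    Single left-to-right pass: for each interior position t, if label t
    differs from both its neighbors and the neighbors equal each other, the
    neighbor label replaces it. The left neighbor is read from the evolving
    output and the right neighbor from the input; this makes exactly one
    pass exhaustive (no isolated interior label can survive, and a repaired
    position can never become isolated again), so the operation is
    idempotent, while a position is still only ever changed when its two
    *original* neighbors agree. First and last positions are never
    modified; identity on sequences of length <= 2.
    """
    src = list(d_ml)
    out = list(src)
    for t in range(1, len(src) - 1):
        if out[t - 1] != src[t] != src[t + 1] and out[t - 1] == src[t + 1]:
            out[t] = out[t - 1]
    return out


def generate_sample_labels(d_r: Sequence, cfg: WindowConfig) -> np.ndarray:
    """Expand window labels to the per-sample stream ``d_g``.

    Each of the first ``n_S - 1`` labels emits ``ss`` samples; the final
    label emits ``ws`` samples, for a total of ``ws + ss * (n_S - 1)``.
    """
    d_r = list(d_r)
    if not d_r:
        raise ValueError("d_r must contain at least one window label")
    parts = [np.full(cfg.ss, lab) for lab in d_r[:-1]]
    parts.append(np.full(cfg.ws, d_r[-1]))
    return np.concatenate(parts)


def segment_sequence(
    seq,
    task_label: str,
    models: SubtaskModelSet,
    cfg: WindowConfig,
    swma: SwmaConfig | None = None,
    peak_prominence_frac: float = 0.1,
) -> LabelStream:
    """Full sub-task segmentation of one sequence.

    ``seq`` is a :class:`~shoulderseg.synthetic.TaskSequence` (or any object
    with a ``signal`` attribute); ``task_label`` routes to the matching
    per-task model. Pass ``swma`` to pre-filter the raw signal first (omit
    it if the signal is already pre-processed).
    """
    signal = np.asarray(seq.signal if hasattr(seq, "signal") else seq, dtype=float)
    if swma is not None:
        signal = swma_filter(signal, swma)
    windows = sliding_window(signal, cfg)
    feats = np.array(
        [sequence_features(seg, peak_prominence_frac) for _, _, seg in windows]
    )
    model = models.for_task(task_label)
    d_ml = classify_windows(model, feats)
    d_r = rule_modify(d_ml)
    d_g = generate_sample_labels(d_r, cfg)
    return LabelStream(d_ml=d_ml, d_r=d_r, d_g=d_g, cfg=cfg)
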