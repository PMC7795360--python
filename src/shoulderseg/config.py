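"""Pipeline configuration with YAML round-trip.

Defaults are the study settings: SWMA window m=9, PCA variance threshold
0.99, 0.2 s windows with 50 % overlap at 128 Hz, SVM backend, per-task
sub-task models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .constants import FS_HZ
from .preprocessing import SwmaConfig
from .segmentation import WindowConfig
from .task_id import TaskClassifierSpec

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    swma_m: int = 9
    swma_scheme: str = "example"
    pca_thres: float = 0.99
    window_s: float = 0.2
    overlap_frac: float = 0.5
    fs_hz: int = FS_HZ
    model: str = "svm"
    svm_c: float = 1.0
    svm_gamma: float | str = "auto"
    knn_k: int = 7
    cart_min_leaf: int = 1
    subtask_scope: str = "per_task"
    peak_prominence_frac: float = 0.1
    average: str = "macro"
    seed: int = 0

    def swma_config(self) -> SwmaConfig:
        return SwmaConfig(m=self.swma_m, scheme=self.swma_scheme)

    def window_config(self) -> WindowConfig:
        return WindowConfig.from_seconds(self.window_s, self.overlap_frac, self.fs_hz)

    def classifier_spec(self) -> TaskClassifierSpec:
        return TaskClassifierSpec(
            model=self.model,
            svm_c=self.svm_c,
            svm_gamma=self.svm_gamma,
            knn_k=self.knn_k,
            cart_min_leaf=self.cart_min_leaf,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
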