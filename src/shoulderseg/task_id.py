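"""Shoulder-task identification: 5-class sequence-level classification.

Three discriminative backends are provided — a one-vs-all RBF-kernel SVM,
k-nearest-neighbors (default k=7, Euclidean), and a Gini-impurity CART —
behind a common wrapper that exposes per-class confidence scores and a
deterministic argmax decision. Confidence semantics per backend:

* SVM: one-vs-rest decision values passed through a softmax — a monotone
  surrogate for class probabilities, used only for the argmax;
* kNN: neighbor vote fractions; vote ties break by smaller mean neighbor
  distance, then by class order;
* CART: leaf class frequencies.

All remaining ties break toward the lower-indexed class (T1 < ... < T5,
A < B < C). The wrapper optionally carries the :class:`~shoulderseg.features.PcaTransform`
it was trained behind, so a saved model bundle is self-contained.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .constants import TASKS
from .features import PcaTransform, apply_pca

__all__ = [
    "TaskClassifierSpec",
    "TaskPrediction",
    "LabelClassifier",
    "train_task_model",
    "classify_task",
    "save_model",
    "load_model",
]

_MODELS = ("svm", "knn", "cart")


@dataclass(frozen=True)
class TaskClassifierSpec:
    """Backend choice and hyperparameters for a label classifier."""

    model: str = "svm"
    svm_c: float = 1.0
    svm_gamma: float | str = "auto"  # "auto" -> 1 / (l * mean feature variance)
    knn_k: int = 7
    cart_min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if isinstance(self.svm_gamma, str):
            if self.svm_gamma != "auto":
                raise ValueError("svm_gamma must be 'auto' or a positive number")
        elif self.svm_gamma <= 0:
            raise ValueError("svm_gamma must be 'auto' or a positive number")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.cart_min_leaf < 1:
            raise ValueError("cart_min_leaf must be >= 1")


@dataclass
class TaskPrediction:
    """Predicted label plus the per-class confidence scores behind it."""

    label: str
    scores: dict[str, float]


def _build_estimator(spec: TaskClassifierSpec):
    if spec.model == "svm":
        gamma = "scale" if spec.svm_gamma == "auto" else spec.svm_gamma
        return OneVsRestClassifier(
            SVC(kernel="rbf", C=spec.svm_c, gamma=gamma, random_state=spec.seed)
        )
    if spec.model == "knn":
        return KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean")
    return DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=spec.cart_min_leaf, random_state=spec.seed
    )


def _softmax(d: np.ndarray) -> np.ndarray:
    e = np.exp(d - d.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class LabelClassifier:
    """A fitted multi-class classifier with a fixed class order.

    ``class_order`` fixes both the score-vector layout and the tie-break
    direction of the argmax decision. Use :meth:`fit` once; ``predict``
    and ``predict_scores`` then accept (n, l) matrices or single vectors.
    """

    def __init__(
        self,
        spec: TaskClassifierSpec,
        class_order: Sequence[str],
        pca: PcaTransform | None = None,
    ) -> None:
        self.spec = spec
        self.class_order = tuple(class_order)
        self.pca = pca
        self._est = None
        self._train_X: np.ndarray | None = None
        self._train_y: np.ndarray | None = None

    @property
    def is_fitted(self) -> bool:
        return self._est is not None

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "LabelClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype="U8")
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, l) with one label per row")
        present = [c for c in self.class_order if c in set(y)]
        if len(present) < 2:
            raise ValueError(
                f"training set must contain >= 2 classes, got {present}"
            )
        unknown = set(y) - set(self.class_order)
        if unknown:
            raise ValueError(f"labels outside class order: {sorted(unknown)}")
        if X.shape[0] < len(present):
            raise ValueError("need at least one row per class")
        self._classes_present = tuple(present)
        spec = self.spec
        if spec.model == "knn" and spec.knn_k > X.shape[0]:
            # tiny training sets: a k beyond n_train is undefined, clamp
            spec = dataclasses.replace(spec, knn_k=X.shape[0])
        est = _build_estimator(spec)
        est.fit(X, y)
        self._est = est
        if self.spec.model == "knn":
            self._train_X, self._train_y = X, y
        return self

    def _check(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError("classifier is not fitted")
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        return arr

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) confidence matrix in ``class_order`` layout."""
        arr = self._check(X)
        est_classes = list(self._est.classes_)
        n_cls = len(self.class_order)
        scores = np.zeros((arr.shape[0], n_cls))

        if self.spec.model == "svm":
            d = self._est.decision_function(arr)
            if d.ndim == 1:  # binary one-vs-rest degenerates to one margin
                d = np.column_stack([-d, d])
            p = _softmax(d)
        elif self.spec.model == "cart":
            p = self._est.predict_proba(arr)
        else:  # knn: vote fractions
            dist, idx = self._est.kneighbors(arr)
            p = np.zeros((arr.shape[0], len(est_classes)))
            for r in range(arr.shape[0]):
                labs = self._train_y[idx[r]]
                for c_i, c in enumerate(est_classes):
                    p[r, c_i] = np.mean(labs == c)

        for c_i, c in enumerate(est_classes):
            scores[:, self.class_order.index(c)] = p[:, c_i]
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax labels; ties break by the documented backend rules."""
        arr = self._check(X)
        scores = self.predict_scores(arr)
        labels = np.empty(arr.shape[0], dtype="U8")
        if self.spec.model == "knn":
            dist, idx = self._est.kneighbors(arr)
        for r in range(arr.shape[0]):
            row = scores[r]
            best = np.flatnonzero(row == row.max())
            if len(best) > 1 and self.spec.model == "knn":
                # vote tie: smaller mean neighbor distance, then class order
                labs = self._train_y[idx[r]]
                mean_d = []
                for b in best:
                    c = self.class_order[b]
                    sel = labs == c
                    mean_d.append(dist[r][sel].mean() if sel.any() else np.inf)
                best = best[np.flatnonzero(mean_d == np.min(mean_d))]
            labels[r] = self.class_order[best[0]]
        return labels

    def predict_one(self, v: np.ndarray) -> TaskPrediction:
        v = np.asarray(v, dtype=float)
        scores = self.predict_scores(v[None, :])[0]
        label = self.predict(v[None, :])[0]
        return TaskPrediction(
            label=str(label),
            scores={c: float(s) for c, s in zip(self.class_order, scores)},
        )


def train_task_model(
    train_features: np.ndarray,
    train_labels: Sequence[str],
    spec: TaskClassifierSpec,
    pca: PcaTransform | None = None,
) -> LabelClassifier:
    """Fit the 5-class shoulder-task classifier on PCA-reduced features."""
    model = LabelClassifier(spec, TASKS, pca=pca)
    return model.fit(train_features, train_labels)


def classify_task(model: LabelClassifier, features: np.ndarray) -> TaskPrediction:
    """Classify one sequence-level feature vector (raw 144-d if the model
    carries a PCA, else already-reduced)."""
    v = np.asarray(features, dtype=float)
    if model.pca is not None and v.shape[-1] == model.pca.k:
        v = apply_pca(model.pca, v)
    return model.predict_one(v)


def save_model(model: LabelClassifier, path) -> None:
    """Serialize a fitted classifier (joblib bundle)."""
    joblib.dump(
        {
            "spec": model.spec,
            "class_order": model.class_order,
            "pca": None if model.pca is None else model.pca.to_dict(),
            "estimator": model._est,
            "train_X": model._train_X,
            "train_y": model._train_y,
        },
        path,
    )


def load_model(path) -> LabelClassifier:
    d = joblib.load(path)
    pca = None if d["pca"] is None else PcaTransform.from_dict(d["pca"])
    model = LabelClassifier(d["spec"], d["class_order"], pca=pca)
    model._est = d["estimator"]
    model._train_X = d["train_X"]
    model._train_y = d["train_y"]
    return model
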