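"""Statistical/kinematic feature extraction and PCA-based feature selection.

Each tri-axial sensor (one accelerometer or gyroscope) yields 36 features in
a fixed feature-type-major layout:

* per-axis statistics, x then y then z within each type: mean, standard
  deviation, variance, maximum, minimum, range, kurtosis, skewness
  (positions 1-24);
* the three pairwise axis correlation coefficients (x,y), (x,z), (y,z)
  (positions 25-27);
* per-axis kinematic counts: number of velocity peaks, zero crossings,
  mean crossings (positions 28-36).

A full two-IMU sequence or window gives 4 sensors x 36 = 144 features in
sensor order wrist-accel, wrist-gyro, arm-accel, arm-gyro.

Moments are population moments (divide by n); kurtosis is the raw fourth
standardized moment (not excess), matching the usual convention of the
field's toolboxes. Degenerate inputs are made deterministic: a constant
axis has skewness/kurtosis 0, correlations involving a zero-variance axis
are 0 (with a warning), and no peaks or crossings.

Feature selection is PCA on z-scored features: the retained dimensionality
``l`` is the smallest number of leading components whose eigenvalues sum to
at least ``thres`` (default 0.99) of the total variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from sklearn.decomposition import PCA

from .constants import CHANNELS, SENSOR_SLICES, SENSORS

__all__ = [
    "sensor_features",
    "sequence_features",
    "feature_names",
    "PcaTransform",
    "fit_pca",
    "apply_pca",
]

_AXES = ("x", "y", "z")
_MOMENT_STATS = ("mean", "std", "var", "max", "min", "range", "kurtosis", "skewness")
_CORR_PAIRS = ((0, 1), (0, 2), (1, 2))
_KINEMATIC = ("nvp", "nzr", "nmr")

N_FEATURES_PER_SENSOR = 36
N_FEATURES = len(SENSORS) * N_FEATURES_PER_SENSOR


def _strict_crossings(s: np.ndarray, level: float) -> int:
    """Strict sign changes of (s - level); exact zeros keep the previous sign."""
    d = s - level
    signs = np.sign(d)
    nz = signs[signs != 0]
    if nz.size < 2:
        return 0
    return int(np.sum(nz[:-1] * nz[1:] < 0))


def _n_peaks(s: np.ndarray, prominence_frac: float) -> int:
    rng = float(np.max(s) - np.min(s))
    if rng == 0.0:
        return 0
    peaks, _ = sp_signal.find_peaks(s, prominence=prominence_frac * rng)
    return int(peaks.size)


def sensor_features(
    triplet: np.ndarray, peak_prominence_frac: float = 0.1
) -> np.ndarray:
    """36-feature vector for one tri-axial sensor.

    ``triplet`` is an (n, 3) array (columns x, y, z), n >= 2. The peak
    counter requires a local maximum to have prominence at least
    ``peak_prominence_frac`` of the axis range, guarding against counting
    noise wiggles as movement peaks.
    """
    arr = np.asarray(triplet, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"sensor triplet must be (n, 3), got {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("sensor triplet needs at least 2 samples")

    out = np.empty(N_FEATURES_PER_SENSOR)
    pos = 0
    for stat in _MOMENT_STATS:
        for ax in range(3):
            s = arr[:, ax]
            if stat == "mean":
                v = np.mean(s)
            elif stat == "std":
                v = np.std(s)
            elif stat == "var":
                v = np.var(s)
            elif stat == "max":
                v = np.max(s)
            elif stat == "min":
                v = np.min(s)
            elif stat == "range":
                v = np.max(s) - np.min(s)
            elif stat == "kurtosis":
                v = 0.0 if np.std(s) == 0 else sp_stats.kurtosis(
                    s, fisher=False, bias=True
                )
            else:  # skewness
                v = 0.0 if np.std(s) == 0 else sp_stats.skew(s, bias=True)
            out[pos] = v
            pos += 1

    stds = np.std(arr, axis=0)
    for i, j in _CORR_PAIRS:
        if stds[i] == 0.0 or stds[j] == 0.0:
            warnings.warn(
                "zero-variance axis in correlation; coefficient set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            out[pos] = 0.0
        else:
            out[pos] = np.corrcoef(arr[:, i], arr[:, j])[0, 1]
        pos += 1

    for kin in _KINEMATIC:
        for ax in range(3):
            s = arr[:, ax]
            if kin == "nvp":
                v = _n_peaks(s, peak_prominence_frac)
            elif kin == "nzr":
                v = _strict_crossings(s, 0.0)
            else:  # nmr
                v = _strict_crossings(s, float(np.mean(s)))
            out[pos] = v
            pos += 1
    return out


def sequence_features(
    seq_signal: np.ndarray, peak_prominence_frac: float = 0.1
) -> np.ndarray:
    """144-feature descriptor of a 12-channel sequence or window."""
    sig = np.asarray(seq_signal, dtype=float)
    if sig.ndim != 2 or sig.shape[1] != len(CHANNELS):
        raise ValueError(
            f"signal must have {len(CHANNELS)} channels, got shape {sig.shape}"
        )
    parts = [
        sensor_features(sig[:, SENSOR_SLICES[name]], peak_prominence_frac)
        for name in SENSORS
    ]
    return np.concatenate(parts)


def feature_names() -> list[str]:
    """The 144 feature names, index-aligned with :func:`sequence_features`."""
    names: list[str] = []
    for sensor in SENSORS:
        for stat in _MOMENT_STATS:
            names.extend(f"{sensor}_{stat}_{ax}" for ax in _AXES)
        names.extend(
            f"{sensor}_corr_{_AXES[i]}{_AXES[j]}" for i, j in _CORR_PAIRS
        )
        for kin in _KINEMATIC:
            names.extend(f"{sensor}_{kin}_{ax}" for ax in _AXES)
    return names


@dataclass
class PcaTransform:
    """Fitted standardization + PCA basis with the retained count ``l``.

    ``components`` holds all k principal axes as rows (descending
    eigenvalue); projection uses only the first ``l``. ``scale`` entries
    that were 0 in the training data are stored as 1.
    """

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    l: int
    thres: float

    @property
    def k(self) -> int:
        return self.mean.shape[0]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "l": int(self.l),
            "thres": float(self.thres),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaTransform":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            l=int(d["l"]),
            thres=float(d["thres"]),
        )


def fit_pca(
    feature_matrix: np.ndarray, thres: float = 0.99, standardize: bool = True
) -> PcaTransform:
    """Fit standardization and PCA on training features; choose ``l``.

    ``l`` is the smallest number of leading components whose cumulative
    eigenvalue share reaches ``thres``. With ``thres=1.0`` this is the rank
    of the (standardized) covariance. Standardization (the default) z-scores
    each feature so that unit-heavy features (e.g. variance in g^2 vs peak
    counts) do not dominate the eigenbasis.
    """
    F = np.asarray(feature_matrix, dtype=float)
    if F.ndim != 2:
        raise ValueError("feature_matrix must be 2-D (n_train x k)")
    if F.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit PCA")
    if not (0.0 < thres <= 1.0):
        raise ValueError("thres must be in (0, 1]")

    mean = F.mean(axis=0)
    if standardize:
        scale = F.std(axis=0)
        scale[scale == 0.0] = 1.0
    else:
        scale = np.ones(F.shape[1])
    Z = (F - mean) / scale

    pca = PCA(svd_solver="full")
    pca.fit(Z)
    eig = pca.explained_variance_
    total = eig.sum()
    if total <= 0:
        l = 1
    else:
        ratio = np.cumsum(eig) / total
        l = int(np.argmax(ratio >= thres - 1e-12)) + 1

    # pad to k rows if n_train - 1 < k (sklearn returns min(n-1, k) components)
    comps = pca.components_
    eigs = eig
    if comps.shape[0] < F.shape[1]:
        pad = F.shape[1] - comps.shape[0]
        comps = np.vstack([comps, np.zeros((pad, F.shape[1]))])
        eigs = np.concatenate([eigs, np.zeros(pad)])

    return PcaTransform(
        mean=mean, scale=scale, components=comps, eigenvalues=eigs, l=l, thres=thres
    )


def apply_pca(t: PcaTransform, v: np.ndarray) -> np.ndarray:
    """Project feature vector(s) onto the first ``l`` principal axes."""
    arr = np.asarray(v, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != t.k:
        raise ValueError(f"expected feature dimension {t.k}, got {arr.shape}")
    z = (arr - t.mean) / t.scale
    proj = z @ t.components[: t.l].T
    return proj[0] if single else proj
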