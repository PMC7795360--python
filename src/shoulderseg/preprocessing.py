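"""Symmetry-weighted moving average (SWMA) noise suppression.

The SWMA is a symmetric FIR smoother over an odd window of ``m`` samples in
which points closer to the center get higher weight. Two weight schemes are
provided, selectable through :class:`SwmaConfig`:

* ``"example"`` (default): center weight ``(m + 1) / 2``, intermediate
  neighbors weight 1, the outermost pair weight 0.5 — for m=5 this is the
  pattern (0.5, 1, 3, 1, 0.5) normalized by 6.
* ``"linear"``: triangular weights ``delta_i = delta_0 - i`` decreasing by 1
  per lag — for m=5 the pattern (1, 2, 3, 2, 1) normalized by 9.

The two readings of the published weight rule disagree; the worked numeric
pattern above is the default anchor. At the sequence edges the window is
truncated to the available samples and renormalized by the sum of the
present weights, which keeps the output a convex combination of the input
everywhere (so constants are fixed points and output stays within the input
range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SwmaConfig", "swma_weights", "swma_filter"]

_SCHEMES = ("example", "linear")


@dataclass(frozen=True)
class SwmaConfig:
    """SWMA window length (odd), weight scheme, and edge policy."""

    m: int = 9
    scheme: str = "example"
    edge_policy: str = "truncate_renormalize"

    def __post_init__(self) -> None:
        if self.m < 1 or self.m % 2 == 0:
            raise ValueError(f"m must be an odd positive integer, got {self.m}")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}, got {self.scheme!r}")
        if self.edge_policy != "truncate_renormalize":
            raise ValueError("only edge_policy='truncate_renormalize' is supported")

    @property
    def delta0(self) -> float:
        """Center weight (m + 1) / 2."""
        return (self.m + 1) / 2


def swma_weights(m: int, scheme: str = "example") -> np.ndarray:
    """Full symmetric kernel of length ``m`` (unnormalized), center at m//2."""
    cfg = SwmaConfig(m=m, scheme=scheme)
    half = m // 2  # number of neighbor pairs
    w = np.empty(m)
    w[half] = cfg.delta0
    if scheme == "example":
        for i in range(1, half + 1):
            wi = 0.5 if i == half else 1.0
            w[half - i] = w[half + i] = wi
    else:  # linear: delta_i = delta_0 - i
        for i in range(1, half + 1):
            w[half - i] = w[half + i] = cfg.delta0 - i
    return w


def swma_filter(signal: np.ndarray, config: SwmaConfig | None = None) -> np.ndarray:
    """Apply the SWMA smoother along axis 0.

    Accepts a 1-D signal or an (n, channels) matrix (each channel filtered
    independently). Output has the same shape and length as the input; edge
    windows are truncated and renormalized.
    """
    config = config if config is not None else SwmaConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim not in (1, 2):
        raise ValueError("signal must be 1-D or 2-D (samples x channels)")
    if x.shape[0] < 1:
        raise ValueError("signal must contain at least one sample")

    w = swma_weights(config.m, config.scheme)
    if x.ndim == 2:
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            out[:, j] = swma_filter(x[:, j], config)
        return out

    # Truncate-and-renormalize edges: numerator and denominator convolved
    # with the same kernel so each output is sum(w_present * x) / sum(w_present).
    if x.shape[0] >= config.m:
        num = np.convolve(x, w, mode="same")
        den = np.convolve(np.ones_like(x), w, mode="same")
        return num / den
    # signal shorter than the kernel: mode="same" would change the length
    half = config.m // 2
    out = np.empty_like(x)
    for t in range(x.shape[0]):
        lo = max(0, t - half)
        hi = min(x.shape[0], t + half + 1)
        ww = w[half - (t - lo) : half + (hi - t)]
        out[t] = np.dot(ww, x[lo:hi]) / ww.sum()
    return out
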