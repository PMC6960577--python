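"""Realtime Outliers Removal: causal rolling-batch correction of network
outputs.

A streaming sample that leaves the envelope of the last N corrected samples
by more than k robust standard deviations (MAD of the batch around its
median, Gaussian-consistency scaled, floor-protected) is snapped back to
the batch median; all other samples pass through bit-identical. The first
N samples are the warm-up and are never altered. Each of the five output
channels is processed independently.

"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class RTORConfig:
    batch_length: int = 20  # N, samples of causal history
    threshold: float = 4.0  # k, robust-z units
    replacement: str = "batch-median"

    def __post_init__(self) -> None:
        if self.batch_length < 3:
            raise ValueError("batch_length must be >= 3")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.replacement != "batch-median":
            raise ValueError(f"unknown replacement rule {self.replacement!r}")


def _filter_channel(x: np.ndarray, N: int, k: float) -> np.ndarray:
    out = x.copy()
    run_lo = float(np.min(x[:N]))
    run_hi = float(np.max(x[:N]))
    for t in range(N, len(x)):
        batch = out[t - N : t]
        med = np.median(batch)
        mad = np.median(np.abs(batch - med))
        # a sample is an abrupt artifact when it leaves the batch envelope
        # by more than k robust units: a continuing trend exceeds the
        # envelope by ~one slope step, a network glitch by far more. The
        # scale is floored at 10% of the corrected stream's running range
        # so noise-free stretches do not flag negligible excursions.
        excess = max(x[t] - np.max(batch), np.min(batch) - x[t], 0.0)
        floor = max(1e-9, 0.1 * (run_hi - run_lo))
        scale = 1.4826 * max(mad, floor)
        if excess > k * scale:
            out[t] = med
        run_lo = min(run_lo, out[t])
        run_hi = max(run_hi, out[t])
    return out


def rtor_filter(
    stream: np.ndarray, cfg: RTORConfig | None = None
) -> np.ndarray:
    """Correct a (n,) or (n, channels) prediction stream causally.

    If the stream is shorter than the batch length it passes through
    unchanged (with a warning): there is never enough history to judge.
    """
    cfg = cfg or RTORConfig()
    x = np.asarray(stream, dtype=float)
    if x.size == 0:
        raise ValueError("empty stream")
    if len(x) <= cfg.batch_length:
        warnings.warn(
            "stream shorter than RTOR batch length; passing through unchanged",
            stacklevel=2,
        )
        return x.copy()
    if x.ndim == 1:
        return _filter_channel(x, cfg.batch_length, cfg.threshold)
    return np.column_stack(
        [
            _filter_channel(x[:, c], cfg.batch_length, cfg.threshold)
            for c in range(x.shape[1])
        ]
    )
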