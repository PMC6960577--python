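"""Signal conditioning and windowing.

Stage order for each modality trace: linear detrend → abrupt-change
correction (rolling robust z-score) → min-max normalization → (EEG only)
zero-phase beta band-pass → fixed-length windowing. Every stage preserves
the sample count except windowing.

Heart rate is special-cased: RR-interval (Poincaré) features need the
bpm scale, which min-max normalization destroys, so each window also
carries the outlier-corrected but unnormalized HR samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .session import EMOTIONS, FlightSession, TimeSeries


@dataclass
class PreprocConfig:
    window_length: float = 10.0  # seconds
    overlap: float = 0.0  # fraction of window_length, in [0, 1)
    detrend_method: str = "linear"  # or "constant", "none"
    abrupt_threshold: float = 5.0  # robust-z units
    abrupt_window: float = 1.0  # seconds of samples for the rolling window
    normalization: str = "minmax"  # or "none"
    eeg_band: tuple[float, float] = (12.0, 30.0)  # Hz

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if self.eeg_band[0] >= self.eeg_band[1]:
            raise ValueError("EEG band low edge must be below high edge")
        if self.abrupt_threshold <= 0:
            raise ValueError("abrupt_threshold must be positive")


@dataclass
class WindowedSample:
    """All modalities of one session cropped to one time window.

    ``target`` is the per-window mean of the 5-channel face trace; it lies
    in the convex hull of the face values, hence in [0, 1]^5.
    ``hr_bpm_window`` keeps the despiked bpm-scale HR for RR-interval
    features.
    """

    session_id: str
    window_idx: int
    t_start: float
    t_end: float
    hr_window: np.ndarray
    hr_bpm_window: np.ndarray
    gsr_window: np.ndarray
    eeg_windows: np.ndarray  # (n, 8)
    target: np.ndarray  # (5,)
    fs: dict[str, float] = field(default_factory=dict)


def detrend(series: TimeSeries, method: str = "linear") -> TimeSeries:
    """Remove a linear (default) or constant trend; length preserved."""
    if len(series) < 2:
        raise ValueError("detrend needs at least 2 samples")
    if method == "none":
        return series.copy_with(series.values.copy())
    if method not in ("linear", "constant"):
        raise ValueError(f"unknown detrend method {method!r}")
    values = sps.detrend(series.values, axis=0, type=method)
    return series.copy_with(values)


def _rolling_median(x: np.ndarray, win: int) -> np.ndarray:
    win = max(3, win | 1)  # odd, >= 3
    return ndimage.median_filter(x, size=win, mode="nearest")


def _rolling_mad(x: np.ndarray, med: np.ndarray, win: int) -> np.ndarray:
    # median absolute deviation from the rolling median, itself rolling
    win = max(3, win | 1)
    return ndimage.median_filter(np.abs(x - med), size=win, mode="nearest")


def correct_abrupt(series: TimeSeries, threshold: float = 5.0,
                   window_s: float = 1.0) -> TimeSeries:
    """Replace rolling-robust-z outliers by the rolling median.

    A sample whose deviation from the rolling median exceeds
    ``threshold × MAD`` (MAD floored to avoid the all-constant degenerate
    case) is replaced by that median; every other sample is bit-identical
    to the input.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not np.all(np.isfinite(series.values)):
        raise ValueError("non-finite values: upstream corruption")

    def _fix(x: np.ndarray) -> np.ndarray:
        win = int(round(window_s * series.fs))
        med = _rolling_median(x, win)
        mad = _rolling_mad(x, med, win)
        # scale floor: on smooth or noise-free stretches the local MAD
        # collapses to ~0 and natural curvature would be flagged; a deviation
        # below ~half the series' robust amplitude is not distinguishable
        # from signal, so floor the scale at 10% of the global MAD
        global_mad = np.median(np.abs(x - np.median(x)))
        floor = max(1e-12, 0.1 * global_mad)
        z = np.abs(x - med) / (1.4826 * np.maximum(mad, floor))
        out = x.copy()
        out[z > threshold] = med[z > threshold]
        return out

    if series.values.ndim == 1:
        values = _fix(series.values)
    else:
        values = np.column_stack(
            [_fix(series.values[:, c]) for c in range(series.values.shape[1])]
        )
    return series.copy_with(values)


def normalize(series: TimeSeries, method: str = "minmax") -> TimeSeries:
    """Min-max rescale to [0, 1]; a constant series maps to 0.5 everywhere."""
    if method == "none":
        return series.copy_with(series.values.copy())
    if method != "minmax":
        raise ValueError(f"unknown normalization {method!r}")

    def _mm(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi - lo < 1e-15:
            return np.full_like(x, 0.5)
        return (x - lo) / (hi - lo)

    if series.values.ndim == 1:
        values = _mm(series.values)
    else:
        values = np.column_stack(
            [_mm(series.values[:, c]) for c in range(series.values.shape[1])]
        )
    return series.copy_with(values)


def bandpass_beta(series: TimeSeries, low: float = 12.0,
                  high: float = 30.0) -> TimeSeries:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    if series.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {series.fs} Hz violates Nyquist for {high} Hz band edge"
        )
    sos = sps.butter(4, [low, high], btype="band", fs=series.fs, output="sos")
    values = sps.sosfiltfilt(sos, series.values, axis=0)
    return series.copy_with(values)


def preprocess_session(
    session: FlightSession, cfg: PreprocConfig | None = None,
    do_detrend: bool = True, do_outliers: bool = True,
) -> FlightSession:
    """Run the conditioning stages on every modality of a session.

    ``do_detrend`` / ``do_outliers`` toggle the corresponding stages (the
    test matrix switches them off for raw-data runs). Face intensities are
    already bounded targets and are left untouched.
    """
    cfg = cfg or PreprocConfig()

    def _chain(ts: TimeSeries, is_eeg: bool = False) -> TimeSeries:
        out = ts
        if do_detrend:
            out = detrend(out, cfg.detrend_method)
        if do_outliers:
            out = correct_abrupt(out, cfg.abrupt_threshold, cfg.abrupt_window)
        out = normalize(out, cfg.normalization)
        if is_eeg:
            out = bandpass_beta(out, *cfg.eeg_band)
        return out

    hr_bpm = (
        correct_abrupt(session.hr, cfg.abrupt_threshold, cfg.abrupt_window)
        if do_outliers
        else session.hr
    )
    processed = FlightSession(
        session_id=session.session_id,
        hr=_chain(session.hr),
        gsr=_chain(session.gsr),
        eeg=_chain(session.eeg, is_eeg=True),
        face=session.face,
        schedule=session.schedule,
        latent=session.latent,
    )
    processed.hr_bpm = hr_bpm  # despiked, bpm scale, for RR features
    return processed


def windowize(
    session: FlightSession, cfg: PreprocConfig | None = None
) -> list[WindowedSample]:
    """Cut a (preprocessed) session into synchronized fixed-length windows.

    Windows start at stride ``window_length * (1 - overlap)``; each sample
    carries every modality cropped to the identical interval at its native
    rate, and the target is the window mean of the face trace.
    """
    cfg = cfg or PreprocConfig()
    duration = session.duration
    L = cfg.window_length
    if L > duration + 1e-9:
        raise ValueError(
            f"window_length {L} s exceeds session duration {duration} s"
        )
    stride = L * (1.0 - cfg.overlap)
    n_windows = int(np.floor((duration - L) / stride + 1e-9)) + 1
    hr_bpm = getattr(session, "hr_bpm", session.hr)

    samples = []
    for w in range(n_windows):
        t0 = w * stride
        t1 = t0 + L
        face_w = session.face.slice(t0, t1).values
        target = np.clip(face_w.mean(axis=0), 0.0, 1.0)
        samples.append(
            WindowedSample(
                session_id=session.session_id,
                window_idx=w,
                t_start=t0,
                t_end=t1,
                hr_window=session.hr.slice(t0, t1).values,
                hr_bpm_window=hr_bpm.slice(t0, t1).values,
                gsr_window=session.gsr.slice(t0, t1).values,
                eeg_windows=session.eeg.slice(t0, t1).values,
                target=target,
                fs={
                    "hr": session.hr.fs,
                    "gsr": session.gsr.fs,
                    "eeg": session.eeg.fs,
                    "face": session.face.fs,
                },
            )
        )
    return samples


def window_targets(samples: list[WindowedSample]) -> np.ndarray:
    """(n, 5) matrix of window targets in the canonical emotion order."""
    return np.array([s.target for s in samples]).reshape(-1, len(EMOTIONS))
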