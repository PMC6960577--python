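"""Windowed feature extraction: 11 HR + 7 GSR + 72 EEG (9 × 8 ch) = 90.

Feature blocks
--------------
HR      MN MD STD VAR ENT RNG RMS SD1 SD2 SCT SAR   (statistics + Poincaré)
GSR     MN MD STD VAR ENT RNG PEK                   (statistics + peak rate)
EEG/ch  MN MD STD VAR ENT RNG RMS WAC WDC           (statistics + wavelets)

Statistics use population normalization (ddof=0). Differential entropy is a
Freedman–Diaconis histogram plug-in estimate in nats. Wavelet features are
the means of the level-4 ``sym7`` DWT approximation and detail coefficients.
Poincaré descriptors quantify the lag-1 RR-interval scatter: SD1 (short-term
dispersion, minor axis), SD2 (long-term, major axis), the norm of the cloud
centroid, and the fitted ellipse area π·SD1·SD2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .preprocess import WindowedSample
from .session import EEG_CHANNELS, EMOTIONS

ENTROPY_FLOOR = -30.0  # nats; sentinel for degenerate (constant) input

HR_FEATURES = (
    "MN", "MD", "STD", "VAR", "ENT", "RNG", "RMS", "SD1", "SD2", "SCT", "SAR",
)
GSR_FEATURES = ("MN", "MD", "STD", "VAR", "ENT", "RNG", "PEK")
EEG_FEATURES = ("MN", "MD", "STD", "VAR", "ENT", "RNG", "RMS", "WAC", "WDC")


@dataclass
class WaveletConfig:
    mother_wavelet: str = "sym7"
    level: int = 4

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.mother_wavelet not in pywt.wavelist():
            raise ValueError(f"unknown wavelet {self.mother_wavelet!r}")


@dataclass(frozen=True)
class PoincareDescriptors:
    sd1: float  # ms, short-term RR dispersion
    sd2: float  # ms, long-term RR dispersion
    centroid_norm: float  # ms, ‖(x̄, ȳ)‖ of the lag-1 cloud centroid
    ellipse_area: float  # ms², π·SD1·SD2


def basic_stats(values: np.ndarray) -> dict[str, float]:
    """Mean, median, population std/variance, RMS of a window."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    std = float(x.std(ddof=0))
    return {
        "MN": float(x.mean()),
        "MD": float(np.median(x)),
        "STD": std,
        "VAR": std**2,
        "RMS": float(np.sqrt(np.mean(x**2))),
    }


def differential_entropy(values: np.ndarray, bins: str = "fd") -> float:
    """Histogram plug-in estimate of differential entropy, in nats.

    ĥ = −Σ p̂_i ln p̂_i + ln Δ for bin width Δ and bin probabilities p̂_i.
    Constant input has no density and returns the ENTROPY_FLOOR sentinel.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("entropy estimator needs >= 10 samples")
    if np.ptp(x) < 1e-15:
        return ENTROPY_FLOOR
    counts, edges = np.histogram(x, bins=bins)
    widths = np.diff(edges)
    p = counts / counts.sum()
    nz = p > 0
    h = float(-np.sum(p[nz] * np.log(p[nz] / widths[nz])))
    return max(h, ENTROPY_FLOOR)


def sample_range(values: np.ndarray, mode: str = "extrema") -> float:
    """Window range: ``max − min`` (default) or ``|last − first|``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("range needs >= 2 samples")
    if mode == "extrema":
        return float(x.max() - x.min())
    if mode == "endpoints":
        return float(abs(x[-1] - x[0]))
    raise ValueError(f"unknown range mode {mode!r}")


def count_peaks(values: np.ndarray, fs: float, prominence: float = 0.05) -> float:
    """Rate of prominent local maxima, in peaks per second."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    x = np.asarray(values, dtype=float)
    peaks, _ = sps.find_peaks(x, prominence=prominence)
    return float(len(peaks) / (x.size / fs))


def wavelet_features(
    values: np.ndarray, cfg: WaveletConfig | None = None
) -> dict[str, float]:
    """Mean level-L approximation (WAC) and detail (WDC) DWT coefficients."""
    cfg = cfg or WaveletConfig()
    x = np.asarray(values, dtype=float)
    wavelet = pywt.Wavelet(cfg.mother_wavelet)
    min_len = (wavelet.dec_len - 1) * 2**cfg.level
    if x.size < min_len:
        raise ValueError(
            f"window of {x.size} samples too short for level {cfg.level} "
            f"decomposition (needs >= {min_len})"
        )
    coeffs = pywt.wavedec(x, wavelet, level=cfg.level)
    return {"WAC": float(coeffs[0].mean()), "WDC": float(coeffs[1].mean())}


def rr_from_hr(hr_bpm: np.ndarray) -> np.ndarray:
    """RR intervals in ms from instantaneous heart rate: RR = 60000 / HR."""
    hr = np.asarray(hr_bpm, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("heart rate must be positive bpm")
    return 60000.0 / hr


def poincare_descriptors(rr_ms: np.ndarray) -> PoincareDescriptors:
    """Lag-1 Poincaré descriptors of an RR series.

    With x = RR[:-1], y = RR[1:], centroid (x̄, ȳ): d1/d2 are each point's
    distances to the identity-line axes through the centroid; SD1/SD2 are
    their root mean squares (population normalization).
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 3:
        raise ValueError("Poincaré descriptors need >= 3 RR values")
    x, y = rr[:-1], rr[1:]
    xc, yc = x.mean(), y.mean()
    d1 = np.abs((x - xc) - (y - yc)) / np.sqrt(2.0)
    d2 = np.abs((x - xc) + (y - yc)) / np.sqrt(2.0)
    sd1 = float(np.sqrt(np.mean(d1**2)))
    sd2 = float(np.sqrt(np.mean(d2**2)))
    return PoincareDescriptors(
        sd1=sd1,
        sd2=sd2,
        centroid_norm=float(np.hypot(xc, yc)),
        ellipse_area=float(np.pi * sd1 * sd2),
    )


@dataclass
class FeatureConfig:
    wavelet: WaveletConfig | None = None
    range_mode: str = "extrema"
    gsr_drop: str = "RMS"  # Table-row pruned to honour the 7-feature GSR count
    peak_prominence: float = 0.05  # in normalized GSR units

    def __post_init__(self) -> None:
        self.wavelet = self.wavelet or WaveletConfig()


def extract_hr_features(
    sample: WindowedSample, cfg: FeatureConfig
) -> dict[str, float]:
    """11 HR features: 7 window statistics + 4 Poincaré descriptors."""
    x = sample.hr_window
    if x.size == 0:
        raise ValueError("missing modality: hr")
    out = basic_stats(x)
    out["ENT"] = differential_entropy(x) if x.size >= 10 else ENTROPY_FLOOR
    out["RNG"] = sample_range(x, cfg.range_mode)
    rr = rr_from_hr(sample.hr_bpm_window)
    pc = poincare_descriptors(rr)
    out.update(SD1=pc.sd1, SD2=pc.sd2, SCT=pc.centroid_norm, SAR=pc.ellipse_area)
    return {k: out[k] for k in HR_FEATURES}


def extract_gsr_features(
    sample: WindowedSample, cfg: FeatureConfig
) -> dict[str, float]:
    """7 GSR features: 6 window statistics + phasic peak rate."""
    x = sample.gsr_window
    if x.size == 0:
        raise ValueError("missing modality: gsr")
    out = basic_stats(x)
    out.pop(cfg.gsr_drop, None)
    out["ENT"] = differential_entropy(x) if x.size >= 10 else ENTROPY_FLOOR
    out["RNG"] = sample_range(x, cfg.range_mode)
    out["PEK"] = count_peaks(x, sample.fs.get("gsr", 1.0), cfg.peak_prominence)
    return {k: out[k] for k in GSR_FEATURES if k in out}


def extract_eeg_features(
    sample: WindowedSample, cfg: FeatureConfig
) -> dict[str, float]:
    """72 EEG features: 9 per channel (statistics + wavelet means) × 8."""
    eeg = sample.eeg_windows
    if eeg.size == 0:
        raise ValueError("missing modality: eeg")
    out: dict[str, float] = {}
    for c, label in enumerate(EEG_CHANNELS):
        x = eeg[:, c]
        stats = basic_stats(x)
        stats["ENT"] = differential_entropy(x) if x.size >= 10 else ENTROPY_FLOOR
        stats["RNG"] = sample_range(x, cfg.range_mode)
        stats.update(wavelet_features(x, cfg.wavelet))
        for name in EEG_FEATURES:
            out[f"{label}_{name}"] = stats[name]
    return out


def extract_all(
    sample: WindowedSample, cfg: FeatureConfig | None = None,
    modalities: tuple[str, ...] = ("hr", "gsr", "eeg"),
) -> dict[str, float]:
    """Full feature vector for one window; 90 features with all modalities."""
    cfg = cfg or FeatureConfig()
    out: dict[str, float] = {}
    if "hr" in modalities:
        out.update({f"hr_{k}": v for k, v in extract_hr_features(sample, cfg).items()})
    if "gsr" in modalities:
        out.update(
            {f"gsr_{k}": v for k, v in extract_gsr_features(sample, cfg).items()}
        )
    if "eeg" in modalities:
        out.update(
            {f"eeg_{k}": v for k, v in extract_eeg_features(sample, cfg).items()}
        )
    return out


class FeatureMatrix:
    """Windowed samples × named features, with modality block structure.

    ``X`` is a DataFrame (rows: windows, MultiIndex session_id/window_idx;
    columns: prefixed feature names), ``y`` the paired (n, 5) target frame.
    """

    def __init__(self, X: pd.DataFrame, y: pd.DataFrame, mode: str = "all"):
        if X.isna().any().any():
            raise ValueError("FeatureMatrix contains NaN cells")
        if len(X) != len(y):
            raise ValueError("X and y row counts differ")
        self.X = X
        self.y = y
        self.mode = mode

    def __len__(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def block_columns(self, block: str) -> list[str]:
        """Columns of one modality block: 'hr', 'gsr', or 'eeg:<channel>'."""
        if block.startswith("eeg:"):
            ch = block.split(":", 1)[1]
            return [c for c in self.X.columns if c.startswith(f"eeg_{ch}_")]
        return [c for c in self.X.columns if c.startswith(f"{block}_")]

    @property
    def blocks(self) -> list[str]:
        out = []
        if any(c.startswith("hr_") for c in self.X.columns):
            out.append("hr")
        if any(c.startswith("gsr_") for c in self.X.columns):
            out.append("gsr")
        out += [
            f"eeg:{ch}"
            for ch in EEG_CHANNELS
            if any(c.startswith(f"eeg_{ch}_") for c in self.X.columns)
        ]
        return out

    def session_ids(self) -> np.ndarray:
        return self.X.index.get_level_values("session_id").to_numpy()

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[mask], self.y[mask], self.mode)

    def to_csv(self, path) -> None:
        pd.concat([self.X, self.y.add_prefix("target_")], axis=1).to_csv(path)


def build_feature_matrix(
    samples: list[WindowedSample], cfg: FeatureConfig | None = None,
    modalities: tuple[str, ...] = ("hr", "gsr", "eeg"),
) -> FeatureMatrix:
    """Extract features for every window and assemble the design matrix."""
    cfg = cfg or FeatureConfig()
    rows, targets, index = [], [], []
    for s in samples:
        rows.append(extract_all(s, cfg, modalities))
        targets.append(s.target)
        index.append((s.session_id, s.window_idx))
    idx = pd.MultiIndex.from_tuples(index, names=["session_id", "window_idx"])
    X = pd.DataFrame(rows, index=idx)
    y = pd.DataFrame(targets, index=idx, columns=list(EMOTIONS))
    return FeatureMatrix(X, y, mode="all")
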