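"""Synthetic flight-cohort generator.

Emulates, statistically, the multimodal recordings of a cohort of simulated
flights: a hidden 5-channel emotion-intensity process driven by the seven
flight tasks, and four observed modalities coupled to it —

* **HR** (1 Hz, bpm): baseline plus slow drift plus beat-to-beat jitter whose
  standard deviation grows with latent arousal (scared + surprised), so that
  short-term RR dispersion (Poincaré SD1) carries the arousal signal;
* **GSR** (16 Hz, µS): slow tonic drift plus phasic exponential-decay peaks
  whose Poisson rate grows with arousal;
* **EEG** (500 Hz, µV, 8 channels): broadband noise plus a 12–30 Hz beta-band
  component whose amplitude is an affine function of the latent intensities,
  with a fixed per-channel mixing matrix so the 8 channels jointly identify
  all five emotions;
* **face** (30 Hz, intensities in [0, 1]): the latent trace observed through
  truncated Gaussian noise — the regression target, standing in for a facial
  expression analyzer's output.

This is a statistical emulation, not a biophysical simulation: there is no
ECG waveform, no cortical dipole model, no skin-conductance deconvolution
ground truth. Its purpose is to give the downstream pipeline a cohort with
known latent structure for parameter-recovery testing.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .session import (
    EMOTIONS,
    TASK_NAMES,
    FlightSession,
    TaskSegment,
    TimeSeries,
    validate_schedule,
)

#: The 13 flight labels used for default cohorts.
DEFAULT_SESSION_IDS = (
    "RC1", "RC2", "RC3", "GC1", "GC3", "LS1", "LS2",
    "VC1", "VC2", "CR1", "CR3", "CLX", "CL3",
)

#: Fraction of the session each task occupies. Chosen so that, with the
#: default emotion means below, each of the five emotions is the dominant one
#: in roughly a fifth of flight time — the argmax-match chance level of a
#: five-emotion problem is then 0.2.
DEFAULT_TASK_FRACTIONS: dict[str, float] = {
    "takeoff": 0.10,
    "climbing": 0.20,
    "cruise": 0.20,
    "descent": 0.10,
    "approach": 0.10,
    "final_approach": 0.20,
    "landing": 0.10,
}

#: Mean emotion-intensity vector per task (happy, sad, angry, surprised,
#: scared). Dominants: takeoff/landing → surprised, climbing → happy,
#: cruise → sad (monotony), descent/approach → angry (workload frustration),
#: final approach → scared.
DEFAULT_TASK_EMOTION_MEANS: dict[str, tuple[float, ...]] = {
    "takeoff": (0.15, 0.05, 0.05, 0.75, 0.25),
    "climbing": (0.75, 0.05, 0.10, 0.15, 0.10),
    "cruise": (0.20, 0.70, 0.10, 0.05, 0.05),
    "descent": (0.10, 0.20, 0.70, 0.10, 0.15),
    "approach": (0.10, 0.15, 0.70, 0.15, 0.25),
    "final_approach": (0.05, 0.10, 0.20, 0.15, 0.80),
    "landing": (0.25, 0.05, 0.10, 0.70, 0.20),
}

#: Per-channel beta-band coupling weights (8 channels × 5 emotions). The
#: first five channels each track one emotion; the last three are mixtures,
#: loosely mimicking spatially distributed cortical involvement.
BETA_MIXING = np.array(
    [
        [1.0, 0.0, 0.0, 0.0, 0.0],  # Fp1
        [0.0, 1.0, 0.0, 0.0, 0.0],  # F3
        [0.0, 0.0, 1.0, 0.0, 0.0],  # C3
        [0.0, 0.0, 0.0, 1.0, 0.0],  # T7
        [0.0, 0.0, 0.0, 0.0, 1.0],  # Fp2
        [0.5, 0.5, 0.0, 0.0, 0.0],  # F4
        [0.0, 0.0, 0.5, 0.5, 0.0],  # C4
        [0.2, 0.2, 0.2, 0.2, 0.2],  # T8
    ]
)

_FS_LATENT = 10.0  # Hz; internal grid for the latent process (tau >> 0.1 s)


@dataclass
class SynthConfig:
    """Cohort-generation parameters.

    Coupling gains set how strongly each modality reflects the latent
    emotions; with all gains zero the modalities are pure noise,
    statistically independent of the latent trace.
    """

    n_flights: int = 13
    session_duration: float = 300.0  # seconds
    fs_hr: float = 1.0
    fs_gsr: float = 16.0
    fs_eeg: float = 500.0
    fs_face: float = 30.0
    task_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TASK_FRACTIONS)
    )
    task_emotion_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TASK_EMOTION_MEANS)
    )
    # latent Ornstein-Uhlenbeck fluctuation around the task means
    latent_sigma: float = 0.06  # stationary sd, intensity units
    latent_tau: float = 20.0  # seconds
    # HR
    hr_baseline: float = 75.0  # bpm
    hr_drift_amp: float = 3.0  # bpm, slow sinusoidal drift
    hr_noise_sd: float = 0.5  # bpm, arousal-independent jitter floor
    hr_variability_gain: float = 6.0  # bpm jitter sd per unit arousal
    # GSR
    gsr_tonic: float = 2.0  # µS
    gsr_drift_amp: float = 0.3  # µS
    gsr_noise_sd: float = 0.02  # µS observation noise
    gsr_peak_rate_base: float = 0.05  # peaks/s at zero arousal
    gsr_peak_rate_gain: float = 0.4  # peaks/s per unit arousal
    gsr_peak_amp: float = 0.3  # µS
    gsr_decay_tau: float = 2.0  # s, phasic decay constant
    # EEG
    eeg_noise_sd: float = 8.0  # µV broadband
    eeg_beta_base: float = 2.0  # µV RMS of beta component at zero intensity
    eeg_beta_power_gain: float = 6.0  # µV RMS per unit mixed intensity
    # face
    face_noise_sd: float = 0.03  # intensity units
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flights < 2:
            raise ValueError("n_flights must be >= 2 (LOOCV needs >= 2 folds)")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        for name in ("fs_hr", "fs_gsr", "fs_eeg", "fs_face"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "hr_variability_gain",
            "gsr_peak_rate_gain",
            "eeg_beta_power_gain",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def decoupled(self) -> "SynthConfig":
        """A copy with all modality-to-emotion coupling gains set to zero."""
        return replace(
            self,
            hr_variability_gain=0.0,
            gsr_peak_rate_gain=0.0,
            eeg_beta_power_gain=0.0,
        )


def make_schedule(
    duration: float, fractions: dict[str, float] | None = None
) -> list[TaskSegment]:
    """Build the seven-task schedule covering ``[0, duration]``."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    fractions = fractions or DEFAULT_TASK_FRACTIONS
    total = sum(fractions[t] for t in TASK_NAMES)
    t = 0.0
    segments = []
    for name in TASK_NAMES:
        dt = duration * fractions[name] / total
        segments.append(TaskSegment(name, t, t + dt))
        t += dt
    # absorb float round-off so the last segment ends exactly at `duration`
    last = segments[-1]
    segments[-1] = TaskSegment(last.task_name, last.t_start, duration)
    return segments


def session_seed(master_seed: int, session_id: str) -> int:
    """Stable per-session seed: CRC32 hash of the id mixed with the master."""
    h = zlib.crc32(session_id.encode("utf-8"))
    return (master_seed * 0x9E3779B1 + h) & 0x7FFFFFFF


def _task_mean_trace(
    schedule: list[TaskSegment], means: dict[str, tuple[float, ...]], t: np.ndarray
) -> np.ndarray:
    """Step-function (n, 5) trace of per-task mean intensities."""
    out = np.zeros((len(t), len(EMOTIONS)))
    for seg in schedule:
        mask = (t >= seg.t_start) & (t < seg.t_end)
        out[mask] = np.asarray(means[seg.task_name])
    # samples exactly at/after the final boundary belong to the last task
    out[t >= schedule[-1].t_end] = np.asarray(means[schedule[-1].task_name])
    return out


def latent_emotion_process(
    schedule: list[TaskSegment], cfg: SynthConfig, seed: int
) -> TimeSeries:
    """Hidden emotion-intensity trace: task means + OU fluctuations, in [0,1].

    Each of the five intensities follows an Ornstein-Uhlenbeck process
    reverting to the current task's mean, with stationary standard deviation
    ``cfg.latent_sigma`` and correlation time ``cfg.latent_tau``; the result
    is clipped to [0, 1].
    """
    validate_schedule(schedule)
    rng = np.random.default_rng(seed)
    duration = schedule[-1].t_end - schedule[0].t_start
    n = max(int(round(duration * _FS_LATENT)), 2)
    t = schedule[0].t_start + np.arange(n) / _FS_LATENT
    mean = _task_mean_trace(schedule, cfg.task_emotion_means, t)

    dt = 1.0 / _FS_LATENT
    rho = np.exp(-dt / cfg.latent_tau)
    innov_sd = cfg.latent_sigma * np.sqrt(1.0 - rho**2)
    dev = np.zeros((n, len(EMOTIONS)))
    if cfg.latent_sigma > 0:
        eps = rng.normal(0.0, innov_sd, size=(n, len(EMOTIONS)))
        dev[0] = rng.normal(0.0, cfg.latent_sigma, size=len(EMOTIONS))
        for i in range(1, n):
            dev[i] = rho * dev[i - 1] + eps[i]
    values = np.clip(mean + dev, 0.0, 1.0)
    return TimeSeries(t, values, _FS_LATENT, "latent")


def _interp_latent(latent: TimeSeries, t: np.ndarray) -> np.ndarray:
    """Latent intensities resampled onto timestamps ``t`` → (len(t), 5)."""
    return np.column_stack(
        [np.interp(t, latent.timestamps, latent.values[:, k]) for k in range(5)]
    )


def _arousal(intensities: np.ndarray) -> np.ndarray:
    """Arousal index in [0, 1]: mean of scared and surprised intensities."""
    i_sur = EMOTIONS.index("surprised")
    i_sca = EMOTIONS.index("scared")
    return 0.5 * (intensities[:, i_sur] + intensities[:, i_sca])


def _gen_hr(cfg: SynthConfig, latent: TimeSeries, rng: np.random.Generator,
            duration: float) -> TimeSeries:
    n = int(round(duration * cfg.fs_hr))
    t = np.arange(n) / cfg.fs_hr
    arous = _arousal(_interp_latent(latent, t))
    phase = rng.uniform(0, 2 * np.pi)
    drift = cfg.hr_drift_amp * np.sin(2 * np.pi * t / 120.0 + phase)
    jitter_sd = cfg.hr_noise_sd + cfg.hr_variability_gain * arous
    jitter = rng.normal(0.0, 1.0, n) * jitter_sd
    values = cfg.hr_baseline + drift + jitter
    return TimeSeries(t, np.maximum(values, 30.0), cfg.fs_hr, "hr")


def _gen_gsr(cfg: SynthConfig, latent: TimeSeries, rng: np.random.Generator,
             duration: float) -> TimeSeries:
    n = int(round(duration * cfg.fs_gsr))
    t = np.arange(n) / cfg.fs_gsr
    arous = _arousal(_interp_latent(latent, t))
    phase = rng.uniform(0, 2 * np.pi)
    tonic = cfg.gsr_tonic + cfg.gsr_drift_amp * np.sin(
        2 * np.pi * t / duration + phase
    )
    rate = cfg.gsr_peak_rate_base + cfg.gsr_peak_rate_gain * arous  # peaks/s
    events = rng.random(n) < rate / cfg.fs_gsr  # thinned Poisson
    amps = np.where(events, cfg.gsr_peak_amp * rng.uniform(0.7, 1.3, n), 0.0)
    k_t = np.arange(int(8 * cfg.gsr_decay_tau * cfg.fs_gsr)) / cfg.fs_gsr
    kernel = np.exp(-k_t / cfg.gsr_decay_tau)
    phasic = signal.fftconvolve(amps, kernel)[:n]
    noise = rng.normal(0.0, cfg.gsr_noise_sd, n)
    return TimeSeries(t, tonic + phasic + noise, cfg.fs_gsr, "gsr")


def _gen_eeg(cfg: SynthConfig, latent: TimeSeries, rng: np.random.Generator,
             duration: float) -> TimeSeries:
    n = int(round(duration * cfg.fs_eeg))
    t = np.arange(n) / cfg.fs_eeg
    intens = _interp_latent(latent, t)  # (n, 5)
    sos = signal.butter(4, [12.0, 30.0], btype="band", fs=cfg.fs_eeg, output="sos")
    channels = np.empty((n, BETA_MIXING.shape[0]))
    for c in range(BETA_MIXING.shape[0]):
        broadband = rng.normal(0.0, cfg.eeg_noise_sd, n)
        carrier = signal.sosfilt(sos, rng.normal(0.0, 1.0, n))
        carrier /= max(carrier.std(), 1e-12)  # unit-RMS beta-band carrier
        amp = cfg.eeg_beta_base + cfg.eeg_beta_power_gain * (
            intens @ BETA_MIXING[c]
        )
        channels[:, c] = broadband + np.maximum(amp, 0.0) * carrier
    return TimeSeries(t, channels, cfg.fs_eeg, "eeg")


def _gen_face(cfg: SynthConfig, latent: TimeSeries, rng: np.random.Generator,
              duration: float) -> TimeSeries:
    n = int(round(duration * cfg.fs_face))
    t = np.arange(n) / cfg.fs_face
    intens = _interp_latent(latent, t)
    noisy = intens + rng.normal(0.0, cfg.face_noise_sd, intens.shape)
    return TimeSeries(t, np.clip(noisy, 0.0, 1.0), cfg.fs_face, "face")


def generate_session(
    cfg: SynthConfig, session_id: str, seed: int
) -> FlightSession:
    """Generate one flight session; fully deterministic given ``seed``."""
    duration = cfg.session_duration
    schedule = make_schedule(duration, cfg.task_fractions)
    ss = np.random.SeedSequence(seed)
    s_latent, s_hr, s_gsr, s_eeg, s_face = ss.spawn(5)
    latent = latent_emotion_process(
        schedule, cfg, int(s_latent.generate_state(1)[0] & 0x7FFFFFFF)
    )
    return FlightSession(
        session_id=session_id,
        hr=_gen_hr(cfg, latent, np.random.default_rng(s_hr), duration),
        gsr=_gen_gsr(cfg, latent, np.random.default_rng(s_gsr), duration),
        eeg=_gen_eeg(cfg, latent, np.random.default_rng(s_eeg), duration),
        face=_gen_face(cfg, latent, np.random.default_rng(s_face), duration),
        schedule=schedule,
        latent=latent,
    )


def cohort_session_ids(n_flights: int) -> list[str]:
    ids = list(DEFAULT_SESSION_IDS[:n_flights])
    ids += [f"XF{i}" for i in range(len(ids) + 1, n_flights + 1)]
    return ids


def generate_cohort(
    cfg: SynthConfig, session_ids: list[str] | None = None
) -> list[FlightSession]:
    """Generate ``cfg.n_flights`` sessions with per-session derived seeds."""
    ids = list(session_ids) if session_ids is not None else cohort_session_ids(
        cfg.n_flights
    )
    if len(ids) != cfg.n_flights:
        raise ValueError(
            f"got {len(ids)} session ids for n_flights={cfg.n_flights}"
        )
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate session ids")
    return [
        generate_session(cfg, sid, session_seed(cfg.rng_seed, sid))
        for sid in ids
    ]
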