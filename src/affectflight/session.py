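"""Domain containers for one simulated flight's multimodal recordings.

A flight session bundles synchronized heart-rate (bpm), skin-conductance
(µS), 8-channel EEG (µV) and 5-channel facial emotion-intensity traces,
plus the seven-task flight schedule. Synthetic sessions additionally carry
the latent emotion trace they were generated from, which downstream
evaluation uses as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical flight-task order. Every schedule contains exactly these seven
#: tasks, contiguous and in this order.
TASK_NAMES = (
    "takeoff",
    "climbing",
    "cruise",
    "descent",
    "approach",
    "final_approach",
    "landing",
)

#: Fixed emotion ordering used for every 5-vector in the package.
EMOTIONS = ("happy", "sad", "angry", "surprised", "scared")

#: 10-20 system electrode labels for the 8 EEG channels, in channel order.
EEG_CHANNELS = ("Fp1", "F3", "C3", "T7", "Fp2", "F4", "C4", "T8")


@dataclass(frozen=True)
class TaskSegment:
    """One flight task occupying ``[t_start, t_end)`` seconds."""

    task_name: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.task_name not in TASK_NAMES:
            raise ValueError(f"unknown task name {self.task_name!r}")
        if not self.t_end > self.t_start:
            raise ValueError(
                f"task {self.task_name!r}: t_end ({self.t_end}) must exceed "
                f"t_start ({self.t_start})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def validate_schedule(schedule: list[TaskSegment]) -> None:
    """Check a schedule is the seven canonical tasks, contiguous and in order."""
    if not schedule:
        raise ValueError("schedule is empty: no tasks to simulate")
    names = tuple(seg.task_name for seg in schedule)
    if names != TASK_NAMES:
        raise ValueError(
            f"schedule must contain exactly the tasks {TASK_NAMES} in order, "
            f"got {names}"
        )
    for prev, nxt in zip(schedule, schedule[1:]):
        if not np.isclose(prev.t_end, nxt.t_start):
            raise ValueError(
                f"schedule gap/overlap between {prev.task_name!r} and "
                f"{nxt.task_name!r}"
            )


@dataclass
class TimeSeries:
    """A uniformly sampled 1-D (or channels-in-columns 2-D) signal."""

    timestamps: np.ndarray  # seconds, uniform at 1/fs, strictly increasing
    values: np.ndarray  # shape (n,) or (n, n_channels)
    fs: float  # Hz
    modality: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.modality or 'series'}")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def slice(self, t_start: float, t_end: float) -> "TimeSeries":
        """Return the samples with ``t_start <= t < t_end``."""
        mask = (self.timestamps >= t_start - 1e-9) & (self.timestamps < t_end - 1e-9)
        return TimeSeries(
            self.timestamps[mask], self.values[mask], self.fs, self.modality
        )

    def copy_with(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(self.timestamps.copy(), values, self.fs, self.modality)


@dataclass
class FlightSession:
    """One flight's synchronized multimodal recordings.

    ``eeg.values`` is (n, 8) with columns ordered as :data:`EEG_CHANNELS`;
    ``face.values`` is (n, 5) ordered as :data:`EMOTIONS`. ``latent`` is the
    hidden emotion trace (same layout as ``face``) available for synthetic
    sessions only.
    """

    session_id: str
    hr: TimeSeries
    gsr: TimeSeries
    eeg: TimeSeries
    face: TimeSeries
    schedule: list[TaskSegment] = field(default_factory=list)
    latent: TimeSeries | None = None

    def __post_init__(self) -> None:
        if self.eeg.values.ndim != 2 or self.eeg.values.shape[1] != len(EEG_CHANNELS):
            raise ValueError(
                f"eeg must have {len(EEG_CHANNELS)} channels, got shape "
                f"{self.eeg.values.shape}"
            )
        if self.face.values.ndim != 2 or self.face.values.shape[1] != len(EMOTIONS):
            raise ValueError("face must have 5 emotion channels")
        if self.face.values.min() < -1e-12 or self.face.values.max() > 1 + 1e-12:
            raise ValueError("face intensities must lie in [0, 1]")
        if self.schedule:
            validate_schedule(self.schedule)

    @property
    def duration(self) -> float:
        return self.hr.duration

    def task_at(self, t: float) -> str:
        for seg in self.schedule:
            if seg.t_start <= t < seg.t_end:
                return seg.task_name
        return self.schedule[-1].task_name if self.schedule else ""
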