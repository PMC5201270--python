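"""Shared in-memory containers for the pipeline.

Conventions used throughout the package:

* amplitudes are in microvolts (uV), time axes in seconds, intervals in
  milliseconds, RR in seconds;
* sample indices are 0-based;
* fiducial times inside a beat are milliseconds from the start of the beat
  window;
* the "vector magnitude" lead is the per-sample L2 norm across leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EcgRecording",
    "MedianBeat",
    "Fiducials",
    "BeatTruth",
    "vector_magnitude",
]


def vector_magnitude(samples: np.ndarray) -> np.ndarray:
    """Per-sample L2 norm across leads; `samples` has shape (n_leads, n)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    return np.sqrt(np.sum(samples**2, axis=0))


@dataclass
class BeatTruth:
    """Generator ground truth for one beat, in samples of the recording."""

    beat_index: int
    qrs_onset: int
    qrs_offset: int
    t_peak: int
    t_end: int
    r_peak: int
    rr_s: float


@dataclass
class EcgRecording:
    """A multi-lead ECG snippet (typically 10 s) plus acquisition metadata.

    ``samples`` has shape (n_leads, n_samples) in uV. ``truth`` optionally
    carries per-beat ground-truth fiducials for synthetic recordings.
    """

    samples: np.ndarray
    fs_hz: float
    lead_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)
    truth: list[BeatTruth] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.lead_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.samples.shape[0]} sample rows"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def vm(self) -> np.ndarray:
        return vector_magnitude(self.samples)


@dataclass
class MedianBeat:
    """Representative beat: per-sample median of R-aligned beats, per lead."""

    samples: np.ndarray  # (n_leads, n) uV
    fs_hz: float
    n_contributing_beats: int
    mean_rr_s: float
    r_index: int  # sample index of the R alignment point within the window

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))

    def vm(self) -> np.ndarray:
        return vector_magnitude(self.samples)


@dataclass
class Fiducials:
    """Delineated fiducials of one (median) beat, ms from beat-window start.

    Invariant: qrs_onset < qrs_offset (J point) < t_peak < t_end, so that
    QT = (J - onset) + J-Tpeak + Tpeak-Tend decomposes additively.
    """

    qrs_onset_ms: float
    qrs_offset_ms: float
    t_peak_ms: float
    t_end_ms: float
    rr_s: float

    def __post_init__(self) -> None:
        seq = (self.qrs_onset_ms, self.qrs_offset_ms, self.t_peak_ms, self.t_end_ms)
        if not all(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"fiducials out of order: {seq}")
        if self.rr_s <= 0:
            raise ValueError("rr_s must be positive")

    @property
    def qt_ms(self) -> float:
        return self.t_end_ms - self.qrs_onset_ms

    @property
    def qrs_duration_ms(self) -> float:
        return self.qrs_offset_ms - self.qrs_onset_ms

    @property
    def jtpeak_ms(self) -> float:
        return self.t_peak_ms - self.qrs_offset_ms

    @property
    def tpeaktend_ms(self) -> float:
        return self.t_end_ms - self.t_peak_ms
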