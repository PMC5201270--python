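"""T-wave morphology biomarkers from a delineated median beat.

Definitions (documented surrogates for proprietary measurement software;
each is switchable through :class:`MorphologyConfig`):

* **flatness** -- treat the rectified, area-normalized T wave as a density
  over time and compute its kurtosis ``k = mu4 / mu2^2``; flatness is
  ``F = 1 - k**-0.5``.  A Gaussian-profile T gives ``1 - 3**-0.5 ~ 0.423``;
  heavier shoulders (flatter tops relative to spread) push F toward 1.
* **asymmetry** -- mirror difference about the peak of the peak-normalized
  wave: ``A = sum|w(p+u) - w(p-u)| / sum(w(p+u) + w(p-u))`` over the
  symmetric overlap window; 0 iff mirror-symmetric.
* **ERD/LRD at level L** (default 30% of peak amplitude) -- time from the
  last pre-peak crossing of ``L x peak`` to the peak (early repolarization
  duration) and from the peak to the first post-peak crossing (late),
  linearly interpolated between samples.
* **amplitude** -- maximum of the vector-magnitude T wave (value at Tpeak).
* **ventricular gradient** -- magnitude of the per-lead time-integral vector
  over QRS onset -> Tend, in uV*s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Fiducials, MedianBeat

__all__ = [
    "MorphologyError",
    "MorphologyConfig",
    "TWaveSegment",
    "MorphologyRecord",
    "extract_t_segment",
    "t_flatness",
    "t_asymmetry",
    "erd_lrd",
    "t_amplitude",
    "ventricular_gradient",
    "compute_morphology",
]


class MorphologyError(ValueError):
    """Segment is degenerate for the requested biomarker."""


@dataclass
class MorphologyConfig:
    erd_lrd_level: float = 0.30  # fraction of peak amplitude
    t_onset_after_j_ms: float = 10.0  # T-onset surrogate: J + this offset
    t_end_pad_ms: float = 30.0  # pad after Tend so limb tails are covered


@dataclass
class TWaveSegment:
    """Rectified, baseline-corrected T wave on the analysis lead (uV)."""

    values: np.ndarray
    fs_hz: float
    peak_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 3:
            raise MorphologyError("T segment too short")
        if not 0 < self.peak_index < self.values.size - 1:
            raise MorphologyError("T peak must be strictly interior to the segment")
        if self.values[self.peak_index] <= 0:
            raise MorphologyError("nonpositive peak amplitude after rectification")

    @property
    def ms_per_sample(self) -> float:
        return 1000.0 / self.fs_hz


@dataclass
class MorphologyRecord:
    flatness_du: float
    asymmetry_du: float
    amplitude_uv: float
    erd30_ms: float
    lrd30_ms: float
    tvec_max_uv: float | None = None
    vg_uvs: float | None = None


def extract_t_segment(
    beat: MedianBeat,
    fid: Fiducials,
    config: MorphologyConfig | None = None,
    baseline_uv: float = 0.0,
) -> TWaveSegment:
    """Cut the T wave from the vector-magnitude lead between the T-onset
    surrogate (J + offset) and Tend (+ pad), rectified against baseline."""
    cfg = config or MorphologyConfig()
    vm = beat.vm()
    ms = 1000.0 / beat.fs_hz
    start = int(round((fid.qrs_offset_ms + cfg.t_onset_after_j_ms) / ms))
    stop = int(round((fid.t_end_ms + cfg.t_end_pad_ms) / ms))
    start = max(0, start)
    stop = min(vm.size, stop)
    seg = np.clip(vm[start:stop] - baseline_uv, 0.0, None)
    peak = int(round(fid.t_peak_ms / ms)) - start
    if not 0 < peak < seg.size - 1:
        raise MorphologyError("T peak outside the extracted segment")
    # snap to the local sampled maximum (guards against rounding)
    lo, hi = max(0, peak - 3), min(seg.size, peak + 4)
    peak = lo + int(np.argmax(seg[lo:hi]))
    return TWaveSegment(values=seg, fs_hz=beat.fs_hz, peak_index=peak)


def t_flatness(seg: TWaveSegment) -> float:
    """Kurtosis-based flatness of the area-normalized T wave (d.u.)."""
    y = seg.values
    area = float(np.sum(y))
    if area <= 0:
        raise MorphologyError("zero-area T segment")
    p = y / area
    x = np.arange(y.size, dtype=float)
    mean = float(np.sum(x * p))
    mu2 = float(np.sum((x - mean) ** 2 * p))
    mu4 = float(np.sum((x - mean) ** 4 * p))
    if mu2 <= 0:
        raise MorphologyError("degenerate (zero-spread) T segment")
    kurt = mu4 / mu2**2
    return 1.0 - kurt**-0.5


def t_asymmetry(seg: TWaveSegment) -> float:
    """Mirror-difference asymmetry about the peak (0 = symmetric)."""
    p = seg.peak_index
    w = seg.values / seg.values[p]
    m = min(p, w.size - 1 - p)
    if m < 1:
        raise MorphologyError("peak at segment boundary")
    right = w[p + 1 : p + m + 1]
    stop = p - m - 1
    left = w[p - 1 : (stop if stop >= 0 else None) : -1]
    denom = float(np.sum(right + left))
    if denom == 0:
        raise MorphologyError("empty overlap window")
    return float(np.sum(np.abs(right - left))) / denom


def _crossing_ms(seg: TWaveSegment, level_uv: float, side: int) -> float:
    """Interpolated time (ms) from peak to the level crossing on one limb.

    ``side=-1`` scans backwards (ascending limb, last pre-peak crossing),
    ``side=+1`` forwards (descending limb, first post-peak crossing).
    """
    y = seg.values
    p = seg.peak_index
    idx = np.arange(p, -1, -1) if side < 0 else np.arange(p, y.size)
    vals = y[idx]
    below = np.flatnonzero(vals <= level_uv)
    if below.size == 0:
        raise MorphologyError("limb does not descend below the level in the segment")
    j = below[0]
    if j == 0:
        return 0.0
    a, b = vals[j - 1], vals[j]
    frac = (a - level_uv) / (a - b) if a != b else 0.0
    return (j - 1 + frac) * seg.ms_per_sample


def erd_lrd(seg: TWaveSegment, level: float = 0.30) -> dict[str, float]:
    """Early/late repolarization durations at ``level`` x peak amplitude."""
    if not 0 < level <= 1:
        raise MorphologyError("level must be in (0, 1]")
    peak_uv = seg.values[seg.peak_index]
    level_uv = level * peak_uv
    return {
        "erd_ms": _crossing_ms(seg, level_uv, side=-1),
        "lrd_ms": _crossing_ms(seg, level_uv, side=+1),
    }


def t_amplitude(seg: TWaveSegment) -> float:
    """Peak T amplitude on the vector-magnitude lead (uV)."""
    return float(seg.values[seg.peak_index])


def ventricular_gradient(beat: MedianBeat, fid: Fiducials) -> float:
    """Magnitude of the per-lead QRS-onset->Tend integral vector (uV*s)."""
    if beat.samples.shape[0] < 2:
        raise MorphologyError("ventricular gradient needs a multi-lead beat")
    ms = 1000.0 / beat.fs_hz
    start = int(round(fid.qrs_onset_ms / ms))
    stop = int(round(fid.t_end_ms / ms)) + 1
    window = beat.samples[:, start:stop]
    integrals = np.trapezoid(window, dx=1.0 / beat.fs_hz, axis=1)
    return float(np.linalg.norm(integrals))


def compute_morphology(
    beat: MedianBeat,
    fid: Fiducials,
    config: MorphologyConfig | None = None,
    baseline_uv: float = 0.0,
) -> MorphologyRecord:
    """All morphology biomarkers for one delineated median beat."""
    cfg = config or MorphologyConfig()
    seg = extract_t_segment(beat, fid, cfg, baseline_uv)
    durations = erd_lrd(seg, cfg.erd_lrd_level)
    amp = t_amplitude(seg)
    vg = (
        ventricular_gradient(beat, fid) if beat.samples.shape[0] >= 2 else None
    )
    return MorphologyRecord(
        flatness_du=t_flatness(seg),
        asymmetry_du=t_asymmetry(seg),
        amplitude_uv=amp,
        erd30_ms=durations["erd_ms"],
        lrd30_ms=durations["lrd_ms"],
        tvec_max_uv=amp,
        vg_uvs=vg,
    )
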