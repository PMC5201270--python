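"""Fiducial detection on 10-s recordings via a representative median beat.

The analysis lead is the vector magnitude (per-sample L2 norm across leads).
QRS onset/offset come from derivative-threshold crossings around the R
deflection, the T peak from the maximum of the (smoothed) T wave, and T-end
from the tangent method: the steepest descending tangent extended to the
isoelectric baseline.  A threshold-crossing T-end is available behind a
config flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import EcgRecording, Fiducials, MedianBeat

__all__ = [
    "DelineationError",
    "DelineationConfig",
    "resample",
    "detect_r_peaks",
    "build_median_beat",
    "delineate_beat",
    "measure_intervals",
    "delineate_recording",
]


class DelineationError(ValueError):
    """Recording or beat cannot be measured."""


@dataclass
class DelineationConfig:
    """Tunable delineation parameters (all windows in ms unless noted)."""

    target_fs_hz: float = 1000.0
    qrs_smooth_ms: float = 9.0  # Savitzky-Golay window for the QRS region
    t_smooth_ms: float = 31.0  # wider smoothing for the low-frequency T wave
    qrs_deriv_frac: float = 0.05  # threshold as a fraction of max |dV/dt|
    qrs_gap_close_ms: float = 24.0  # bridge sub-threshold gaps between Q/R/S
    qrs_halfspan_ms: float = 200.0  # search span around R for QRS edges
    baseline_from_ms: float = 60.0  # baseline window: [onset-from, onset-to]
    baseline_to_ms: float = 10.0
    t_search_from_j_ms: float = 40.0  # start of T search after the J point
    t_refine_halfwidth_ms: float = 15.0  # parabolic refinement of the peak
    tend_fit_halfwidth_ms: float = 14.0  # slope fit around the steepest point
    tend_search_span_ms: float = 220.0
    min_t_amplitude_uv: float = 30.0  # noise floor for a measurable T wave
    tend_method: str = "tangent"  # or "threshold"
    tend_threshold_frac: float = 0.05
    rr_exclusion_frac: float = 0.20  # beats deviating more from median RR


def _odd_window(ms: float, fs_hz: float, minimum: int = 5) -> int:
    n = max(minimum, int(round(ms * fs_hz / 1000.0)))
    return n + 1 if n % 2 == 0 else n


def resample(rec: EcgRecording, target_fs_hz: float) -> EcgRecording:
    """Band-limited (polyphase) resampling of all leads."""
    if target_fs_hz <= 0:
        raise ValueError("target_fs_hz must be positive")
    if target_fs_hz < rec.fs_hz:
        raise ValueError("only upsampling (target >= source rate) is supported")
    if target_fs_hz == rec.fs_hz:
        return rec
    frac = Fraction(target_fs_hz / rec.fs_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    samples = signal.resample_poly(rec.samples, up, down, axis=1, padtype="line")
    truth = None
    if rec.truth is not None:
        scale = target_fs_hz / rec.fs_hz
        truth = [
            replace(
                t,
                qrs_onset=int(round(t.qrs_onset * scale)),
                qrs_offset=int(round(t.qrs_offset * scale)),
                t_peak=int(round(t.t_peak * scale)),
                t_end=int(round(t.t_end * scale)),
                r_peak=int(round(t.r_peak * scale)),
            )
            for t in rec.truth
        ]
    return EcgRecording(samples, target_fs_hz, rec.lead_names, dict(rec.metadata), truth)


def detect_r_peaks(rec: EcgRecording, min_qrs_uv: float = 50.0) -> np.ndarray:
    """One index per beat at the dominant QRS deflection of the vector lead.

    Works on smoothed slope energy (squared derivative integrated over a
    short window), where the steep QRS dwarfs the low-slope T wave, then
    snaps each detection to the local vector-magnitude maximum.
    """
    vm = rec.vm()
    win = _odd_window(15.0, rec.fs_hz)
    vm_s = signal.savgol_filter(vm, win, 3)
    floor = float(np.median(vm_s))
    peak = float(np.max(vm_s))
    if peak - floor < min_qrs_uv:
        raise DelineationError("no beats detected (flat or all-noise input)")
    energy = np.gradient(vm_s) ** 2
    box = max(3, int(round(0.08 * rec.fs_hz)))  # 80 ms integration window
    energy = np.convolve(energy, np.ones(box) / box, mode="same")
    distance = int(round(0.2 * rec.fs_hz))  # 200 ms refractory
    idx, _ = signal.find_peaks(energy, height=0.25 * energy.max(), distance=distance)
    if idx.size < 2:
        raise DelineationError("fewer than two beats detected")
    half = int(round(0.06 * rec.fs_hz))
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(vm_s.size, i + half + 1)
        refined.append(lo + int(np.argmax(vm_s[lo:hi])))
    refined = np.unique(refined)
    return refined


def build_median_beat(rec: EcgRecording, r_peaks: np.ndarray) -> MedianBeat:
    """Align beats on R and take the per-sample median per lead.

    Beats whose preceding RR deviates more than the configured fraction from
    the median RR are excluded (ectopy/bigeminy guard); at least three usable
    beats are required.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 3:
        raise DelineationError("need at least 3 R peaks for a median beat")
    rr = np.diff(r_peaks) / rec.fs_hz
    med_rr = float(np.median(rr))
    pre = int(round(min(300.0, 350.0 * med_rr) * rec.fs_hz / 1000.0))
    post = int(round(min(650.0, 750.0 * med_rr) * rec.fs_hz / 1000.0))

    windows = []
    kept_rr = []
    for i, r in enumerate(r_peaks):
        rr_prev = rr[i - 1] if i > 0 else None
        rr_next = rr[i] if i < rr.size else None
        neighbors = [x for x in (rr_prev, rr_next) if x is not None]
        if any(abs(x - med_rr) > 0.20 * med_rr for x in neighbors):
            continue
        if r - pre < 0 or r + post > rec.n_samples:
            continue
        windows.append(rec.samples[:, r - pre : r + post])
        kept_rr.append(rr_prev if rr_prev is not None else rr_next)
    if len(windows) < 3:
        raise DelineationError("fewer than 3 usable beats after RR exclusion")
    stack = np.stack(windows, axis=0)  # (n_beats, n_leads, n)
    return MedianBeat(
        samples=np.median(stack, axis=0),
        fs_hz=rec.fs_hz,
        n_contributing_beats=len(windows),
        mean_rr_s=float(np.mean(kept_rr)),
        r_index=pre,
    )


def _interp_crossing(x: np.ndarray, i_out: int, i_in: int, level: float) -> float:
    """Linear-interpolated index where ``x`` crosses ``level`` between the
    sample outside the region and the one inside it."""
    a, b = x[i_out], x[i_in]
    if b == a:
        return float(i_in)
    frac = (level - a) / (b - a)
    return i_out + frac * (i_in - i_out)


def delineate_beat(beat: MedianBeat, config: DelineationConfig | None = None) -> Fiducials:
    """Locate QRS onset/offset, T peak and T end on a median beat."""
    cfg = config or DelineationConfig()
    fs = beat.fs_hz
    ms = 1000.0 / fs  # ms per sample
    vm = beat.vm()
    n = vm.size
    if n < int(0.3 * fs):
        raise DelineationError("beat window too short")

    vq = signal.savgol_filter(vm, _odd_window(cfg.qrs_smooth_ms, fs), 3)
    r_idx = int(np.argmax(vq))
    deriv = np.gradient(vq)
    span = int(round(cfg.qrs_halfspan_ms / ms))
    lo, hi = max(0, r_idx - span), min(n, r_idx + span)
    thr = cfg.qrs_deriv_frac * float(np.max(np.abs(deriv[lo:hi])))
    mask = np.abs(deriv) > thr
    mask[:lo] = False
    mask[hi:] = False
    # bridge short sub-threshold gaps so Q/R/S form one supra-threshold run
    gap = int(round(cfg.qrs_gap_close_ms / ms))
    above = np.flatnonzero(mask)
    if above.size == 0:
        raise DelineationError("no QRS derivative activity found")
    for a, b in zip(above, above[1:]):
        if 1 < b - a <= gap:
            mask[a:b] = True
    run = np.flatnonzero(mask)
    run = run[(run >= lo) & (run < hi)]
    seg = np.flatnonzero(np.diff(run) > 1)
    # contiguous run containing R
    starts = np.concatenate(([0], seg + 1))
    ends = np.concatenate((seg, [run.size - 1]))
    onset_i = offset_i = None
    for s, e in zip(starts, ends):
        if run[s] <= r_idx <= run[e]:
            onset_i, offset_i = run[s], run[e]
            break
    if onset_i is None:
        # R not inside a run (can happen at the exact apex); take nearest run
        onset_i, offset_i = run[0], run[-1]
    abs_d = np.abs(deriv)
    onset = (
        _interp_crossing(abs_d, onset_i - 1, onset_i, thr) if onset_i > 0 else float(onset_i)
    )
    offset = (
        _interp_crossing(abs_d, offset_i + 1, offset_i, thr)
        if offset_i < n - 1
        else float(offset_i)
    )

    b_from = int(round(onset - cfg.baseline_from_ms / ms))
    b_to = int(round(onset - cfg.baseline_to_ms / ms))
    baseline = float(np.median(vm[max(0, b_from) : max(1, b_to)])) if b_to > 1 else 0.0

    vt = signal.savgol_filter(vm, _odd_window(cfg.t_smooth_ms, fs), 2)
    t_from = int(round(offset + cfg.t_search_from_j_ms / ms))
    t_to = n - int(round(10.0 / ms))
    if t_to - t_from < 10:
        raise DelineationError("no room for a T wave after the QRS")
    tp_i = t_from + int(np.argmax(vt[t_from:t_to]))
    t_amp = float(vt[tp_i] - baseline)
    if t_amp < cfg.min_t_amplitude_uv:
        raise DelineationError(
            f"T amplitude {t_amp:.1f} uV below the {cfg.min_t_amplitude_uv} uV floor"
        )
    # parabolic refinement of the peak location
    hw = int(round(cfg.t_refine_halfwidth_ms / ms))
    sl = slice(max(t_from, tp_i - hw), min(t_to, tp_i + hw + 1))
    xs = np.arange(sl.start, sl.stop, dtype=float)
    coef = np.polyfit(xs, vt[sl], 2)
    tp = -coef[1] / (2 * coef[0]) if coef[0] < 0 else float(tp_i)
    if not sl.start <= tp <= sl.stop:
        tp = float(tp_i)

    dv = np.gradient(vt)
    s_from = tp_i + int(round(5.0 / ms))
    s_to = min(n - 2, tp_i + int(round(cfg.tend_search_span_ms / ms)))
    if s_to - s_from < 3:
        raise DelineationError("descending T limb truncated by the beat window")
    st_i = s_from + int(np.argmin(dv[s_from:s_to]))

    if cfg.tend_method == "tangent":
        fh = int(round(cfg.tend_fit_halfwidth_ms / ms))
        sl = slice(max(tp_i, st_i - fh), min(n, st_i + fh + 1))
        xs = np.arange(sl.start, sl.stop, dtype=float)
        slope, intercept = np.polyfit(xs, vt[sl], 1)
        if slope >= 0:
            raise DelineationError("no descending tangent found after the T peak")
        tend = (baseline - intercept) / slope
    elif cfg.tend_method == "threshold":
        level = baseline + cfg.tend_threshold_frac * t_amp
        below = np.flatnonzero(vt[st_i:s_to] <= level)
        if below.size == 0:
            raise DelineationError("T wave does not return to baseline in the window")
        j = st_i + below[0]
        tend = _interp_crossing(vt, j - 1, j, level)
    else:
        raise ValueError(f"unknown tend_method {cfg.tend_method!r}")

    try:
        return Fiducials(
            qrs_onset_ms=onset * ms,
            qrs_offset_ms=offset * ms,
            t_peak_ms=tp * ms,
            t_end_ms=tend * ms,
            rr_s=beat.mean_rr_s,
        )
    except ValueError as err:
        raise DelineationError(f"fiducials inconsistent: {err}") from err


def measure_intervals(fid: Fiducials) -> dict[str, float]:
    """Subinterval durations; QT = QRS + J-Tpeak + Tpeak-Tend by construction."""
    return {
        "rr_s": fid.rr_s,
        "qt_ms": fid.qt_ms,
        "jtpeak_ms": fid.jtpeak_ms,
        "tpeaktend_ms": fid.tpeaktend_ms,
        "qrs_ms": fid.qrs_duration_ms,
    }


def delineate_recording(
    rec: EcgRecording, config: DelineationConfig | None = None
) -> tuple[MedianBeat, Fiducials]:
    """Resample -> R detection -> median beat -> fiducials, in one call."""
    cfg = config or DelineationConfig()
    if cfg.target_fs_hz > rec.fs_hz:
        rec = resample(rec, cfg.target_fs_hz)
    r_peaks = detect_r_peaks(rec)
    beat = build_median_beat(rec, r_peaks)
    fid = delineate_beat(beat, cfg)
    return beat, fid
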