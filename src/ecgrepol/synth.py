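"""Synthetic crossover-trial generator with waveform-level ground truth.

This module emulates a five-period randomized crossover study in 21 healthy
subjects in which a selective hERG potassium-channel blocker (dofetilide or
moxifloxacin) is given alone or combined with a late sodium-current blocker
(mexiletine or lidocaine).  It provides two levels of synthesis:

* **waveform level** -- 10-s multi-lead ECGs built from a parametric beat
  model (biphasic QRS plus a two-half-bell T wave with a heavy-shoulder
  mixing term), with per-beat ground-truth fiducials, so the delineation and
  morphology stages can be validated against known truth;

* **biomarker level** -- per-recording biomarker tables drawn directly from
  the calibrated population model, used for trial-scale statistical studies
  (placebo-corrected effect estimation, ROC ranking) where waveform synthesis
  would only add cost, not information.

Both levels share one calibration: population mean placebo-corrected changes
at the concentration peak (Cmax) of each drug reproduce the published
clinical effect sizes (e.g. dofetilide ~+45 ms QTc, ~+29 ms J-Tpeakc; the
combinations ~+17-18 ms QTc with J-Tpeakc pulled back to ~+1-4 ms).
Drug effects are linear in plasma concentration and additive across
co-administered drugs on the beat-parameter scale; inter-subject variability
enters through lognormal sensitivity multipliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal

from .core import BeatTruth, EcgRecording

__all__ = [
    "ARMS",
    "DRUGS",
    "ARM_DRUGS",
    "TIMEPOINT_LABELS",
    "BASELINE_MEAN",
    "BASELINE_SD",
    "DRUG_EFFECT_TARGETS",
    "MEASUREMENT_SD",
    "TrialDesign",
    "SubjectProfile",
    "BeatParams",
    "PkModel",
    "DrugEffectModel",
    "simulate_pk",
    "default_pk_models",
    "apply_drug_effect",
    "synthesize_beat",
    "synthesize_recording",
    "simulate_trial",
    "simulate_biomarker_trial",
    "simulate_alpha_baseline",
    "baseline_beat_params",
    "calibrate_effects",
    "default_biomarker_slopes",
    "t_wave_shape",
    "tangent_tpeak_tend",
    "level_crossing_time",
    "shape_flatness",
]

# ---------------------------------------------------------------------------
# Study constants
# ---------------------------------------------------------------------------

ARMS = (
    "placebo",
    "dofetilide",
    "moxifloxacin",
    "mexiletine+dofetilide",
    "lidocaine+dofetilide",
)
DRUGS = ("dofetilide", "moxifloxacin", "mexiletine", "lidocaine")
ARM_DRUGS = {
    "placebo": (),
    "dofetilide": ("dofetilide",),
    "moxifloxacin": ("moxifloxacin",),
    "mexiletine+dofetilide": ("mexiletine", "dofetilide"),
    "lidocaine+dofetilide": ("lidocaine", "dofetilide"),
}

#: post-dose sampling grid (hours after the first of three daily doses)
TIMEPOINT_LABELS = {0.0: "baseline", 2.0: "morning", 6.5: "afternoon", 13.0: "evening"}

BIOMARKERS = (
    "qtc_ms",
    "jtpeakc_ms",
    "tpeaktend_ms",
    "flatnessc_du",
    "asymmetry_du",
    "erd30_ms",
    "lrd30_ms",
    "amplitudec_uv",
)

#: healthy-volunteer baseline population (heart-rate-corrected scale)
BASELINE_MEAN = {
    "qtc_ms": 397.1,
    "jtpeakc_ms": 228.2,
    "tpeaktend_ms": 82.2,
    "flatnessc_du": 0.43,
    "asymmetry_du": 0.20,
    "erd30_ms": 50.1,
    "lrd30_ms": 31.1,
    "amplitudec_uv": 569.0,
}
BASELINE_SD = {
    "qtc_ms": 14.0,
    "jtpeakc_ms": 18.2,
    "tpeaktend_ms": 6.4,
    "flatnessc_du": 0.05,
    # reported to vanishing precision; a small nonzero spread is used
    "asymmetry_du": 0.02,
    "erd30_ms": 7.4,
    "lrd30_ms": 5.3,
    "amplitudec_uv": 149.0,
}
BASELINE_HR_BPM = (60.7, 6.3)

#: population-mean placebo-corrected change per biomarker when the drug is at
#: its reference (peak) concentration.  hERG blockers prolong repolarization
#: and flatten/shrink the T wave; the late sodium-current blockers are
#: parameterized as increments over co-administered dofetilide so that the
#: combination arms land on their published population values.
DRUG_EFFECT_TARGETS = {
    "dofetilide": {
        "qtc_ms": 45.2,
        "jtpeakc_ms": 29.1,
        "tpeaktend_ms": 17.9,
        "flatnessc_du": 0.11,
        "asymmetry_du": 0.20,
        "erd30_ms": 19.8,
        "lrd30_ms": 9.8,
        "amplitudec_uv": -87.9,
    },
    # weak hERG block: QTc prolongation ~12 ms with the same signature shape
    "moxifloxacin": {
        "qtc_ms": 12.0,
        "jtpeakc_ms": 7.7,
        "tpeaktend_ms": 4.8,
        "flatnessc_du": 0.029,
        "asymmetry_du": 0.053,
        "erd30_ms": 5.3,
        "lrd30_ms": 2.6,
        "amplitudec_uv": -23.3,
    },
    # late-Na block shortens early repolarization: strong negative J-Tpeakc
    "mexiletine": {
        "qtc_ms": -27.9,
        "jtpeakc_ms": -28.0,
        "tpeaktend_ms": -3.3,
        "flatnessc_du": -0.05,
        "asymmetry_du": -0.11,
        "erd30_ms": -8.7,
        "lrd30_ms": 1.5,
        "amplitudec_uv": 32.8,
    },
    "lidocaine": {
        "qtc_ms": -27.3,
        "jtpeakc_ms": -25.0,
        "tpeaktend_ms": -5.0,
        "flatnessc_du": -0.05,
        "asymmetry_du": -0.10,
        "erd30_ms": -8.6,
        "lrd30_ms": 0.0,
        "amplitudec_uv": 30.3,
    },
}

#: replicate-to-replicate measurement scatter (raw scale, one 10-s ECG)
MEASUREMENT_SD = {
    "qt_ms": 6.0,
    "jtpeak_ms": 7.0,
    "tpeaktend_ms": 5.0,
    "flatness_du": 0.035,
    "asymmetry_du": 0.06,
    "erd30_ms": 6.0,
    "lrd30_ms": 4.5,
    "amplitude_uv": 40.0,
}

#: rate-correction exponents used when mapping corrected-scale values to raw
CORRECTION_ALPHA = {
    "qtc_ms": 1.0 / 3.0,  # Fridericia
    "jtpeakc_ms": 0.58,
    "flatnessc_du": 0.50,
    "amplitudec_uv": 0.96,
}
RAW_NAME = {
    "qtc_ms": "qt_ms",
    "jtpeakc_ms": "jtpeak_ms",
    "tpeaktend_ms": "tpeaktend_ms",
    "flatnessc_du": "flatness_du",
    "asymmetry_du": "asymmetry_du",
    "erd30_ms": "erd30_ms",
    "lrd30_ms": "lrd30_ms",
    "amplitudec_uv": "amplitude_uv",
}

#: width ratio of the heavy-shoulder T component to the main limb
TAIL_WIDTH_RATIO = 1.6
#: tail weights above this leave the regime where flatness grows with weight
MAX_TAIL_WEIGHT = 0.22


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TrialDesign:
    n_subjects: int = 21
    n_female: int = 8
    arms: tuple[str, ...] = ARMS
    periods: int | None = None
    doses_per_day: int = 3
    timepoint_hours: tuple[float, ...] = (2.0, 6.5, 13.0)
    replicates_per_timepoint: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.periods is None:
            self.periods = len(self.arms)
        if self.n_female > self.n_subjects:
            raise ValueError("n_female cannot exceed n_subjects")
        if self.periods != len(self.arms):
            raise ValueError("periods must equal the number of arms")
        if self.replicates_per_timepoint < 1:
            raise ValueError("replicates_per_timepoint must be >= 1")
        if self.n_subjects < 2:
            raise ValueError("a crossover needs at least 2 subjects")

    def sequence_for(self, subject_index: int) -> tuple[str, ...]:
        """Latin-square-style cyclic rotation of the arm list."""
        k = subject_index % len(self.arms)
        return tuple(self.arms[(i + k) % len(self.arms)] for i in range(len(self.arms)))


@dataclass
class BeatParams:
    """Parametric description of one cardiac cycle.

    The T wave is a two-half-bell: a bell limb of width ``sigma_asc_ms``
    ascending to the peak and ``sigma_desc_ms`` descending from it, each
    mixed with a ``TAIL_WIDTH_RATIO``-times wider component weighted by
    ``t_tail_weight`` (the heavy shoulder controlling flatness).
    """

    qrs_duration_ms: float
    j_to_tpeak_ms: float
    sigma_asc_ms: float
    sigma_desc_ms: float
    t_amplitude_uv: float
    t_tail_weight: float
    rr_s: float
    qrs_amplitude_uv: float = 1100.0

    def __post_init__(self) -> None:
        for name in ("qrs_duration_ms", "j_to_tpeak_ms", "sigma_asc_ms", "sigma_desc_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 <= self.t_tail_weight < 1.0:
            raise ValueError("t_tail_weight must be in [0, 1)")
        if self.rr_s <= 0:
            raise ValueError("rr_s must be positive")

    @property
    def tpeak_to_tend_ms(self) -> float:
        return tangent_tpeak_tend(self.sigma_desc_ms, self.t_tail_weight)

    @property
    def qt_ms(self) -> float:
        return self.qrs_duration_ms + self.j_to_tpeak_ms + self.tpeak_to_tend_ms


@dataclass
class SubjectProfile:
    subject_id: str
    sex: str  # "F" or "M"
    baseline_rr_s: float
    baseline_beat: BeatParams
    random_slopes: dict[str, float] = field(default_factory=dict)
    conc_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.5 <= self.baseline_rr_s <= 1.5:
            raise ValueError("baseline_rr_s outside [0.5, 1.5] s")
        if any(v <= 0 for v in self.random_slopes.values()):
            raise ValueError("sensitivity multipliers must be positive")


@dataclass
class PkModel:
    """One-compartment model with first-order absorption, dose superposition."""

    ka_per_h: float
    ke_per_h: float
    v_scaled: float
    dose_amounts: tuple[float, ...]
    dose_times_h: tuple[float, ...]

    def __post_init__(self) -> None:
        if math.isclose(self.ka_per_h, self.ke_per_h, rel_tol=1e-9):
            raise ValueError("ka == ke (flip-flop degenerate form not supported)")
        if len(self.dose_amounts) != len(self.dose_times_h):
            raise ValueError("dose_amounts and dose_times_h must align")

    @classmethod
    def scaled_to_cmax(
        cls,
        ka_per_h: float,
        ke_per_h: float,
        dose_amounts: tuple[float, ...],
        dose_times_h: tuple[float, ...],
        cmax_ng_ml: float,
    ) -> "PkModel":
        """Choose the volume scale so the population curve peaks at ``cmax``."""
        model = cls(ka_per_h, ke_per_h, 1.0, dose_amounts, dose_times_h)
        grid = np.linspace(0.0, dose_times_h[-1] + 24.0, 4000)
        peak = simulate_pk(model, grid).max()
        return cls(ka_per_h, ke_per_h, cmax_ng_ml / peak, dose_amounts, dose_times_h)

    def tmax_h(self, horizon_h: float = 36.0) -> float:
        grid = np.linspace(0.0, horizon_h, 7200)
        return float(grid[np.argmax(simulate_pk(self, grid))])


@dataclass
class DrugEffectModel:
    """Linear concentration -> beat-parameter slopes, per drug.

    Each entry maps a drug name to slopes (per ng/mL) on ``j_to_tpeak_ms``,
    ``sigma_desc_ms``, ``t_amplitude_uv`` and ``t_tail_weight``.  Effects of
    co-administered drugs add on the beat-parameter scale; zero concentration
    implies zero effect by construction.
    """

    slopes: dict[str, dict[str, float]]


# ---------------------------------------------------------------------------
# Pharmacokinetics
# ---------------------------------------------------------------------------


def simulate_pk(model: PkModel, times_h) -> np.ndarray:
    """Plasma concentration (ng/mL) at ``times_h`` (sorted, nonnegative)."""
    t = np.asarray(times_h, dtype=float)
    if t.ndim and np.any(np.diff(t) < 0):
        raise ValueError("times_h must be sorted")
    if np.any(t < 0):
        raise ValueError("times_h must be nonnegative")
    ka, ke = model.ka_per_h, model.ke_per_h
    conc = np.zeros_like(t, dtype=float)
    for dose, t0 in zip(model.dose_amounts, model.dose_times_h):
        tau = t - t0
        mask = tau > 0
        conc[mask] += (
            dose
            * model.v_scaled
            * ka
            / (ka - ke)
            * (np.exp(-ke * tau[mask]) - np.exp(-ka * tau[mask]))
        )
    return conc


def default_pk_models() -> dict[str, PkModel]:
    """Population PK per drug, calibrated so the three-dose regimens peak
    ~12.5-13 h after the first dose at the published mean concentrations."""
    three_doses = (0.0, 5.5, 11.0)
    return {
        "dofetilide": PkModel.scaled_to_cmax(0.8, 0.22, (1, 1, 1), three_doses, 1.8),
        "mexiletine": PkModel.scaled_to_cmax(0.8, 0.22, (1, 1, 1), three_doses, 1426.0),
        "lidocaine": PkModel.scaled_to_cmax(0.8, 0.22, (1, 1, 1), three_doses, 2261.0),
        # single morning dose, fast absorption: effects peak in the morning
        "moxifloxacin": PkModel.scaled_to_cmax(1.5, 0.15, (1,), (0.0,), 3000.0),
    }


#: reference time-point (h) at which each drug's calibration target applies
DRUG_REFERENCE_HOUR = {
    "dofetilide": 13.0,
    "mexiletine": 13.0,
    "lidocaine": 13.0,
    "moxifloxacin": 2.0,
}


# ---------------------------------------------------------------------------
# T-wave shape mathematics (shared by generator truth and calibration)
# ---------------------------------------------------------------------------


def t_wave_shape(
    u_ms,
    sigma_asc_ms: float,
    sigma_desc_ms: float,
    tail_weight: float,
    k: float = TAIL_WIDTH_RATIO,
) -> np.ndarray:
    """Unit-peak T shape at offsets ``u_ms`` from the peak (negative = early)."""
    u = np.asarray(u_ms, dtype=float)
    sig = np.where(u < 0, sigma_asc_ms, sigma_desc_ms)
    narrow = np.exp(-0.5 * (u / sig) ** 2)
    wide = np.exp(-0.5 * (u / (k * sig)) ** 2)
    return (1.0 - tail_weight) * narrow + tail_weight * wide


def _desc_value_and_slope(u: float, sigma: float, w: float, k: float):
    f = (1 - w) * math.exp(-0.5 * (u / sigma) ** 2) + w * math.exp(
        -0.5 * (u / (k * sigma)) ** 2
    )
    fp = -(1 - w) * u / sigma**2 * math.exp(-0.5 * (u / sigma) ** 2) - w * u / (
        k * sigma
    ) ** 2 * math.exp(-0.5 * (u / (k * sigma)) ** 2)
    return f, fp


def tangent_tpeak_tend(
    sigma_desc_ms: float, tail_weight: float, k: float = TAIL_WIDTH_RATIO
) -> float:
    """Tpeak->Tend (ms) of the descending limb under the tangent rule.

    The tangent at the steepest descending point is extended to the zero
    baseline; its intersection defines T-end, mirroring the delineator.
    """
    res = optimize.minimize_scalar(
        lambda u: _desc_value_and_slope(u, sigma_desc_ms, tail_weight, k)[1],
        bounds=(0.2 * sigma_desc_ms, 3.0 * k * sigma_desc_ms),
        method="bounded",
        options={"xatol": 1e-6},
    )
    u_star = float(res.x)
    f, fp = _desc_value_and_slope(u_star, sigma_desc_ms, tail_weight, k)
    return u_star + f / abs(fp)


def level_crossing_time(
    sigma_ms: float, tail_weight: float, level: float, k: float = TAIL_WIDTH_RATIO
) -> float:
    """Offset (ms) from the peak at which one limb crosses ``level``x peak."""
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    if level == 1.0:
        return 0.0

    def g(u):
        return _desc_value_and_slope(u, sigma_ms, tail_weight, k)[0] - level

    hi = k * sigma_ms
    while g(hi) > 0:
        hi *= 1.5
    return float(optimize.brentq(g, 0.0, hi, xtol=1e-9))


def shape_flatness(
    sigma_asc_ms: float,
    sigma_desc_ms: float,
    tail_weight: float,
    k: float = TAIL_WIDTH_RATIO,
) -> float:
    """Kurtosis-based flatness of the continuous T shape (see morphology)."""
    span = 6.0 * k * max(sigma_asc_ms, sigma_desc_ms)
    u = np.linspace(-span, span, 8001)
    y = t_wave_shape(u, sigma_asc_ms, sigma_desc_ms, tail_weight, k)
    y = y / np.trapezoid(y, u)
    mean = np.trapezoid(u * y, u)
    mu2 = np.trapezoid((u - mean) ** 2 * y, u)
    mu4 = np.trapezoid((u - mean) ** 4 * y, u)
    return 1.0 - (mu2**2 / mu4) ** 0.5


# ---------------------------------------------------------------------------
# Baseline beat and drug-effect calibration (waveform level)
# ---------------------------------------------------------------------------

_REF_RR_S = 60.0 / BASELINE_HR_BPM[0]  # population mean RR at baseline


def baseline_beat_params(rr_s: float = _REF_RR_S) -> BeatParams:
    """Population-mean beat.

    The ascending limb width reproduces the published early repolarization
    duration (~50 ms at the 30% level); the descending width and shoulder
    weight are set for a plausible terminal T; J-Tpeak is then fixed so the
    truth-derived QT matches the baseline QTc after Fridericia correction.
    """
    qrs = 90.0
    sigma_asc = 32.2
    sigma_desc = 24.0
    tail = 0.06
    qt_target = BASELINE_MEAN["qtc_ms"] * _REF_RR_S ** (1.0 / 3.0)
    tpte = tangent_tpeak_tend(sigma_desc, tail)
    jtp = qt_target - qrs - tpte
    return BeatParams(
        qrs_duration_ms=qrs,
        j_to_tpeak_ms=jtp,
        sigma_asc_ms=sigma_asc,
        sigma_desc_ms=sigma_desc,
        t_amplitude_uv=BASELINE_MEAN["amplitudec_uv"] * _REF_RR_S**0.96,
        t_tail_weight=tail,
        rr_s=rr_s,
    )


def _solve_sigma_desc(tpte_target_ms: float, tail_weight: float) -> float:
    """Invert the tangent Tpeak-Tend rule for the descending width."""
    return float(
        optimize.brentq(
            lambda s: tangent_tpeak_tend(s, tail_weight) - tpte_target_ms,
            5.0,
            120.0,
            xtol=1e-8,
        )
    )


def calibrate_effects(pk_models: dict[str, PkModel] | None = None) -> DrugEffectModel:
    """Solve per-drug beat-parameter slopes from the population targets.

    For each drug the corrected-scale interval targets are converted to raw
    changes at the population RR, the descending-limb width is inverted
    through the tangent rule so the QT change decomposes consistently, and
    slopes are the changes divided by the drug's reference concentration.
    """
    pk_models = pk_models or default_pk_models()
    base = baseline_beat_params()
    f_qt = _REF_RR_S ** (1.0 / 3.0)
    f_jtp = _REF_RR_S**0.58
    f_amp = _REF_RR_S**0.96
    tail_delta = {"dofetilide": 0.04, "moxifloxacin": 0.011}

    cref = {
        d: float(simulate_pk(pk_models[d], [DRUG_REFERENCE_HOUR[d]])[0]) for d in DRUGS
    }

    slopes: dict[str, dict[str, float]] = {}
    herg_abs: dict[str, dict[str, float]] = {}
    for drug in ("dofetilide", "moxifloxacin"):
        tgt = DRUG_EFFECT_TARGETS[drug]
        d_jtp = tgt["jtpeakc_ms"] * f_jtp
        d_qt = tgt["qtc_ms"] * f_qt
        d_tpte = d_qt - d_jtp
        d_tail = tail_delta[drug]
        sigma_new = _solve_sigma_desc(
            base.tpeak_to_tend_ms + d_tpte, base.t_tail_weight + d_tail
        )
        d_amp = tgt["amplitudec_uv"] * f_amp
        herg_abs[drug] = {
            "j_to_tpeak_ms": d_jtp,
            "sigma_desc_ms": sigma_new - base.sigma_desc_ms,
            "t_amplitude_uv": d_amp,
            "t_tail_weight": d_tail,
        }
        slopes[drug] = {key: val / cref[drug] for key, val in herg_abs[drug].items()}

    # late-Na blockers: solve the combination endpoint, subtract dofetilide
    combo_targets = {
        "mexiletine": {"qtc_ms": 17.3, "jtpeakc_ms": 1.1, "amplitudec_uv": -55.1},
        "lidocaine": {"qtc_ms": 17.9, "jtpeakc_ms": 4.1, "amplitudec_uv": -57.6},
    }
    for drug, tgt in combo_targets.items():
        d_jtp_combo = tgt["jtpeakc_ms"] * f_jtp
        d_qt_combo = tgt["qtc_ms"] * f_qt
        d_tail_combo = 0.015
        sigma_combo = _solve_sigma_desc(
            base.tpeak_to_tend_ms + (d_qt_combo - d_jtp_combo),
            base.t_tail_weight + d_tail_combo,
        )
        dof = herg_abs["dofetilide"]
        delta = {
            "j_to_tpeak_ms": d_jtp_combo - dof["j_to_tpeak_ms"],
            "sigma_desc_ms": (sigma_combo - base.sigma_desc_ms) - dof["sigma_desc_ms"],
            "t_amplitude_uv": tgt["amplitudec_uv"] * f_amp - dof["t_amplitude_uv"],
            "t_tail_weight": d_tail_combo - dof["t_tail_weight"],
        }
        slopes[drug] = {key: val / cref[drug] for key, val in delta.items()}
    return DrugEffectModel(slopes=slopes)


def apply_drug_effect(
    base: BeatParams, effects: DrugEffectModel, concentrations: dict[str, float]
) -> BeatParams:
    """Additive, concentration-linear modification of a beat. Deterministic."""
    if any(c < 0 for c in concentrations.values()):
        raise ValueError("concentrations must be nonnegative")
    delta = {"j_to_tpeak_ms": 0.0, "sigma_desc_ms": 0.0, "t_amplitude_uv": 0.0, "t_tail_weight": 0.0}
    for drug, conc in concentrations.items():
        if conc == 0 or drug not in effects.slopes:
            continue
        for key, slope in effects.slopes[drug].items():
            delta[key] += slope * conc
    try:
        out = replace(
            base,
            j_to_tpeak_ms=base.j_to_tpeak_ms + delta["j_to_tpeak_ms"],
            sigma_desc_ms=base.sigma_desc_ms + delta["sigma_desc_ms"],
            t_amplitude_uv=base.t_amplitude_uv + delta["t_amplitude_uv"],
            t_tail_weight=min(base.t_tail_weight + delta["t_tail_weight"], MAX_TAIL_WEIGHT),
        )
    except ValueError as err:
        raise ValueError(
            f"drug effect magnitude outside the admissible range: {err}"
        ) from err
    if out.t_amplitude_uv <= 0:
        raise ValueError("drug effect magnitude outside the admissible range")
    return out


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

_QRS_LEAD_IN_MS = 120.0
#: QRS sub-waves as (center, width, amplitude) fractions of (duration, R amp)
_QRS_COMPONENTS = ((0.15, 0.30, -0.12), (0.50, 0.50, 1.00), (0.85, 0.30, -0.18))


def _qrs_wave(t_ms: np.ndarray, duration_ms: float, amplitude_uv: float) -> np.ndarray:
    out = np.zeros_like(t_ms, dtype=float)
    for c, w, a in _QRS_COMPONENTS:
        center = c * duration_ms
        width = w * duration_ms
        x = (t_ms - center) / width
        mask = np.abs(x) < 0.5
        out[mask] += a * amplitude_uv * np.cos(np.pi * x[mask]) ** 2
    return out


def _qrs_truth_edges(duration_ms: float, amplitude_uv: float) -> tuple[float, float]:
    """Truth QRS onset/offset: first/last excursion above 0.5% of the R peak."""
    t = np.linspace(0.0, duration_ms, 8001)
    q = np.abs(_qrs_wave(t, duration_ms, amplitude_uv))
    above = np.flatnonzero(q >= 0.005 * amplitude_uv)
    return float(t[above[0]]), float(t[above[-1]])


def synthesize_beat(
    params: BeatParams, fs_hz: float
) -> tuple[np.ndarray, dict[str, float]]:
    """One beat on the vector-magnitude scale plus ground-truth fiducials (ms).

    The truth T-end follows the tangent rule on the continuous descending
    limb, so a tangent-method delineator measures the same quantity the
    generator declares.
    """
    if fs_hz < 250:
        raise ValueError("fs_hz must be >= 250")
    n = int(round(params.rr_s * fs_hz))
    t_ms = np.arange(n) / fs_hz * 1000.0
    onset_nominal = _QRS_LEAD_IN_MS
    j_ms = onset_nominal + params.qrs_duration_ms
    tpeak_ms = j_ms + params.j_to_tpeak_ms
    tpte_ms = tangent_tpeak_tend(params.sigma_desc_ms, params.t_tail_weight)
    tend_ms = tpeak_ms + tpte_ms

    t_support_end = tend_ms + 2.5 * TAIL_WIDTH_RATIO * params.sigma_desc_ms
    if t_support_end > t_ms[-1]:
        raise ValueError("QRS and T support exceed the cardiac cycle (inadmissible params)")
    if tpeak_ms - 2.0 * params.sigma_asc_ms <= j_ms:
        raise ValueError("T wave overlaps the QRS complex (inadmissible params)")

    wave = _qrs_wave(t_ms - onset_nominal, params.qrs_duration_ms, params.qrs_amplitude_uv)
    tshape = params.t_amplitude_uv * t_wave_shape(
        t_ms - tpeak_ms, params.sigma_asc_ms, params.sigma_desc_ms, params.t_tail_weight
    )
    # confine the T wave between just after J and the end of its support
    win = np.zeros_like(t_ms)
    ramp = 20.0
    start = j_ms + 10.0
    rising = (t_ms >= start) & (t_ms < start + ramp)
    win[rising] = 0.5 * (1 - np.cos(np.pi * (t_ms[rising] - start) / ramp))
    win[(t_ms >= start + ramp) & (t_ms <= t_support_end - ramp)] = 1.0
    falling = (t_ms > t_support_end - ramp) & (t_ms <= t_support_end)
    win[falling] = 0.5 * (1 + np.cos(np.pi * (t_ms[falling] - (t_support_end - ramp)) / ramp))
    wave = wave + tshape * win

    on_edge, off_edge = _qrs_truth_edges(params.qrs_duration_ms, params.qrs_amplitude_uv)
    truth = {
        "qrs_onset_ms": onset_nominal + on_edge,
        "qrs_offset_ms": onset_nominal + off_edge,
        "t_peak_ms": tpeak_ms,
        "t_end_ms": tend_ms,
        "r_peak_ms": onset_nominal + 0.5 * params.qrs_duration_ms,
        "rr_s": params.rr_s,
    }
    return wave, truth


def _lead_directions(n_leads: int) -> np.ndarray:
    """Unit-norm projection of the dipole onto pseudo-orthogonal leads."""
    if n_leads == 1:
        return np.array([1.0])
    base = np.array([0.80, 0.48, 0.36, 0.20, 0.12])
    d = base[:n_leads] if n_leads <= 5 else np.resize(base, n_leads)
    return d / np.linalg.norm(d)


def synthesize_recording(
    beat: BeatParams,
    duration_s: float = 10.0,
    rr_variability: float = 0.0,
    noise_uv_rms: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    fs_hz: float = 500.0,
    n_leads: int = 3,
    amplitude_lsb_uv: float = 2.5,
    metadata: dict | None = None,
) -> EcgRecording:
    """Concatenated beats with jittered RR, band-limited noise and 2.5-uV
    quantization; identical seeds give bit-identical samples."""
    if noise_uv_rms < 0:
        raise ValueError("noise_uv_rms must be nonnegative")
    if duration_s < 2 * beat.rr_s:
        raise ValueError("duration_s must cover at least two beats")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration_s * fs_hz))
    base = np.zeros(n_total)
    truth: list[BeatTruth] = []
    start = 0
    idx = 0
    while True:
        rr_i = beat.rr_s * float(np.exp(rng.normal(0.0, rr_variability))) if rr_variability else beat.rr_s
        beat_i = replace(beat, rr_s=rr_i)
        wave, t = synthesize_beat(beat_i, fs_hz)
        if start + wave.size > n_total:
            break
        base[start : start + wave.size] = wave
        to_idx = lambda ms: start + int(round(ms * fs_hz / 1000.0))
        truth.append(
            BeatTruth(
                beat_index=idx,
                qrs_onset=to_idx(t["qrs_onset_ms"]),
                qrs_offset=to_idx(t["qrs_offset_ms"]),
                t_peak=to_idx(t["t_peak_ms"]),
                t_end=to_idx(t["t_end_ms"]),
                r_peak=to_idx(t["r_peak_ms"]),
                rr_s=rr_i,
            )
        )
        start += wave.size
        idx += 1

    directions = _lead_directions(n_leads)
    samples = directions[:, None] * base[None, :]
    if noise_uv_rms > 0:
        sos = signal.butter(3, 40.0, fs=fs_hz, output="sos")
        noise = signal.sosfiltfilt(sos, rng.standard_normal((n_leads, n_total)), axis=1)
        noise *= noise_uv_rms / np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
        samples = samples + noise
    if amplitude_lsb_uv:
        samples = np.round(samples / amplitude_lsb_uv) * amplitude_lsb_uv
    lead_names = tuple(f"L{i+1}" for i in range(n_leads))
    return EcgRecording(samples, fs_hz, lead_names, metadata or {}, truth)


# ---------------------------------------------------------------------------
# Subject and trial generation
# ---------------------------------------------------------------------------


def _make_subjects(
    design: TrialDesign, rng: np.random.Generator, slope_cv: float, conc_cv: float
) -> list[SubjectProfile]:
    base = baseline_beat_params()
    subjects = []
    for i in range(design.n_subjects):
        hr = float(np.clip(rng.normal(*BASELINE_HR_BPM), 45.0, 95.0))
        rr = 60.0 / hr
        beat = replace(
            base,
            rr_s=rr,
            j_to_tpeak_ms=base.j_to_tpeak_ms * float(np.exp(rng.normal(0, 0.07))),
            sigma_asc_ms=base.sigma_asc_ms * float(np.exp(rng.normal(0, 0.07))),
            sigma_desc_ms=base.sigma_desc_ms * float(np.exp(rng.normal(0, 0.07))),
            t_amplitude_uv=base.t_amplitude_uv * float(np.exp(rng.normal(0, 0.25))),
            t_tail_weight=float(np.clip(base.t_tail_weight + rng.normal(0, 0.015), 0.0, 0.15)),
        )
        mults = {
            d: float(np.exp(rng.normal(-0.5 * slope_cv**2, slope_cv))) for d in DRUGS
        }
        cfs = {d: float(np.exp(rng.normal(-0.5 * conc_cv**2, conc_cv))) for d in DRUGS}
        subjects.append(
            SubjectProfile(
                subject_id=f"S{i+1:02d}",
                sex="F" if i < design.n_female else "M",
                baseline_rr_s=rr,
                baseline_beat=beat,
                random_slopes=mults,
                conc_factors=cfs,
            )
        )
    return subjects


def simulate_trial(
    design: TrialDesign,
    pk_models: dict[str, PkModel] | None = None,
    effects: DrugEffectModel | None = None,
    noise_uv_rms: float = 12.0,
    rr_variability: float = 0.02,
    fs_hz: float = 500.0,
    duration_s: float = 10.0,
    slope_cv: float = 0.30,
    conc_cv: float = 0.15,
):
    """Yield waveform recordings for the full crossover (generator function).

    Every subject passes through every arm following a cyclic Latin-square
    sequence; each time-point (baseline plus the post-dose grid) yields
    ``replicates_per_timepoint`` 10-s recordings with per-beat ground truth.
    The whole trial is a pure function of (design, models, design.seed).
    """
    pk_models = pk_models or default_pk_models()
    effects = effects if effects is not None else calibrate_effects(pk_models)
    root = np.random.SeedSequence(design.seed)
    subj_seed, rec_seed = root.spawn(2)
    rng = np.random.default_rng(subj_seed)
    subjects = _make_subjects(design, rng, slope_cv, conc_cv)
    rec_seeds = iter(rec_seed.spawn(
        design.n_subjects
        * len(design.arms)
        * (1 + len(design.timepoint_hours))
        * design.replicates_per_timepoint
    ))

    timepoints = (0.0,) + tuple(design.timepoint_hours)
    for si, subj in enumerate(subjects):
        sequence = design.sequence_for(si)
        seq_label = "-".join(a[:3] for a in sequence)
        for period, arm in enumerate(sequence, start=1):
            for tp_h in timepoints:
                conc = {}
                for drug in ARM_DRUGS[arm]:
                    pop = float(simulate_pk(pk_models[drug], [tp_h])[0])
                    conc[drug] = pop * subj.conc_factors[drug]
                mult_conc = {
                    d: c * subj.random_slopes[d] for d, c in conc.items()
                }
                beat = apply_drug_effect(subj.baseline_beat, effects, mult_conc)
                for rep in range(1, design.replicates_per_timepoint + 1):
                    meta = {
                        "subject": subj.subject_id,
                        "sex": subj.sex,
                        "arm": arm,
                        "period": period,
                        "sequence": seq_label,
                        "timepoint_h": tp_h,
                        "timepoint": TIMEPOINT_LABELS.get(tp_h, f"t{tp_h:g}h"),
                        "replicate": rep,
                    }
                    for drug in DRUGS:
                        meta[f"conc_{drug}"] = conc.get(drug, 0.0)
                    yield synthesize_recording(
                        beat,
                        duration_s=duration_s,
                        rr_variability=rr_variability,
                        noise_uv_rms=noise_uv_rms,
                        seed=next(rec_seeds),
                        fs_hz=fs_hz,
                        metadata=meta,
                    )


# ---------------------------------------------------------------------------
# Biomarker-level trial generation (trial-scale statistical studies)
# ---------------------------------------------------------------------------


def default_biomarker_slopes(
    pk_models: dict[str, PkModel] | None = None,
) -> dict[str, dict[str, float]]:
    """Corrected-scale biomarker slope (units per ng/mL) per drug."""
    pk_models = pk_models or default_pk_models()
    out = {}
    for drug in DRUGS:
        cref = float(simulate_pk(pk_models[drug], [DRUG_REFERENCE_HOUR[drug]])[0])
        out[drug] = {m: DRUG_EFFECT_TARGETS[drug][m] / cref for m in BIOMARKERS}
    return out


def simulate_biomarker_trial(
    design: TrialDesign,
    pk_models: dict[str, PkModel] | None = None,
    slopes: dict[str, dict[str, float]] | None = None,
    measurement_sd: dict[str, float] | None = None,
    slope_cv: float = 0.30,
    conc_cv: float = 0.15,
    rr_within_sd: float = 0.04,
    period_effect_frac: float = 0.3,
    seed: int | np.random.SeedSequence | None = None,
):
    """Raw biomarker table for the full crossover, bypassing waveforms.

    Each biomarker is generated marginally on the heart-rate-corrected scale
    (subject baseline + linear concentration effects with lognormal
    per-drug sensitivity multipliers + period effects), then mapped to the
    raw scale through the correction exponents and per-replicate measurement
    scatter.  Population-mean placebo-corrected changes at each drug's
    reference concentration equal ``DRUG_EFFECT_TARGETS`` by construction.
    """
    import pandas as pd

    pk_models = pk_models or default_pk_models()
    slopes = slopes or default_biomarker_slopes(pk_models)
    noise = measurement_sd or MEASUREMENT_SD
    rng = np.random.default_rng(design.seed if seed is None else seed)

    subjects = []
    for i in range(design.n_subjects):
        hr = float(np.clip(rng.normal(*BASELINE_HR_BPM), 45.0, 95.0))
        base = {}
        for m in BIOMARKERS:
            val = rng.normal(BASELINE_MEAN[m], BASELINE_SD[m])
            base[m] = float(np.clip(val, 0.05 * BASELINE_MEAN[m], None))
        subjects.append(
            {
                "subject": f"S{i+1:02d}",
                "sex": "F" if i < design.n_female else "M",
                "rr0": 60.0 / hr,
                "base": base,
                "mult": {d: float(np.exp(rng.normal(-0.5 * slope_cv**2, slope_cv))) for d in DRUGS},
                "cf": {d: float(np.exp(rng.normal(-0.5 * conc_cv**2, conc_cv))) for d in DRUGS},
            }
        )

    period_eff = {
        (p, m): rng.normal(0.0, period_effect_frac * noise[RAW_NAME[m]])
        for p in range(1, design.periods + 1)
        for m in BIOMARKERS
    }

    timepoints = (0.0,) + tuple(design.timepoint_hours)
    rows = []
    for si, subj in enumerate(subjects):
        sequence = design.sequence_for(si)
        seq_label = "-".join(a[:3] for a in sequence)
        for period, arm in enumerate(sequence, start=1):
            for tp_h in timepoints:
                conc = {
                    drug: float(simulate_pk(pk_models[drug], [tp_h])[0]) * subj["cf"][drug]
                    for drug in ARM_DRUGS[arm]
                }
                for rep in range(1, design.replicates_per_timepoint + 1):
                    rr = subj["rr0"] * float(np.exp(rng.normal(0.0, rr_within_sd)))
                    row = {
                        "subject": subj["subject"],
                        "sex": subj["sex"],
                        "arm": arm,
                        "period": period,
                        "sequence": seq_label,
                        "timepoint_h": tp_h,
                        "timepoint": TIMEPOINT_LABELS.get(tp_h, f"t{tp_h:g}h"),
                        "replicate": rep,
                        "rr_s": rr,
                    }
                    for drug in DRUGS:
                        row[f"conc_{drug}"] = conc.get(drug, 0.0)
                    for m in BIOMARKERS:
                        v_c = subj["base"][m] + period_eff[(period, m)]
                        for drug, c in conc.items():
                            v_c += slopes[drug][m] * subj["mult"][drug] * c
                        alpha = CORRECTION_ALPHA.get(m, 0.0)
                        raw = v_c * rr**alpha
                        raw += rng.normal(0.0, noise[RAW_NAME[m]])
                        row[RAW_NAME[m]] = raw
                    rows.append(row)
    return pd.DataFrame(rows)


def simulate_alpha_baseline(
    alpha: float,
    n_subjects: int = 21,
    n_per_subject: int = 3,
    noise_sigma: float = 0.05,
    base_mean: float = 0.43,
    subject_sd: float = 0.05,
    rr_within_log_sd: float = 0.28,
    rr_between_log_sd: float = 0.08,
    seed: int | np.random.SeedSequence = 0,
    equal_alpha_by_sex: bool = True,
    alpha_female: float | None = None,
):
    """Baseline rows ``value = c_subject * rr^alpha * exp(noise)`` for
    correction-exponent estimation.

    The RR spread emulates ambulatory baseline sampling across a full day
    (sleep-to-active heart rates), which is what makes a population
    correction exponent identifiable from a small study.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        sex = "F" if i % 2 == 0 else "M"
        a = alpha if (equal_alpha_by_sex or sex == "M" or alpha_female is None) else alpha_female
        c = base_mean * float(np.exp(rng.normal(0.0, subject_sd)))
        rr0 = _REF_RR_S * float(np.exp(rng.normal(0.0, rr_between_log_sd)))
        for _ in range(n_per_subject):
            rr = rr0 * float(np.exp(rng.normal(0.0, rr_within_log_sd)))
            value = c * rr**a * float(np.exp(rng.normal(0.0, noise_sigma)))
            rows.append({"subject": f"S{i+1:02d}", "sex": sex, "value": value, "rr_s": rr})
    return pd.DataFrame(rows)
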