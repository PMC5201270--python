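"""Placebo-corrected change-from-baseline and exposure-response modelling.

The central estimand is the placebo-corrected change from baseline
("delta-delta"): for each active arm and post-dose time-point, the adjusted
mean of (change on treatment) minus (time-matched change on placebo) in the
crossover, from a linear mixed model with sequence, period, time, treatment
and treatment x time fixed effects and a subject random intercept.  Under a
balanced design the estimate reduces to the cell-means contrast, which
serves as the oracle in the tests.

Concentration-response uses a per-subject random intercept + slope linear
model; "signature" curves evaluate those models at 25% increments of the
population Cmax with delta-method confidence intervals.  Mitigation of a
hERG-blocker effect by a co-administered inward-current blocker is tested
with a paired t-test of observed combination responses against the
responses predicted from the hERG blocker's own concentration-response at
each subject's measured concentration, summarized with Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "DeltaDeltaEstimate",
    "ConcResponseModel",
    "SignaturePoint",
    "EffectSize",
    "changes_from_baseline",
    "placebo_corrected_rows",
    "delta_delta",
    "conc_response_fit",
    "predict_signature",
    "mitigation_test",
    "cohens_d",
]


@dataclass
class DeltaDeltaEstimate:
    arm: str
    timepoint: float
    biomarker: str
    estimate: float
    ci95_low: float
    ci95_high: float

    def __post_init__(self) -> None:
        if not self.ci95_low <= self.estimate <= self.ci95_high:
            raise ValueError("estimate must lie inside its confidence interval")


@dataclass
class ConcResponseModel:
    biomarker: str
    intercept: float
    slope: float  # units per ng/mL
    intercept_se: float
    slope_se: float
    intercept_slope_cov: float
    re_cov: np.ndarray | None  # 2x2 random intercept/slope covariance
    n_subjects: int


@dataclass
class SignaturePoint:
    cmax_fraction: float
    pred: float
    ci95_low: float
    ci95_high: float


@dataclass
class EffectSize:
    cohens_d: float
    label: str


# ---------------------------------------------------------------------------
# Change-from-baseline bookkeeping
# ---------------------------------------------------------------------------


def changes_from_baseline(
    table: pd.DataFrame,
    biomarkers: list[str],
    baseline_hour: float = 0.0,
) -> pd.DataFrame:
    """Per subject/arm/time-point change from the period-specific baseline.

    Replicate recordings within a time-point are aggregated by their median
    before differencing.  Returns one row per subject x arm x post-dose
    time-point with ``<biomarker>`` columns holding changes.
    """
    keys = ["subject", "arm", "period", "sequence", "timepoint_h"]
    keep = [c for c in table.columns if c.startswith("conc_")]
    agg = (
        table.groupby(keys, as_index=False)[biomarkers + keep].median(numeric_only=True)
    )
    base = agg[agg["timepoint_h"] == baseline_hour]
    if base.empty:
        raise ValueError(f"no baseline rows at t = {baseline_hour} h")
    base = base.set_index(["subject", "arm"])[biomarkers]
    post = agg[agg["timepoint_h"] != baseline_hour].copy()
    idx = pd.MultiIndex.from_frame(post[["subject", "arm"]])
    missing = ~idx.isin(base.index)
    if missing.any():
        raise ValueError("baseline row missing for some subject/period")
    for m in biomarkers:
        post[m] = post[m].to_numpy() - base[m].loc[idx].to_numpy()
    return post.reset_index(drop=True)


def placebo_corrected_rows(
    changes: pd.DataFrame, biomarkers: list[str], placebo_arm: str = "placebo"
) -> pd.DataFrame:
    """Subject-level, time-matched placebo-corrected changes (crossover)."""
    plc = changes[changes["arm"] == placebo_arm]
    if plc.empty:
        raise ValueError("placebo rows required for placebo correction")
    plc = plc.set_index(["subject", "timepoint_h"])[biomarkers]
    out = changes[changes["arm"] != placebo_arm].copy()
    idx = pd.MultiIndex.from_frame(out[["subject", "timepoint_h"]])
    keep = idx.isin(plc.index)
    out = out[keep].copy()
    idx = idx[keep]
    for m in biomarkers:
        out[m] = out[m].to_numpy() - plc[m].loc[idx].to_numpy()
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Delta-delta mixed model
# ---------------------------------------------------------------------------

_DD_FORMULA = (
    "value ~ C(sequence) + C(period) + C(timepoint_h) + C(arm) + C(arm):C(timepoint_h)"
)


def _contrast_vector(design_info, arm: str, timepoint: float, placebo_arm: str):
    """L = x(arm, t) - x(placebo, t); sequence/period covariates cancel."""
    from patsy import dmatrix

    probe = pd.DataFrame(
        {
            "sequence": ["__s__", "__s__"],
            "period": [1, 1],
            "timepoint_h": [timepoint, timepoint],
            "arm": [arm, placebo_arm],
        }
    )
    # patsy raises on unseen levels; map the probe onto observed levels
    probe["sequence"] = design_info.factor_infos[
        [f for f in design_info.factor_infos if "sequence" in f.name()][0]
    ].categories[0]
    probe["period"] = design_info.factor_infos[
        [f for f in design_info.factor_infos if "period" in f.name()][0]
    ].categories[0]
    x = np.asarray(dmatrix(design_info, probe, return_type="matrix"))
    return x[0] - x[1]


def delta_delta(
    changes: pd.DataFrame,
    biomarker: str,
    placebo_arm: str = "placebo",
) -> list[DeltaDeltaEstimate]:
    """Placebo-corrected adjusted mean change per active arm and time-point.

    ``changes`` holds one row per subject x arm x time-point with the change
    from baseline in ``biomarker`` (see :func:`changes_from_baseline`).
    """
    df = changes.rename(columns={biomarker: "value"})[
        ["subject", "arm", "period", "sequence", "timepoint_h", "value"]
    ].copy()
    if placebo_arm not in set(df["arm"]):
        raise ValueError("placebo arm missing from the change table")
    arms = [a for a in df["arm"].unique() if a != placebo_arm]
    if not arms:
        raise ValueError("no active arms present")

    ols = smf.ols(_DD_FORMULA, data=df).fit()
    design_info = ols.model.data.design_info
    if np.linalg.matrix_rank(ols.model.exog) < min(ols.model.exog.shape):
        pass  # aliased sequence/period levels are fine; contrasts cancel them
    noiseless = ols.ssr / max(ols.df_resid, 1) < 1e-18 * max(1.0, float(df["value"].var() or 1.0))

    params = cov = None
    if not noiseless:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mlm = smf.mixedlm(_DD_FORMULA, data=df, groups=df["subject"])
                res = mlm.fit(reml=True, method=["lbfgs", "powell"])
            k = len(res.fe_params)
            params = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[:k, :k]
        except Exception:
            params = None
    if params is None:
        params = np.asarray(ols.params)
        cov = np.asarray(ols.cov_params())
        if noiseless:
            cov = np.zeros_like(cov)

    out = []
    zcrit = stats.norm.ppf(0.975)
    for arm in arms:
        for tp in sorted(df.loc[df["arm"] == arm, "timepoint_h"].unique()):
            L = _contrast_vector(design_info, arm, tp, placebo_arm)
            est = float(L @ params)
            se = float(np.sqrt(max(L @ cov @ L, 0.0)))
            out.append(
                DeltaDeltaEstimate(
                    arm=arm,
                    timepoint=float(tp),
                    biomarker=biomarker,
                    estimate=est,
                    ci95_low=est - zcrit * se,
                    ci95_high=est + zcrit * se,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Concentration-response
# ---------------------------------------------------------------------------


def conc_response_fit(
    rows: pd.DataFrame, biomarker: str, conc_col: str
) -> ConcResponseModel:
    """Random intercept + slope model of change vs plasma concentration.

    ``rows`` holds subject-level placebo-corrected changes for one drug arm
    with that drug's measured concentrations.  Under balance with no noise
    the population slope equals the mean of per-subject least-squares
    slopes, which is the oracle used in the tests.
    """
    df = rows.rename(columns={biomarker: "value", conc_col: "conc"})[
        ["subject", "value", "conc"]
    ].dropna()
    if df["subject"].nunique() < 5:
        raise ValueError("need at least 5 subjects for a random-slope model")
    per_subj_levels = df.groupby("subject")["conc"].nunique()
    if (per_subj_levels < 2).any():
        raise ValueError("every subject needs at least 2 concentration levels")
    if df["conc"].var() == 0:
        raise ValueError("all concentrations identical")

    # two-stage oracle-compatible fallback values
    def subj_slope(sub):
        return np.polyfit(sub["conc"], sub["value"], 1)

    fits = np.array([subj_slope(sub) for _, sub in df.groupby("subject")])
    mean_slope, mean_int = float(np.mean(fits[:, 0])), float(np.mean(fits[:, 1]))
    resid = []
    for (_, sub), (sl, ic) in zip(df.groupby("subject"), fits):
        resid.extend(sub["value"] - (ic + sl * sub["conc"]))
    noiseless = float(np.var(resid)) < 1e-18 * max(1.0, float(df["value"].var() or 1.0))

    if not noiseless:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mlm = smf.mixedlm("value ~ conc", data=df, groups=df["subject"], re_formula="~conc")
                res = mlm.fit(reml=True, method=["lbfgs", "powell"])
            cov_fe = np.asarray(res.cov_params())[:2, :2]
            return ConcResponseModel(
                biomarker=biomarker,
                intercept=float(res.fe_params["Intercept"]),
                slope=float(res.fe_params["conc"]),
                intercept_se=float(res.bse_fe["Intercept"]),
                slope_se=float(res.bse_fe["conc"]),
                intercept_slope_cov=float(cov_fe[0, 1]),
                re_cov=np.asarray(res.cov_re),
                n_subjects=int(df["subject"].nunique()),
            )
        except Exception:
            pass
    n = df["subject"].nunique()
    int_se = float(np.std(fits[:, 1], ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    slope_se = float(np.std(fits[:, 0], ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ConcResponseModel(
        biomarker=biomarker,
        intercept=mean_int,
        slope=mean_slope,
        intercept_se=int_se,
        slope_se=slope_se,
        intercept_slope_cov=0.0,
        re_cov=np.cov(fits.T) if n > 1 else None,
        n_subjects=int(n),
    )


def predict_signature(
    model: ConcResponseModel,
    cmax: float,
    fractions: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00),
) -> list[SignaturePoint]:
    """Predicted change and delta-method 95% CI at fractions of Cmax."""
    if cmax <= 0:
        raise ValueError("cmax must be positive")
    zcrit = stats.norm.ppf(0.975)
    out = []
    for f in sorted(fractions):
        c = f * cmax
        pred = model.intercept + model.slope * c
        var = (
            model.intercept_se**2
            + c**2 * model.slope_se**2
            + 2 * c * model.intercept_slope_cov
        )
        se = float(np.sqrt(max(var, 0.0)))
        out.append(SignaturePoint(f, float(pred), pred - zcrit * se, pred + zcrit * se))
    return out


def mitigation_test(
    observed: np.ndarray, model: ConcResponseModel, concentrations: np.ndarray
) -> dict[str, float]:
    """Paired t-test of observed combination responses against predictions
    from the single-drug concentration-response at each subject's measured
    concentration.  Two-sided p; a significant negative mean difference
    indicates mitigation of the single-drug effect."""
    observed = np.asarray(observed, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if observed.shape != conc.shape:
        raise ValueError("observed and concentrations must be paired per subject")
    if observed.size < 3:
        raise ValueError("need at least 3 pairs")
    predicted = model.intercept + model.slope * conc
    diff = observed - predicted
    if np.allclose(diff, 0.0):
        return {"mean_difference": 0.0, "p_value": 1.0, "n": observed.size}
    t_res = stats.ttest_rel(observed, predicted)
    return {
        "mean_difference": float(np.mean(diff)),
        "p_value": float(t_res.pvalue),
        "n": observed.size,
    }


_D_LABELS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


def cohens_d(x, y, paired: bool = True) -> EffectSize:
    """Cohen's d with the conventional magnitude labels.

    Paired: mean difference over the SD of the differences.  Unpaired: mean
    difference over the pooled SD.  Labels switch at the printed bounds
    (|d| = 0.5 is "medium").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must align")
        diff = x - y
        sd = float(np.std(diff, ddof=1))
        if sd == 0:
            if np.allclose(diff, 0):
                return EffectSize(0.0, "negligible")
            raise ValueError("zero variance with nonzero difference")
        d = float(np.mean(diff) / sd)
    else:
        nx, ny = x.size, y.size
        pooled = np.sqrt(
            ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
        )
        if pooled == 0:
            if np.mean(x) == np.mean(y):
                return EffectSize(0.0, "negligible")
            raise ValueError("zero variance with nonzero difference")
        d = float((np.mean(x) - np.mean(y)) / pooled)
    label = "large"
    for bound, name in _D_LABELS:
        if abs(d) < bound:
            label = name
            break
    return EffectSize(d, label)
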