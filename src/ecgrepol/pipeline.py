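"""End-to-end pipeline driver: simulate -> delineate -> morphology ->
correct -> exposure-response -> classify, with persisted intermediates and
a reproducibility manifest.

All randomness flows from one root seed that is split per stage, so a rerun
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cl
from . import exposure as ex
from . import io as eio
from . import morphology as mph
from . import ratecorrect as rc
from . import synth
from .delineate import DelineationConfig, DelineationError, delineate_recording, measure_intervals

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "measure_recording"]

log = logging.getLogger("ecgrepol")

__version__ = "0.1.0"

#: time-points pooled per arm for classification (hERG blockers peak when
#: their concentrations do: morning/afternoon for the single-morning-dose
#: drug, afternoon/evening for the three-dose regimens)
CLASSIFY_TIMEPOINTS = {
    "dofetilide": (6.5, 13.0),
    "moxifloxacin": (2.0, 6.5),
    "mexiletine+dofetilide": (6.5, 13.0),
    "lidocaine+dofetilide": (6.5, 13.0),
}
ARM_CLASS = {
    "dofetilide": cl.NEGATIVE_CLASS,
    "moxifloxacin": cl.NEGATIVE_CLASS,
    "mexiletine+dofetilide": cl.POSITIVE_CLASS,
    "lidocaine+dofetilide": cl.POSITIVE_CLASS,
}

CORRECTED_BIOMARKERS = [
    "qtc_ms",
    "jtpeakc_ms",
    "tpeaktend_ms",
    "flatnessc_du",
    "asymmetry_du",
    "erd30_ms",
    "lrd30_ms",
    "amplitudec_uv",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with units in the field names."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    mode: str = "waveform"  # "waveform" (full ECG synthesis) or "biomarker"
    # design
    n_subjects: int = 21
    n_female: int = 8
    arms: tuple[str, ...] = synth.ARMS
    timepoint_hours: tuple[float, ...] = (2.0, 6.5, 13.0)
    replicates_per_timepoint: int = 3
    # waveform synthesis / measurement
    fs_hz: float = 500.0
    resample_fs_hz: float = 1000.0
    duration_s: float = 10.0
    noise_uv_rms: float = 12.0
    rr_variability: float = 0.02
    write_waveforms: bool = False
    # statistics
    n_bootstrap: int = 2000
    cv_folds: int = 10
    tree_jtpeakc_threshold_ms: float = 9.0
    tree_qtc_threshold_ms: float = 29.0
    delineation: DelineationConfig = field(default_factory=DelineationConfig)
    morphology: mph.MorphologyConfig = field(default_factory=mph.MorphologyConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = list(self.arms)
        d["timepoint_hours"] = list(self.timepoint_hours)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "delineation" in d and isinstance(d["delineation"], dict):
            d["delineation"] = DelineationConfig(**d["delineation"])
        if "morphology" in d and isinstance(d["morphology"], dict):
            d["morphology"] = mph.MorphologyConfig(**d["morphology"])
        if "arms" in d:
            d["arms"] = tuple(d["arms"])
        if "timepoint_hours" in d:
            d["timepoint_hours"] = tuple(d["timepoint_hours"])
        return cls(**d)

    def design(self) -> synth.TrialDesign:
        return synth.TrialDesign(
            n_subjects=self.n_subjects,
            n_female=self.n_female,
            arms=self.arms,
            timepoint_hours=self.timepoint_hours,
            replicates_per_timepoint=self.replicates_per_timepoint,
            seed=self.seed,
        )


def _estimate_baseline_uv(beat, onset_ms: float) -> float:
    vm = beat.vm()
    ms = 1000.0 / beat.fs_hz
    a = max(0, int(round((onset_ms - 60.0) / ms)))
    b = max(1, int(round((onset_ms - 10.0) / ms)))
    return float(np.median(vm[a:b])) if b > a else 0.0


def measure_recording(
    rec,
    dcfg: DelineationConfig | None = None,
    mcfg: mph.MorphologyConfig | None = None,
) -> dict:
    """Delineate one recording and compute all eight biomarkers (raw)."""
    beat, fid = delineate_recording(rec, dcfg)
    intervals = measure_intervals(fid)
    baseline = _estimate_baseline_uv(beat, fid.qrs_onset_ms)
    morph = mph.compute_morphology(beat, fid, mcfg, baseline_uv=baseline)
    row = dict(rec.metadata)
    row.update(
        rr_s=intervals["rr_s"],
        qt_ms=intervals["qt_ms"],
        jtpeak_ms=intervals["jtpeak_ms"],
        tpeaktend_ms=intervals["tpeaktend_ms"],
        flatness_du=morph.flatness_du,
        asymmetry_du=morph.asymmetry_du,
        erd30_ms=morph.erd30_ms,
        lrd30_ms=morph.lrd30_ms,
        amplitude_uv=morph.amplitude_uv,
        vg_uvs=morph.vg_uvs if morph.vg_uvs is not None else np.nan,
        quality_flag="ok",
    )
    return row


def _classification_table(corrected: pd.DataFrame) -> pd.DataFrame:
    changes = ex.changes_from_baseline(corrected, CORRECTED_BIOMARKERS)
    rows = ex.placebo_corrected_rows(changes, CORRECTED_BIOMARKERS)
    keep = pd.Series(False, index=rows.index)
    for arm, tps in CLASSIFY_TIMEPOINTS.items():
        keep |= (rows["arm"] == arm) & rows["timepoint_h"].isin(tps)
    rows = rows[keep].copy()
    rows["label"] = rows["arm"].map(ARM_CLASS)
    return rows.dropna(subset=["label"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, persist intermediates under ``config.out_dir`` and
    return the manifest (also written as ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()
    counts: dict[str, int] = {}
    exclusions: dict[str, int] = {}

    # --- stage 1+2: simulate and measure -----------------------------------
    if config.mode == "waveform":
        log.info("simulate+measure: synthesizing and delineating recordings")
        rows = []
        n_rec = 0
        failures = 0
        wave_dir = out / "recordings"
        if config.write_waveforms:
            wave_dir.mkdir(exist_ok=True)
        for rec in synth.simulate_trial(
            design,
            noise_uv_rms=config.noise_uv_rms,
            rr_variability=config.rr_variability,
            fs_hz=config.fs_hz,
            duration_s=config.duration_s,
        ):
            n_rec += 1
            if config.write_waveforms:
                m = rec.metadata
                name = f"{m['subject']}_{m['arm']}_{m['timepoint_h']:g}h_r{m['replicate']}.csv"
                eio.write_waveform(rec, wave_dir / name)
            try:
                rows.append(
                    measure_recording(rec, config.delineation, config.morphology)
                )
            except DelineationError as err:
                failures += 1
                row = dict(rec.metadata)
                row["quality_flag"] = str(err)
                rows.append(row)
        measured = pd.DataFrame(rows)
        counts["recordings"] = n_rec
        exclusions["unmeasurable_recordings"] = failures
        measured = measured[measured["quality_flag"] == "ok"].drop(columns="quality_flag")
    elif config.mode == "biomarker":
        log.info("simulate: drawing biomarker-level trial")
        measured = synth.simulate_biomarker_trial(design)
        counts["recordings"] = len(measured)
        exclusions["unmeasurable_recordings"] = 0
    else:
        raise PipelineError("simulate", f"unknown mode {config.mode!r}")
    if measured.empty:
        raise PipelineError("measure", "no measurable recordings")
    eio.write_table(measured, out / "biomarkers.csv")
    counts["biomarker_rows"] = len(measured)

    # --- stage 3: heart-rate correction ------------------------------------
    log.info("correct: applying heart-rate correction")
    spec = rc.default_spec()
    corrected = rc.correct_table(measured, spec)
    eio.write_table(corrected, out / "corrected.csv")
    eio.write_config({"corrections": spec.to_dict()}, out / "correction_spec.yaml")
    counts["corrected_rows"] = len(corrected)

    # --- stage 4: placebo-corrected changes and delta-delta ----------------
    log.info("ddelta: fitting crossover mixed models")
    biomarkers = [b for b in CORRECTED_BIOMARKERS if b in corrected.columns]
    changes = ex.changes_from_baseline(corrected, biomarkers)
    eio.write_table(changes, out / "changes.csv")
    dd_rows = []
    for b in biomarkers:
        try:
            for est in ex.delta_delta(changes, b):
                dd_rows.append(
                    {
                        "arm": est.arm,
                        "timepoint_h": est.timepoint,
                        "biomarker": b,
                        "estimate": est.estimate,
                        "ci95_low": est.ci95_low,
                        "ci95_high": est.ci95_high,
                    }
                )
        except ValueError as err:
            raise PipelineError("ddelta", f"{b}: {err}") from err
    ddelta = pd.DataFrame(dd_rows)
    eio.write_table(ddelta, out / "ddelta.csv")
    counts["ddelta_estimates"] = len(ddelta)

    # --- stage 5: classification -------------------------------------------
    log.info("classify: ROC and decision-tree analysis")
    feats = _classification_table(corrected)
    if feats.empty or feats["label"].nunique() < 2:
        raise PipelineError(
            "classify", "need both hERG and multichannel arms for classification"
        )
    eio.write_table(feats, out / "classification_rows.csv")
    counts["classification_rows"] = len(feats)
    seed_seq = np.random.SeedSequence(config.seed).spawn(3)
    labels = feats["label"].to_numpy()

    roc_models = {
        "jtpeakc": ["jtpeakc_ms"],
        "qtc": ["qtc_ms"],
        "flatness": ["flatnessc_du"],
        "qtc+jtpeakc": ["qtc_ms", "jtpeakc_ms"],
    }
    roc_out = {}
    scores = {}
    for name, cols in roc_models.items():
        X = feats[cols].to_numpy()
        model = cl.logistic_fit(X, labels, tuple(cols))
        s = model.predict_proba(X)
        scores[name] = s
        res = cl.roc_auc(s, labels, tuple(cols))
        ci = cl.auc_bootstrap_ci(s, labels, config.n_bootstrap, seed=seed_seq[0])
        roc_out[name] = {
            "auc": res.auc,
            "ci95": list(ci),
            "sensitivity": res.best_sensitivity,
            "specificity": res.best_specificity,
            "features": list(cols),
        }
    delong = {
        "jtpeakc_vs_qtc": cl.delong_test(scores["jtpeakc"], scores["qtc"], labels),
        "jtpeakc_vs_qtc+jtpeakc": cl.delong_test(
            scores["jtpeakc"], scores["qtc+jtpeakc"], labels
        ),
    }

    rule = cl.TreeRule(config.tree_jtpeakc_threshold_ms, config.tree_qtc_threshold_ms)
    preds = cl.tree_classify(
        feats["jtpeakc_ms"].to_numpy(), feats["qtc_ms"].to_numpy(), rule
    )
    tree_eval = cl.evaluate_classifier(
        preds, labels, n_boot=config.n_bootstrap, seed=seed_seq[1]
    )
    learned = None
    y_counts = feats["label"].value_counts()
    if y_counts.min() >= config.cv_folds:
        tree = cl.learn_tree(
            feats[["jtpeakc_ms", "qtc_ms"]].to_numpy(),
            labels,
            feature_names=("jtpeakc_ms", "qtc_ms"),
            folds=config.cv_folds,
            seed=config.seed,
        )
        learned_rule = tree.as_rule()
        learned = {
            "cv": tree.cv_metrics,
            "rule": None
            if learned_rule is None
            else {
                "jtpeakc_threshold_ms": learned_rule.jtpeakc_threshold_ms,
                "qtc_threshold_ms": learned_rule.qtc_threshold_ms,
            },
        }

    results = {
        "roc": roc_out,
        "delong": delong,
        "fixed_rule": {
            "thresholds": {
                "jtpeakc_ms": rule.jtpeakc_threshold_ms,
                "qtc_ms": rule.qtc_threshold_ms,
            },
            "evaluation": tree_eval,
        },
        "learned_tree": learned,
    }
    eio.write_json(results, out / "classification.json")

    # --- manifest -----------------------------------------------------------
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # the scientific config excludes paths
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "counts": counts,
        "exclusions": exclusions,
    }
    eio.write_json(manifest, out / "manifest.json")
    eio.write_config(cfg_dict, out / "config.yaml")
    return manifest
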