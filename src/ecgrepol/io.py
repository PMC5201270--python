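"""Delimited-text formats for waveforms, tables and configuration.

Dialect: comma separator, dot decimal, header row, UTF-8.  Units are
embedded in column names (``_uv``, ``_s``, ``_ms``) to prevent silent unit
drift.  Each waveform CSV (column 1 ``time_s``, one ``<lead>_uv`` column
per lead) is paired with a ``.meta.json`` sidecar carrying the sampling
rate and recording metadata, and optionally a ``.truth.csv`` with per-beat
ground-truth sample positions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BeatTruth, EcgRecording

__all__ = [
    "write_waveform",
    "read_waveform",
    "write_table",
    "read_table",
    "write_config",
    "read_config",
    "write_json",
]


class FormatError(ValueError):
    """Malformed waveform/table input."""


def write_waveform(rec: EcgRecording, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs_hz
    df = pd.DataFrame({"time_s": t})
    for name, row in zip(rec.lead_names, rec.samples):
        df[f"{name}_uv"] = row
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "fs_hz": rec.fs_hz,
        "lead_names": list(rec.lead_names),
        "metadata": rec.metadata,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if rec.truth:
        rows = [
            {
                "beat_index": t_.beat_index,
                "qrs_onset": t_.qrs_onset,
                "qrs_offset": t_.qrs_offset,
                "t_peak": t_.t_peak,
                "t_end": t_.t_end,
                "r_peak": t_.r_peak,
                "rr_s": t_.rr_s,
            }
            for t_ in rec.truth
        ]
        pd.DataFrame(rows).to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def read_waveform(path: str | Path) -> EcgRecording:
    path = Path(path)
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path.name} (field fs_hz)")
    meta = json.loads(meta_path.read_text())
    if "fs_hz" not in meta:
        raise FormatError("metadata missing required field 'fs_hz'")
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("waveform file missing 'time_s' column (seconds)")
    lead_cols = [c for c in df.columns if c.endswith("_uv")]
    if not lead_cols:
        raise FormatError("no lead columns ending in '_uv' (microvolts) found")
    samples = df[lead_cols].to_numpy(dtype=float).T
    truth = None
    truth_path = path.with_suffix(".truth.csv")
    if truth_path.exists():
        tdf = pd.read_csv(truth_path)
        truth = [
            BeatTruth(
                beat_index=int(r.beat_index),
                qrs_onset=int(r.qrs_onset),
                qrs_offset=int(r.qrs_offset),
                t_peak=int(r.t_peak),
                t_end=int(r.t_end),
                r_peak=int(r.r_peak),
                rr_s=float(r.rr_s),
            )
            for r in tdf.itertuples()
        ]
    return EcgRecording(
        samples=samples,
        fs_hz=float(meta["fs_hz"]),
        lead_names=tuple(c[:-3] for c in lead_cols),
        metadata=meta.get("metadata", {}),
        truth=truth,
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise FormatError(f"malformed table {path}: {err}") from err


def write_config(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))
    return path


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
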