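"""Readers and writers for the plain-text interchange formats.

Expression matrices travel as TSV (probes x samples, header row of sample
ids) with a YAML sidecar mapping each sample to its condition; cluster sets
as 5-column BED (chrom, start, end, name, count; 0-based half-open);
isotopomer time courses and dose-response curves as CSV.  Reports are JSON
with the full parameter set embedded for replayability.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .chip import ClusterSet
from .ti import ExpressionMatrix

__all__ = [
    "write_expression", "read_expression",
    "write_bed", "read_bed",
    "write_mida_csv", "read_mida_csv",
    "read_dose_response_csv",
    "write_report",
]


def write_expression(matrix: ExpressionMatrix, matrix_path, conditions_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
    cond = {s: dict(row) for s, row in matrix.conditions.iterrows()}
    Path(conditions_path).write_text(yaml.safe_dump(cond, sort_keys=True))


def read_expression(matrix_path, conditions_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    cond = yaml.safe_load(Path(conditions_path).read_text())
    conditions = pd.DataFrame.from_dict(cond, orient="index")
    conditions.index.name = "sample"
    return ExpressionMatrix(values, conditions)


def write_bed(clusters: ClusterSet, path) -> None:
    clusters.frame[["chrom", "start", "end", "name", "count"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path, label: str = "") -> ClusterSet:
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "name", "count"])
    return ClusterSet(frame, label=label or Path(path).stem)


def write_mida_csv(timecourse: pd.DataFrame, path) -> None:
    timecourse.to_csv(path, index=False)


def read_mida_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    req = {"analyte", "time", "mass_index", "fraction"}
    if not req.issubset(df.columns):
        raise ValueError(f"MIDA CSV missing columns {sorted(req - set(df.columns))}")
    return df


def read_dose_response_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"concentration", "response"}.issubset(df.columns):
        raise ValueError("dose-response CSV needs 'concentration' and 'response'")
    return df


def write_report(path, stage: str, parameters: dict, results: dict) -> dict:
    """Versioned JSON report embedding the exact parameters used."""
    from . import __version__

    report = {
        "tool": "sgrmkit",
        "version": __version__,
        "stage": stage,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameters": parameters,
        "results": results,
    }
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable) + "\n")
    return report


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
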