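"""Plain-text table IO for every pipeline stage.

Everything is TSV/CSV/JSON so any language can interoperate: biomarkers as
long-format TSV, per-subject ROI time series as TSV with a node-name
header, confounds as TSV with BIDS-style column names (``trans_x ..
rot_z, wm, csf``), demographics as TSV, plus JSON sidecars recording
generator parameters and seeds.  Readers validate schemas and report the
offending line for malformed rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Demographics, TimeSeriesBundle

CONFOUND_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z", "wm", "csf"]

_BIOMARKER_COLUMNS = ["subject_id", "metal", "medium", "value", "lod", "censored"]


def _check_columns(df: pd.DataFrame, expected: list[str], path: Path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} (header line 1)")


def write_biomarkers(panel: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    _check_columns(panel, _BIOMARKER_COLUMNS, path)
    panel[_BIOMARKER_COLUMNS].to_csv(path, sep="\t", index=False)


def read_biomarkers(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, _BIOMARKER_COLUMNS, path)
    for line_offset, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            float(row["value"])
            float(row["lod"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: malformed numeric value at line {line_offset}")
    df["censored"] = df["censored"].astype(bool)
    dup = df.duplicated(subset=["subject_id", "metal", "medium"])
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise ValueError(f"{path}: duplicate subject/metal/medium record at line {line}")
    return df


def write_demographics(demographics: list[Demographics], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [d.subject_id for d in demographics],
            "age": [d.age for d in demographics],
            "sex": [d.sex for d in demographics],
        }
    ).to_csv(path, sep="\t", index=False)


def read_demographics(path: str | Path) -> list[Demographics]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["subject_id", "age", "sex"], path)
    if df["subject_id"].duplicated().any():
        line = int(np.flatnonzero(df["subject_id"].duplicated())[0]) + 2
        raise ValueError(f"{path}: duplicate subject_id at line {line}")
    return [
        Demographics(subject_id=str(r.subject_id), age=float(r.age), sex=int(r.sex))
        for r in df.itertuples()
    ]


def write_timeseries_bundle(bundle: TimeSeriesBundle, out_dir: str | Path, node_names: list[str] | None = None) -> None:
    """One ``<subject>_timeseries.tsv`` + ``<subject>_confounds.tsv`` pair."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_nodes = bundle.Y.shape[1]
    names = node_names or [f"node{i:03d}" for i in range(n_nodes)]
    if len(names) != n_nodes:
        raise ValueError("node_names length mismatch")
    pd.DataFrame(bundle.Y, columns=names).to_csv(
        out_dir / f"{bundle.subject_id}_timeseries.tsv", sep="\t", index=False
    )
    conf = pd.DataFrame(
        np.column_stack([bundle.motion, bundle.wm, bundle.csf]), columns=CONFOUND_COLUMNS
    )
    conf.to_csv(out_dir / f"{bundle.subject_id}_confounds.tsv", sep="\t", index=False)


def read_timeseries_bundle(subject_id: str, in_dir: str | Path, tr: float = 1.0) -> TimeSeriesBundle:
    in_dir = Path(in_dir)
    ts_path = in_dir / f"{subject_id}_timeseries.tsv"
    cf_path = in_dir / f"{subject_id}_confounds.tsv"
    Y = pd.read_csv(ts_path, sep="\t")
    conf = pd.read_csv(cf_path, sep="\t")
    _check_columns(conf, CONFOUND_COLUMNS, cf_path)
    if Y.isna().any().any():
        line = int(np.flatnonzero(Y.isna().any(axis=1))[0]) + 2
        raise ValueError(f"{ts_path}: missing value at line {line}")
    return TimeSeriesBundle(
        subject_id=subject_id,
        Y=Y.to_numpy(dtype=float),
        motion=conf[CONFOUND_COLUMNS[:6]].to_numpy(dtype=float),
        wm=conf["wm"].to_numpy(dtype=float),
        csf=conf["csf"].to_numpy(dtype=float),
        tr=tr,
    )


def node_names_for(subject_id: str, in_dir: str | Path) -> list[str]:
    header = pd.read_csv(Path(in_dir) / f"{subject_id}_timeseries.tsv", sep="\t", nrows=0)
    return list(header.columns)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
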