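"""LOD handling, descriptive statistics, and the exposure feature matrix.

Concentrations below the limit of detection are replaced by LOD/sqrt(2),
the standard single-imputation for left-censored log-normal biomarkers.
Descriptive statistics are geometric (GM/GSD) because the concentrations
are log-normal.  The model's feature matrix is the wide subject x 36 table
with medium-letter + metal-symbol column names (``UPb`` = urinary lead,
``BZn`` = blood zinc, ...); subjects missing any cell are excluded
(complete-case rule).

Features enter the predictive model as raw (substituted) concentrations:
tree ensembles are invariant to monotone transforms, so a log transform
would change nothing downstream except the beeswarm x-axis.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .reference import METALS, MEDIA, MEDIUM_LETTER

logger = logging.getLogger(__name__)

__all__ = [
    "feature_name",
    "feature_columns",
    "substitute_lod",
    "apply_lod_substitution",
    "geometric_stats",
    "correlation_table",
    "assemble_feature_matrix",
]

#: Canonical column order: media in panel-table order, metals within medium.
_MEDIA_ORDER = ("saliva", "hair", "fingernails", "toenails", "urine", "blood")
_METAL_ORDER = ("Mn", "Pb", "Cr", "Cu", "Ni", "Zn")


def feature_name(metal: str, medium: str) -> str:
    """Column label for one cell, e.g. ('Pb', 'urine') -> 'UPb'."""
    if metal not in METALS:
        raise ValueError(f"unknown metal {metal!r}")
    if medium not in MEDIA:
        raise ValueError(f"unknown medium {medium!r}")
    return MEDIUM_LETTER[medium] + metal


def feature_columns() -> list[str]:
    """The 36 feature labels in canonical order."""
    return [feature_name(metal, medium) for medium in _MEDIA_ORDER for metal in _METAL_ORDER]


def substitute_lod(value, lod):
    """Replace values strictly below the LOD with LOD/sqrt(2).

    Scalar or array-valued; values equal to the LOD are kept unchanged.
    """
    value = np.asarray(value, dtype=float)
    lod = np.asarray(lod, dtype=float)
    if np.any(value < 0):
        raise ValueError("negative concentration")
    if np.any(lod < 0):
        raise ValueError("negative LOD")
    out = np.where(value < lod, lod / math.sqrt(2.0), value)
    return float(out) if out.ndim == 0 else out


def apply_lod_substitution(panel: pd.DataFrame) -> pd.DataFrame:
    """LOD-substitute the ``value`` column of a long-format panel."""
    out = panel.copy()
    out["value"] = substitute_lod(out["value"].to_numpy(), out["lod"].to_numpy())
    return out


def geometric_stats(values) -> tuple[float, float]:
    """Geometric mean and geometric standard deviation.

    GM = exp(mean(ln v)); GSD = exp(sd(ln v)) with the sample (n-1)
    standard deviation.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(v <= 0):
        raise ValueError("geometric statistics require positive values")
    logs = np.log(v)
    return float(np.exp(logs.mean())), float(np.exp(logs.std(ddof=1)))


def correlation_table(panel_or_features: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """36 x 36 correlation matrix between exposure features.

    Accepts either a long-format panel (pivoted internally) or an already
    wide feature matrix.  ``method`` is ``pearson`` or ``spearman``
    (average-rank ties).  Constant columns produce NaN entries with a
    warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if {"metal", "medium", "value"}.issubset(panel_or_features.columns):
        wide = assemble_feature_matrix(panel_or_features)
    else:
        wide = panel_or_features
    constant = [c for c in wide.columns if wide[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant column(s) {constant}: correlation undefined (NaN)")
    corr = wide.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def assemble_feature_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long panel into the subject x 36 feature matrix.

    Requires LOD substitution to have been applied already.  Subjects with
    any missing cell are dropped (the count is logged); duplicate
    subject x metal x medium records are rejected.  Rows are indexed by
    ``subject_id`` and sorted; columns follow :func:`feature_columns`.
    """
    required = {"subject_id", "metal", "medium", "value"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    dup = panel.duplicated(subset=["subject_id", "metal", "medium"])
    if dup.any():
        bad = panel.loc[dup, ["subject_id", "metal", "medium"]].iloc[0].tolist()
        raise ValueError(f"duplicate record for subject/metal/medium {bad}")
    labeled = panel.assign(
        feature=[feature_name(m, md) for m, md in zip(panel["metal"], panel["medium"])]
    )
    wide = labeled.pivot(index="subject_id", columns="feature", values="value")
    cols = feature_columns()
    wide = wide.reindex(columns=cols)
    complete = wide.dropna()
    n_dropped = wide.shape[0] - complete.shape[0]
    if n_dropped:
        logger.info(
            "complete-case rule: dropped %d of %d subjects with missing biomarkers",
            n_dropped,
            wide.shape[0],
        )
    return complete.sort_index()
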