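"""Functional connectivity graphs and global efficiency.

Conditioned ROI time series become a Pearson correlation matrix; the
strongest positive correlations are kept at a fixed edge density to form a
binary undirected graph; global efficiency (GE) summarises how efficiently
the graph integrates: the mean over ordered node pairs of the inverse
shortest-path length (hop counts), 1 for a complete graph, 0 for an empty
one, with disconnected pairs contributing 0.

Cohort-level post-processing mirrors the analysis convention: GE is min-max
scaled to [0, 1] across subjects and then adjusted for age and biological
sex as standardized OLS residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .synthetic import Demographics

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "pearson_matrix",
    "binarize_proportional",
    "shortest_paths",
    "global_efficiency",
    "scale_and_adjust",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with node labels."""

    C: np.ndarray
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("C must have unit diagonal")
        if np.nanmax(np.abs(C)) > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")
        self.C = C
        if not self.node_names:
            self.node_names = [f"node{i:03d}" for i in range(C.shape[0])]
        if len(self.node_names) != C.shape[0]:
            raise ValueError("node_names length mismatch")


@dataclass
class BinaryGraph:
    """Unweighted undirected adjacency at a given edge density."""

    A: np.ndarray
    density: float

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.A = A.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.A.sum() // 2)


def pearson_matrix(Y: np.ndarray, node_names: list[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlations between all column pairs of a T x N matrix."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (time x nodes)")
    T, N = Y.shape
    if T < 3:
        raise ValueError("need at least 3 time points")
    names = node_names or [f"node{i:03d}" for i in range(N)]
    sd = Y.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for node(s): {bad}")
    C = np.corrcoef(Y, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return ConnectivityMatrix(C=C, node_names=names)


def binarize_proportional(conn: ConnectivityMatrix | np.ndarray, density: float) -> BinaryGraph:
    """Keep the strongest positive correlations at a fixed edge density.

    The top ``round(density * N(N-1)/2)`` edges by correlation value are
    retained; ties break deterministically by (larger r, smaller i, smaller
    j). Negative or zero correlations are never retained, so if fewer
    positive edges exist than the target count the graph is sparser than
    requested (with a warning).
    """
    C = conn.C if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, dtype=float)
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    N = C.shape[0]
    n_possible = N * (N - 1) // 2
    k = round(density * n_possible)
    if k == 0:
        raise ValueError(f"density {density} retains zero edges for N={N}")
    iu, ju = np.triu_indices(N, k=1)
    r = C[iu, ju]
    pos = r > 0
    if not np.any(pos):
        raise ValueError("no positive correlations: nothing to retain")
    order = np.lexsort((ju[pos], iu[pos], -r[pos]))
    n_keep = min(k, int(pos.sum()))
    if n_keep < k:
        warnings.warn(
            f"only {int(pos.sum())} positive correlations available; "
            f"graph density below requested {density}"
        )
    sel = np.flatnonzero(pos)[order[:n_keep]]
    A = np.zeros((N, N), dtype=np.int8)
    A[iu[sel], ju[sel]] = 1
    A += A.T
    return BinaryGraph(A=A, density=density)


def shortest_paths(graph: BinaryGraph | np.ndarray) -> np.ndarray:
    """Hop-count matrix by breadth-first search; inf for disconnected pairs."""
    A = graph.A if isinstance(graph, BinaryGraph) else np.asarray(graph)
    D = _csgraph_shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)
    return D


def global_efficiency(graph: BinaryGraph | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Equivalently the average over nodes of nodal efficiency
    ``E_i = (1/(N-1)) * sum_{j != i} 1/d_ij`` with ``1/inf = 0``.
    """
    A = graph.A if isinstance(graph, BinaryGraph) else np.asarray(graph)
    N = A.shape[0]
    if N < 2:
        raise ValueError("need at least 2 nodes")
    D = shortest_paths(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(D)] = 0.0
    return float(inv.sum() / (N * (N - 1)))


def scale_and_adjust(
    ge: np.ndarray | list[float],
    demographics: list[Demographics],
    scale_mode: str = "minmax",
) -> pd.DataFrame:
    """Cohort-level scaling and age/sex adjustment of global efficiency.

    ``ge_scaled`` maps the cohort to [0, 1] (``minmax``; the alternative
    ``max`` divides by the cohort maximum only).  ``ge_adj`` is the
    standardized residual (mean 0, sd 1, sample sd) from the OLS regression
    of ``ge_scaled`` on intercept, age and sex.
    """
    ge = np.asarray(ge, dtype=float)
    if ge.shape[0] != len(demographics):
        raise ValueError("ge and demographics length mismatch")
    if ge.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(ge) == 0:
        raise ValueError("constant efficiency vector cannot be scaled")
    if scale_mode == "minmax":
        scaled = (ge - ge.min()) / np.ptp(ge)
    elif scale_mode == "max":
        scaled = ge / ge.max()
    else:
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    age = np.array([d.age for d in demographics], dtype=float)
    sex = np.array([d.sex for d in demographics], dtype=float)
    X = np.column_stack([np.ones_like(age), age, sex])
    beta, *_ = np.linalg.lstsq(X, scaled, rcond=None)
    resid = scaled - X @ beta
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("residuals have zero variance; cannot standardize")
    adj = (resid - resid.mean()) / sd
    return pd.DataFrame(
        {
            "subject_id": [d.subject_id for d in demographics],
            "ge_raw": ge,
            "ge_scaled": scaled,
            "ge_adj": adj,
        }
    )
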