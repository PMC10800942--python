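"""Two-step GLM prewhitening of ROI time series.

Serial autocorrelation in BOLD-like series biases residual-based statistics,
so before computing functional connectivity each node's series is whitened:

1. residualize the raw series on the 6 motion parameters;
2. estimate a per-node AR(1) coefficient from those residuals;
3. remove the AR(1) structure from the *raw* series (exact GLS whitening,
   first sample scaled by ``sqrt(1 - phi^2)`` so series length is kept);
4. residualize the whitened series on motion + WM + CSF confounds.

Step 3 operating on the raw data (rather than on the step-1 residuals) is
deliberate; the textbook variant — whitening the step-1 residuals — is
available via ``textbook_order=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import TimeSeriesBundle

__all__ = [
    "WhiteningModel",
    "ols_residuals",
    "estimate_ar1",
    "apply_whitening",
    "prewhiten_two_step",
]


@dataclass
class WhiteningModel:
    """Per-node AR(1) coefficients and the two regression coefficient sets."""

    phi: np.ndarray
    betas_step1: np.ndarray
    betas_step2: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.abs(self.phi) >= 1):
            raise ValueError("AR(1) coefficients must satisfy |phi| < 1")


def _augment_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def ols_residuals(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares residuals of each column of Y on the design X.

    An intercept column is prepended internally. Collinear design columns are
    dropped (QR with column pivoting) with a warning; their coefficients are
    reported as zero so the returned coefficient array always has one row per
    augmented design column.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T = Y.shape[0]
    if X.shape[0] != T:
        raise ValueError(f"design has {X.shape[0]} rows, data has {T}")
    Xa = _augment_intercept(X)
    K = Xa.shape[1]
    if T <= K + 1:
        raise ValueError(f"need T > K + 1 (T={T}, K={K})")

    from scipy.linalg import qr

    _, R, piv = qr(Xa, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xa.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    if rank < K:
        dropped = sorted(set(range(K)) - set(keep))
        warnings.warn(f"design rank-deficient; dropping collinear columns {dropped}")
    Xk = Xa[:, keep]
    beta_k, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
    betas = np.zeros((K, Y.shape[1]))
    betas[keep] = beta_k
    resid = Y - Xk @ beta_k
    return resid, betas


def estimate_ar1(R: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation of each demeaned column, clipped to (-0.999, 0.999).

    Zero-variance columns get phi = 0 with a warning.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if R.shape[0] == 1:
        R = R.T
    T = R.shape[0]
    if T < 3:
        raise ValueError("need at least 3 time points to estimate AR(1)")
    Rc = R - R.mean(axis=0)
    denom = np.sum(Rc**2, axis=0)
    zero = denom == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance column(s); phi set to 0")
        denom = np.where(zero, 1.0, denom)
    num = np.sum(Rc[1:] * Rc[:-1], axis=0)
    phi = np.where(zero, 0.0, num / denom)
    return np.clip(phi, -0.999, 0.999)


def apply_whitening(Y_raw: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """AR(1) difference operator per node.

    ``y'_t = y_t - phi * y_{t-1}`` for t >= 2 and
    ``y'_1 = y_1 * sqrt(1 - phi^2)`` (the exact-whitening scaling, which
    keeps the series length and gives the first sample unit innovation
    variance under a stationary AR(1)).
    """
    Y = np.atleast_2d(np.asarray(Y_raw, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    phi = np.asarray(phi, dtype=float).ravel()
    if phi.shape[0] != Y.shape[1]:
        raise ValueError(f"phi has {phi.shape[0]} entries for {Y.shape[1]} nodes")
    out = np.empty_like(Y)
    out[0] = Y[0] * np.sqrt(1.0 - phi**2)
    out[1:] = Y[1:] - phi * Y[:-1]
    return out


def prewhiten_two_step(
    bundle: TimeSeriesBundle, textbook_order: bool = False
) -> tuple[np.ndarray, WhiteningModel]:
    """Full conditioning pipeline for one subject.

    Returns the step-4 residuals (same shape as ``bundle.Y``) and the fitted
    :class:`WhiteningModel`. With ``textbook_order=True`` the AR(1) operator
    is applied to the step-1 residuals instead of the raw data.
    """
    Y = bundle.Y
    motion = bundle.motion
    if motion.shape[1] != 6:
        raise ValueError("bundle must provide 6 motion regressors")
    resid1, betas1 = ols_residuals(Y, motion)
    phi = estimate_ar1(resid1)
    base = resid1 if textbook_order else Y
    white = apply_whitening(base, phi)
    confounds = np.column_stack([motion, bundle.wm, bundle.csf])
    resid2, betas2 = ols_residuals(white, confounds)
    return resid2, WhiteningModel(phi=phi, betas_step1=betas1, betas_step2=betas2)
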