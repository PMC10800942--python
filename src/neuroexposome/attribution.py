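"""Shapley-value attribution for tree-ensemble predictions.

The attribution question: for one subject, how much did each exposure
feature move the model's prediction away from the average prediction?  The
answer is the interventional Shapley value with a background (reference)
dataset: the value of a coalition S is the model's prediction averaged over
background rows with the features in S taken from the subject and the rest
from the background row.

Two independent routes are provided:

* :func:`shapley_exact` — literal enumeration of all 2^M coalitions for any
  black-box ``predict_fn`` (M <= 15).  This is the oracle.
* :func:`tree_shap` — an exact polynomial-time algorithm for tree
  ensembles.  For each (subject, background row, leaf) triple the path
  constraints partition the path's features into "must come from the
  subject" (set A) and "must come from the background row" (set B); the
  leaf's value then contributes ``|A|!|B|!/(|A|+|B|+1)!``-weighted terms to
  each feature's Shapley value in closed form.  Identical to the oracle up
  to floating point, at a cost linear in background size and leaf count.

Local accuracy (base value + attributions = prediction) is asserted when an
:class:`AttributionSet` is constructed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "AttributionSet",
    "shapley_exact",
    "tree_shap",
    "global_importance",
    "beeswarm_export",
    "plot_importance_bar",
    "plot_beeswarm",
]


@dataclass
class AttributionSet:
    """Per-subject, per-feature Shapley values for one model.

    ``phi`` is n_subjects x n_features (units of the prediction target),
    ``base_value`` the expected prediction over the background, and
    ``predictions`` the model output for each subject.  Local accuracy
    (``base_value + phi.sum(axis=1) == predictions`` within 1e-6) is
    enforced here.
    """

    phi: pd.DataFrame
    base_value: float
    feature_values: pd.DataFrame
    predictions: np.ndarray

    def __post_init__(self) -> None:
        if self.phi.shape != self.feature_values.shape:
            raise ValueError("phi and feature_values must be aligned")
        if not np.array_equal(self.phi.index, self.feature_values.index):
            raise ValueError("phi and feature_values row indices differ")
        total = self.base_value + self.phi.to_numpy().sum(axis=1)
        err = np.max(np.abs(total - self.predictions))
        if err > 1e-6:
            raise ValueError(f"local accuracy violated: max |base + sum(phi) - pred| = {err:.3g}")


def _shapley_weight(s: int, M: int) -> float:
    return math.factorial(s) * math.factorial(M - 1 - s) / math.factorial(M)


def shapley_exact(predict_fn, x, background, M: int | None = None) -> tuple[np.ndarray, float]:
    """Interventional Shapley values by full coalition enumeration.

    ``v(S)`` is ``predict_fn`` averaged over background rows with features
    in S replaced by ``x``'s values; ``phi_j = sum_S w(|S|) (v(S u {j}) -
    v(S))`` over all S not containing j.  Returns (phi, base) where base =
    v(empty set).  Enumeration is 2^M predictions, so M <= 15 is enforced.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background must be non-empty")
    if M is None:
        M = x.shape[0]
    if M != x.shape[0] or M != background.shape[1]:
        raise ValueError("feature-count mismatch between x and background")
    if M > 15:
        raise ValueError(f"M={M} too large for 2^M enumeration; use tree_shap")

    values = {}
    for size in range(M + 1):
        for S in combinations(range(M), size):
            hybrid = background.copy()
            hybrid[:, list(S)] = x[list(S)]
            values[S] = float(np.mean(predict_fn(hybrid)))
    phi = np.zeros(M)
    for j in range(M):
        others = [f for f in range(M) if f != j]
        for size in range(M):
            w = _shapley_weight(size, M)
            for S in combinations(others, size):
                phi[j] += w * (values[tuple(sorted(S + (j,)))] - values[S])
    return phi, values[()]


# ---------------------------------------------------------------------------
# tree ensemble extraction (exact float32 leaf values from the raw model JSON)


@dataclass
class _Leaf:
    value: float
    features: np.ndarray  # constrained feature indices along the path
    lower: np.ndarray  # per constrained feature: value must be >= lower
    upper: np.ndarray  # ... and < upper


class _TreeEnsemble:
    """Split structure of a fitted XGBoost regressor, as leaf path intervals."""

    def __init__(self, booster, base_score: float, feature_names: list[str]):
        raw = json.loads(bytearray(booster.save_raw("json")).decode())
        learner = raw["learner"]
        if learner["gradient_booster"]["name"] != "gbtree":
            raise ValueError("only tree ensembles are supported")
        self.base_score = base_score
        self.feature_names = feature_names
        self.trees: list[list[_Leaf]] = []
        for tree in learner["gradient_booster"]["model"]["trees"]:
            left = tree["left_children"]
            right = tree["right_children"]
            split = tree["split_indices"]
            cond = tree["split_conditions"]
            leaves: list[_Leaf] = []

            def walk(nid: int, bounds: dict[int, tuple[float, float]]) -> None:
                if left[nid] == -1:
                    feats = np.fromiter(bounds.keys(), dtype=np.intp, count=len(bounds))
                    # splits are evaluated in float32, matching xgboost exactly
                    lo = np.array([bounds[f][0] for f in feats], dtype=np.float32)
                    hi = np.array([bounds[f][1] for f in feats], dtype=np.float32)
                    leaves.append(_Leaf(value=float(cond[nid]), features=feats, lower=lo, upper=hi))
                    return
                f, thr = split[nid], cond[nid]
                lo, hi = bounds.get(f, (-np.inf, np.inf))
                if lo < thr:  # left: x[f] < thr
                    b = dict(bounds)
                    b[f] = (lo, min(hi, thr))
                    walk(left[nid], b)
                if hi > thr:  # right: x[f] >= thr
                    b = dict(bounds)
                    b[f] = (max(lo, thr), hi)
                    walk(right[nid], b)

            walk(0, {})
            self.trees.append(leaves)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Evaluation of the ensemble with float64 leaf accumulation.

        Split comparisons are made in float32 (as xgboost does), so routing
        is bit-faithful; only the summation is higher precision.
        """
        X32 = np.atleast_2d(np.asarray(X, dtype=np.float32))
        out = np.full(X32.shape[0], self.base_score)
        for leaves in self.trees:
            for leaf in leaves:
                ok = np.ones(X32.shape[0], dtype=bool)
                for f, lo, hi in zip(leaf.features, leaf.lower, leaf.upper):
                    ok &= (X32[:, f] >= lo) & (X32[:, f] < hi)
                out[ok] += leaf.value
        return out


def _r_table(kmax: int) -> np.ndarray:
    """R[a, b] = a! b! / (a + b + 1)! — the interventional path weights."""
    R = np.zeros((kmax + 1, kmax + 1))
    for a in range(kmax + 1):
        for b in range(kmax + 1):
            R[a, b] = math.factorial(a) * math.factorial(b) / math.factorial(a + b + 1)
    return R


def _extract_ensemble(model) -> _TreeEnsemble:
    from .predictor import GradientBooster

    if isinstance(model, _TreeEnsemble):
        return model
    if isinstance(model, GradientBooster):
        return _TreeEnsemble(model.booster, model.base_score, model.feature_names)
    # raw XGBRegressor: recover base_score from the model config
    try:
        booster = model.get_booster()
    except AttributeError as exc:
        raise TypeError("model must be a GradientBooster or fitted XGBRegressor") from exc
    cfg = json.loads(booster.save_config())
    base = float(cfg["learner"]["learner_model_param"]["base_score"])
    names = booster.feature_names or [f"f{i}" for i in range(booster.num_features())]
    return _TreeEnsemble(booster, base, list(names))


def tree_shap(model, X: pd.DataFrame, background: pd.DataFrame | np.ndarray) -> AttributionSet:
    """Exact interventional Shapley attributions for a tree ensemble.

    ``model`` is a fitted :class:`~neuroexposome.predictor.GradientBooster`
    (or bare XGBRegressor); ``X`` the subjects to explain; ``background``
    the reference distribution (normally the training matrix).
    """
    ensemble = _extract_ensemble(model)
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        if cols != ensemble.feature_names:
            X = X[ensemble.feature_names]
            cols = ensemble.feature_names
        Xv = X.to_numpy(dtype=float)
        index = X.index
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
        cols = ensemble.feature_names
        index = pd.RangeIndex(Xv.shape[0])
        X = pd.DataFrame(Xv, columns=cols, index=index)
    B = (
        background[ensemble.feature_names].to_numpy(dtype=float)
        if isinstance(background, pd.DataFrame)
        else np.atleast_2d(np.asarray(background, dtype=float))
    )
    if B.shape[0] == 0:
        raise ValueError("background must be non-empty")
    nb = B.shape[0]
    n, M = Xv.shape

    kmax = max((len(l.features) for leaves in ensemble.trees for l in leaves), default=0)
    R = _r_table(kmax + 1)

    # split comparisons in float32, matching xgboost's routing exactly
    B32 = B.astype(np.float32)
    X32 = Xv.astype(np.float32)

    # background-side path satisfaction is subject-independent: precompute
    sat_r: list[list[np.ndarray]] = []
    base_acc = 0.0
    for leaves in ensemble.trees:
        per_tree = []
        for leaf in leaves:
            s = (B32[:, leaf.features] >= leaf.lower) & (B32[:, leaf.features] < leaf.upper)
            per_tree.append(s)
            base_acc += leaf.value * float(s.all(axis=1).sum())
        sat_r.append(per_tree)
    base_value = ensemble.base_score + base_acc / nb

    phi = np.zeros((n, M))
    for i in range(n):
        x = X32[i]
        for leaves, per_tree in zip(ensemble.trees, sat_r):
            for leaf, sr in zip(leaves, per_tree):
                sx = (x[leaf.features] >= leaf.lower) & (x[leaf.features] < leaf.upper)
                xonly = sx[None, :] & ~sr  # nb x k: feature must be in S
                ronly = ~sx[None, :] & sr  # nb x k: feature must be out of S
                reachable = ~(~sx[None, :] & ~sr).any(axis=1)
                if not reachable.any():
                    continue
                a = xonly.sum(axis=1)
                b = ronly.sum(axis=1)
                for t, f in enumerate(leaf.features):
                    pos = xonly[:, t] & reachable
                    if pos.any():
                        phi[i, f] += leaf.value * R[a[pos] - 1, b[pos]].sum()
                    neg = ronly[:, t] & reachable
                    if neg.any():
                        phi[i, f] -= leaf.value * R[a[neg], b[neg] - 1].sum()
    phi /= nb

    predictions = ensemble.predict(Xv)
    return AttributionSet(
        phi=pd.DataFrame(phi, columns=cols, index=index),
        base_value=float(base_value),
        feature_values=X.copy(),
        predictions=predictions,
    )


def loocv_tree_shap(X: pd.DataFrame, y, hp, seed: int = 0) -> pd.DataFrame:
    """Per-fold attributions: explain each subject with the booster that
    never saw it.

    For every subject i a model is trained on the other n-1 rows (matching
    the LOOCV prediction protocol, same per-fold seeds) and subject i's
    interventional Shapley values are computed against that training
    background.  Returns a long DataFrame (subject_id, feature, shap_value,
    base_value) — base values differ per fold, unlike the final-model
    attribution.
    """
    from .predictor import GradientBooster, _canonical, _seed_for_fold

    Xc, yc = _canonical(X, y)
    n = Xc.shape[0]
    rows = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        booster = GradientBooster(hp, seed=_seed_for_fold(seed, i)).fit(Xc.iloc[mask], yc[mask])
        attr = tree_shap(booster, Xc.iloc[[i]], background=Xc.iloc[mask])
        sid = Xc.index[i]
        for feat, val in attr.phi.iloc[0].items():
            rows.append(
                {"subject_id": sid, "feature": feat, "shap_value": val, "base_value": attr.base_value}
            )
        mask[i] = True
    return pd.DataFrame(rows)


def global_importance(attr: AttributionSet) -> pd.DataFrame:
    """Mean |SHAP| per feature, sorted descending (ties alphabetical)."""
    if attr.phi.empty:
        raise ValueError("empty attribution set")
    imp = attr.phi.abs().mean(axis=0)
    table = (
        pd.DataFrame({"feature": imp.index, "mean_abs_shap": imp.to_numpy()})
        .sort_values(["mean_abs_shap", "feature"], ascending=[False, True], ignore_index=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def beeswarm_export(attr: AttributionSet, features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long table for beeswarm plotting plus per-feature sign diagnostics.

    One row per (subject, feature) with the SHAP value, the feature value,
    and the feature's global-importance rank; the per-feature Spearman
    correlation between feature value and SHAP value (``sign_spearman``)
    summarises directionality — negative means higher exposure pushes the
    predicted efficiency down.
    """
    from scipy.stats import spearmanr

    feats = attr.feature_values if features is None else features
    if not attr.phi.index.equals(feats.index) or list(attr.phi.columns) != list(feats.columns):
        raise ValueError("attributions and features are misaligned")
    ranks = global_importance(attr).set_index("feature")["rank"]
    rows = []
    for col in attr.phi.columns:
        sv = attr.phi[col].to_numpy()
        fv = feats[col].to_numpy()
        if np.ptp(fv) > 0 and np.ptp(sv) > 0:
            rho = float(spearmanr(fv, sv).statistic)
        else:
            rho = np.nan
        for sid, s, f in zip(attr.phi.index, sv, fv):
            rows.append(
                {
                    "subject_id": sid,
                    "feature": col,
                    "shap_value": s,
                    "feature_value": f,
                    "feature_rank": int(ranks[col]),
                    "sign_spearman": rho,
                }
            )
    return pd.DataFrame(rows)


def plot_importance_bar(attr: AttributionSet, top: int = 15, ax=None):
    """Horizontal bar plot of mean |SHAP| for the top features."""
    import matplotlib.pyplot as plt

    table = global_importance(attr).head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(table) + 1))
    ax.barh(table["feature"], table["mean_abs_shap"], color="#4c72b0")
    ax.set_xlabel("mean |SHAP| (adjusted GE units)")
    return ax


def plot_beeswarm(attr: AttributionSet, top: int = 10, ax=None, seed: int = 0):
    """Beeswarm-style strip plot: SHAP values coloured by feature value."""
    import matplotlib.pyplot as plt

    table = global_importance(attr).head(top)
    rng = np.random.default_rng(seed)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * top + 1))
    for row, feat in enumerate(table["feature"]):
        sv = attr.phi[feat].to_numpy()
        fv = attr.feature_values[feat].to_numpy()
        order = fv.argsort().argsort() / max(len(fv) - 1, 1)  # rank-normalised colour
        yy = top - 1 - row + rng.uniform(-0.18, 0.18, size=len(sv))
        ax.scatter(sv, yy, c=order, cmap="viridis", s=14, linewidths=0)
    ax.set_yticks(range(top - 1, -1, -1), table["feature"])
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("SHAP value (impact on predicted adjusted GE)")
    return ax
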