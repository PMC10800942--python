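"""Gradient-boosted prediction of adjusted global efficiency with LOOCV.

The estimand is simple: can the 36 exposure features predict the age/sex-
adjusted global-efficiency score out of sample?  Every subject's prediction
comes from a booster trained on the other n-1 subjects (leave-one-out cross
validation), hyperparameters are chosen by random search where each
candidate is scored by full-LOOCV mean squared error, and performance is the
Pearson correlation r between out-of-fold predictions and observations with
explained variance VE = r^2.

The booster is XGBoost behind a narrow wrapper (:class:`GradientBooster`) so
tests can swap in or cross-check alternative tree ensembles.  Determinism
contracts: training rows are canonically sorted by subject id before every
fit (so predictions are invariant to input row order even with subsampling),
and per-fold seeds derive from (seed, held-out position).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HyperParams",
    "SearchSpace",
    "PredictionEvaluation",
    "GradientBooster",
    "sample_hyperparams",
    "loocv_predict",
    "tune",
    "evaluate",
]


@dataclass(frozen=True)
class HyperParams:
    learning_rate: float = 0.1
    max_depth: int = 3
    alpha: float = 0.1  # L1 regularization
    subsample: float = 1.0
    n_rounds: int = 200
    min_child_weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.min_child_weight < 0:
            raise ValueError("min_child_weight must be >= 0")


@dataclass(frozen=True)
class SearchSpace:
    """Random-search ranges; learning_rate and alpha are drawn log-uniform."""

    learning_rate: tuple[float, float] = (0.01, 0.3)
    max_depth: tuple[int, int] = (2, 6)
    alpha: tuple[float, float] = (1e-3, 10.0)
    subsample: tuple[float, float] = (0.5, 1.0)
    n_rounds: tuple[int, int] = (50, 500)
    min_child_weight: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("learning_rate", "max_depth", "alpha", "subsample", "n_rounds", "min_child_weight"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class PredictionEvaluation:
    r: float
    p: float
    ve: float  # fraction, = r^2

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.r <= 1 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if not 0 <= self.p <= 1:
            raise ValueError("p outside [0, 1]")

    @property
    def ve_percent(self) -> int:
        """Explained variance as a rounded whole-number percentage."""
        return round(self.ve * 100)


def _seed_for_fold(seed: int, fold: int) -> int:
    state = np.random.SeedSequence(entropy=seed, spawn_key=(fold,)).generate_state(1)[0]
    return int(state % (2**31 - 1))


class GradientBooster:
    """Thin deterministic wrapper around an XGBoost regressor.

    ``base_score`` is pinned to the training-label mean so a constant target
    is predicted exactly and the attribution stage has an exact base value.
    """

    def __init__(self, hp: HyperParams, seed: int = 0) -> None:
        self.hp = hp
        self.seed = seed
        self.model = None
        self.base_score: float | None = None
        self.feature_names: list[str] | None = None

    def fit(self, X: pd.DataFrame | np.ndarray, y: np.ndarray) -> "GradientBooster":
        import xgboost as xgb

        y = np.asarray(y, dtype=float)
        self.base_score = float(np.mean(y))
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = [f"f{j}" for j in range(X.shape[1])]
            X = pd.DataFrame(X, columns=self.feature_names)
        hp = self.hp
        self.model = xgb.XGBRegressor(
            n_estimators=hp.n_rounds,
            learning_rate=hp.learning_rate,
            max_depth=hp.max_depth,
            reg_alpha=hp.alpha,
            reg_lambda=1.0,
            subsample=hp.subsample,
            min_child_weight=hp.min_child_weight,
            base_score=self.base_score,
            objective="reg:squarederror",
            tree_method="hist",
            n_jobs=1,
            random_state=self.seed,
            verbosity=0,
        )
        self.model.fit(X, y)
        return self

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("booster not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.feature_names)
        return self.model.predict(X[self.feature_names]).astype(float)

    @property
    def booster(self):
        if self.model is None:
            raise RuntimeError("booster not fitted")
        return self.model.get_booster()


def sample_hyperparams(space: SearchSpace, n_iter: int, seed: int = 0) -> list[HyperParams]:
    """Draw ``n_iter`` candidate configurations from the search space."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        lr = np.exp(rng.uniform(np.log(space.learning_rate[0]), np.log(space.learning_rate[1])))
        alpha = np.exp(rng.uniform(np.log(max(space.alpha[0], 1e-12)), np.log(max(space.alpha[1], 1e-12))))
        depth = int(rng.integers(space.max_depth[0], space.max_depth[1] + 1))
        sub = float(rng.uniform(*space.subsample))
        rounds = int(rng.integers(space.n_rounds[0], space.n_rounds[1] + 1))
        mcw = float(rng.uniform(*space.min_child_weight))
        out.append(
            HyperParams(
                learning_rate=float(lr),
                max_depth=depth,
                alpha=float(alpha),
                subsample=sub,
                n_rounds=rounds,
                min_child_weight=mcw,
            )
        )
    return out


def _canonical(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame indexed by subject_id")
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y length mismatch")
    order = np.argsort(X.index.to_numpy())
    return X.iloc[order], y[order]


def loocv_predict(X: pd.DataFrame, y, hp: HyperParams, seed: int = 0) -> pd.Series:
    """Out-of-fold prediction for every subject.

    Subject i's prediction comes from a booster trained on the other n-1
    rows with ``hp``; the fold seed derives from (seed, i) in canonical
    subject order.  Returns a Series indexed like ``X``.
    """
    Xc, yc = _canonical(X, y)
    n = Xc.shape[0]
    if n < 10:
        raise ValueError(f"LOOCV needs at least 10 subjects, got {n}")
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        booster = GradientBooster(hp, seed=_seed_for_fold(seed, i))
        booster.fit(Xc.iloc[mask], yc[mask])
        preds[i] = booster.predict(Xc.iloc[[i]])[0]
        mask[i] = True
    return pd.Series(preds, index=Xc.index, name="predicted").reindex(X.index)


def tune(
    X: pd.DataFrame,
    y,
    space: SearchSpace | None = None,
    n_iter: int = 500,
    seed: int = 0,
) -> tuple[HyperParams, pd.DataFrame]:
    """Random-search hyperparameter tuning scored by LOOCV mean squared error.

    Returns the winning configuration (lowest MSE; ties keep the earlier
    sample) and the full score table (one row per candidate).
    """
    space = space or SearchSpace()
    candidates = sample_hyperparams(space, n_iter, seed=seed)
    _, yc = _canonical(X, y)
    rows = []
    best_idx, best_mse = 0, np.inf
    for idx, hp in enumerate(candidates):
        preds = loocv_predict(X, y, hp, seed=seed)
        mse = float(np.mean((preds.to_numpy() - np.asarray(y, dtype=float)) ** 2))
        rows.append({"candidate": idx, **asdict(hp), "loocv_mse": mse})
        if mse < best_mse:
            best_idx, best_mse = idx, mse
    table = pd.DataFrame(rows)
    return candidates[best_idx], table


def evaluate(pred, obs) -> PredictionEvaluation:
    """Pearson r, two-sided p (t transform, n-2 df) and VE = r^2."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 pairs")
    if pred.std() == 0 or obs.std() == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    res = stats.pearsonr(pred, obs)
    r = float(res.statistic)
    return PredictionEvaluation(r=r, p=float(res.pvalue), ve=r * r)
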