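"""Synthetic cohorts with a planted exposure -> connectivity effect.

The measured cohort this emulates is not public, so recovery testing runs on
synthetic data with the same statistical structure the analysis assumes:

* demographics — configurable sex split and uniform age range;
* biomarkers — log-normal concentrations for the 36 metal x medium cells,
  parameterised by geometric mean / geometric SD / LOD, with a shared
  within-metal latent factor inducing cross-media correlation, and LOD
  censoring flags;
* a latent per-subject *coupling* score that carries the planted exposure
  effect (e.g. urinary lead down, blood zinc up) plus age/sex terms;
* 111-node BOLD-like ROI time series whose between-module correlation level
  is a strictly increasing function of coupling, passed through an AR(1)
  filter and contaminated with motion/WM/CSF nuisance signals.

Because the planted effect lives on the *latent covariance*, not on the
efficiency values themselves, every downstream stage (prewhitening, graph
construction, efficiency, prediction, attribution) is exercised before the
effect can be recovered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import BiomarkerSpec, METALS, MEDIA, reference_specs

__all__ = [
    "Demographics",
    "EffectSpec",
    "TimeSeriesBundle",
    "gen_cohort",
    "gen_biomarkers",
    "plant_effect",
    "gen_timeseries",
]


@dataclass(frozen=True)
class Demographics:
    subject_id: str
    age: float
    sex: int  # female = 1

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex}")


@dataclass(frozen=True)
class EffectSpec:
    """Planted exposure effect on the latent coupling scale.

    ``target_features`` are (metal, medium) cells; each gets a direction
    (+1/-1) and a non-negative standardized magnitude.  ``link`` selects the
    monotone transform applied to the z-scored log concentration: ``linear``
    uses z itself, ``threshold`` uses the sign of z (a hard exceedance
    effect).
    """

    target_features: tuple[tuple[str, str], ...] = ()
    signs: tuple[int, ...] = ()
    magnitudes: tuple[float, ...] = ()
    link: str = "linear"

    def __post_init__(self) -> None:
        if not (len(self.target_features) == len(self.signs) == len(self.magnitudes)):
            raise ValueError("target_features, signs and magnitudes must have equal length")
        if any(abs(s) != 1 for s in self.signs):
            raise ValueError("signs must be +1 or -1")
        if any(m < 0 for m in self.magnitudes):
            raise ValueError("magnitudes must be >= 0")
        if self.link not in ("linear", "threshold"):
            raise ValueError(f"unknown link {self.link!r}")

    @classmethod
    def default(cls, magnitude: float = 1.0) -> "EffectSpec":
        """Urinary lead down / blood zinc up, equal magnitudes."""
        return cls(
            target_features=(("Pb", "urine"), ("Zn", "blood")),
            signs=(-1, +1),
            magnitudes=(magnitude, magnitude),
        )


@dataclass
class TimeSeriesBundle:
    """Per-subject ROI time series plus nuisance regressors.

    ``Y`` is T x N (BOLD-like arbitrary units), ``motion`` T x 6,
    ``wm``/``csf`` length T, ``tr`` in seconds.
    """

    subject_id: str
    Y: np.ndarray
    motion: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float).ravel()
        self.csf = np.asarray(self.csf, dtype=float).ravel()
        T = self.Y.shape[0]
        if self.motion.shape != (T, 6):
            raise ValueError(f"motion must be {T} x 6, got {self.motion.shape}")
        if self.wm.shape[0] != T or self.csf.shape[0] != T:
            raise ValueError("wm/csf length must match Y")
        for name, arr in (("Y", self.Y), ("motion", self.motion), ("wm", self.wm), ("csf", self.csf)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


def _subject_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"sub-{i + 1:0{width}d}" for i in range(n)]


def gen_cohort(
    n: int,
    female_frac: float = 0.57,
    age_range: tuple[float, float] = (13.0, 25.0),
    seed: int = 0,
) -> list[Demographics]:
    """Draw a cohort with a fixed sex split and uniform ages.

    Exactly ``round(n * female_frac)`` subjects are female (sex = 1); sexes
    are assigned to random positions. Ages are uniform on ``age_range``.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 <= female_frac <= 1:
        raise ValueError("female_frac must be in [0, 1]")
    lo, hi = age_range
    if lo > hi:
        raise ValueError(f"invalid age range: min {lo} > max {hi}")
    rng = np.random.default_rng(seed)
    n_female = round(n * female_frac)
    sex = np.zeros(n, dtype=int)
    sex[rng.permutation(n)[:n_female]] = 1
    ages = rng.uniform(lo, hi, size=n)
    return [
        Demographics(subject_id=sid, age=float(a), sex=int(s))
        for sid, a, s in zip(_subject_ids(n), ages, sex)
    ]


def gen_biomarkers(
    specs: list[BiomarkerSpec] | None,
    demographics: list[Demographics],
    corr: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a long-format biomarker panel.

    For each spec, ``ln(concentration) ~ Normal(ln gm, ln gsd)``.  Media of
    the same metal share a latent standard-normal factor with loading
    ``sqrt(corr)``, so any two media of one metal have log-scale correlation
    ``corr``.  Values below the spec's LOD keep their sampled value but are
    flagged ``censored`` for the downstream LOD-substitution stage.

    Returns a DataFrame with columns
    ``subject_id, metal, medium, value, lod, censored``.
    """
    if specs is None:
        specs = reference_specs()
    if not 0 <= corr < 1:
        raise ValueError("corr must be in [0, 1)")
    cells = {(s.metal, s.medium) for s in specs}
    missing = [(m, md) for m in METALS for md in MEDIA if (m, md) not in cells]
    if missing and len(specs) == 36:
        raise ValueError(f"duplicate specs shadow missing cells: {missing}")
    if missing:
        raise ValueError(f"incomplete spec grid, missing cells: {missing[:5]}...")
    if len(specs) != 36:
        raise ValueError(f"expected 36 specs, got {len(specs)}")

    rng = np.random.default_rng(seed)
    n = len(demographics)
    ids = [d.subject_id for d in demographics]
    latent = {metal: rng.standard_normal(n) for metal in METALS}
    rows = []
    for spec in specs:
        eps = rng.standard_normal(n)
        z = np.sqrt(corr) * latent[spec.metal] + np.sqrt(1.0 - corr) * eps
        conc = np.exp(np.log(spec.gm) + np.log(spec.gsd) * z)
        censored = conc < spec.lod
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": ids,
                    "metal": spec.metal,
                    "medium": spec.medium,
                    "value": conc,
                    "lod": spec.lod,
                    "censored": censored,
                }
            )
        )
    panel = pd.concat(rows, ignore_index=True)
    return panel.sort_values(["subject_id", "medium", "metal"], ignore_index=True)


def plant_effect(
    panel: pd.DataFrame,
    demographics: list[Demographics],
    effect: EffectSpec,
    seed: int = 0,
    baseline: float = 0.0,
    beta_age: float = 0.2,
    beta_sex: float = 0.2,
) -> pd.DataFrame:
    """Compute the latent coupling score and latent true efficiency.

    ``coupling_i = baseline + sum_f sign_f * magnitude_f * g(z_i,f)
    + beta_age * z(age_i) + beta_sex * (sex_i - mean sex)`` where ``z_i,f``
    is the z-scored log concentration of feature f and ``g`` is the effect
    link.  The latent true efficiency is a logistic (strictly increasing)
    function of coupling; it exists only for ground-truth recovery checks
    and must never feed the analysis stages.

    Returns a DataFrame ``subject_id, coupling, latent_ge``.
    """
    wide = panel.pivot_table(
        index="subject_id", columns=["metal", "medium"], values="value", aggfunc="first"
    )
    ids = [d.subject_id for d in demographics]
    wide = wide.loc[ids]
    coupling = np.full(len(ids), baseline, dtype=float)
    for (metal, medium), sign, mag in zip(effect.target_features, effect.signs, effect.magnitudes):
        if (metal, medium) not in wide.columns:
            raise KeyError(f"effect feature ({metal}, {medium}) not present in panel")
        logv = np.log(wide[(metal, medium)].to_numpy(dtype=float))
        sd = logv.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance feature ({metal}, {medium}): z-score undefined")
        z = (logv - logv.mean()) / sd
        if effect.link == "threshold":
            z = np.sign(z)
        coupling += sign * mag * z
    ages = np.array([d.age for d in demographics], dtype=float)
    sexes = np.array([d.sex for d in demographics], dtype=float)
    if ages.std(ddof=1) > 0:
        coupling += beta_age * (ages - ages.mean()) / ages.std(ddof=1)
    coupling += beta_sex * (sexes - sexes.mean())
    latent_ge = 1.0 / (1.0 + np.exp(-coupling))
    return pd.DataFrame({"subject_id": ids, "coupling": coupling, "latent_ge": latent_ge})


def _smooth_walk(rng: np.random.Generator, T: int, window: int = 20) -> np.ndarray:
    """Unit-variance smooth random walk (moving-average smoothed cumsum)."""
    w = np.cumsum(rng.standard_normal(T + window))
    kernel = np.ones(window) / window
    w = np.convolve(w, kernel, mode="valid")[:T]
    w = w - w.mean()
    sd = w.std()
    return w / sd if sd > 0 else w


def _modular_covariance(
    rng: np.random.Generator,
    n_nodes: int,
    n_modules: int,
    r_within: float,
    r_between: float,
    sd_within: float,
    sd_between: float,
) -> np.ndarray:
    """Draw a modular correlation matrix with heterogeneous pair strengths.

    Within-module pairs have latent correlations ~ Normal(r_within,
    sd_within), between-module pairs ~ Normal(r_between, sd_between), both
    clipped to [0, 0.9].  The per-pair spread makes the two strength
    distributions overlap near the proportional-threshold cutoff, so a shift
    of the between-module level changes which edges survive thresholding —
    the mechanism that transmits the planted coupling to global efficiency.

    The assembled matrix is repaired to positive definite by eigenvalue
    clipping plus diagonal renormalization.  Negative eigenvalues of order
    ``sd * sqrt(N)`` are the random-matrix norm for independent per-pair
    draws and are repaired silently; anything beyond that spectral-spread
    scale indicates a structural problem and triggers a warning first.
    """
    labels = np.sort(np.arange(n_nodes) % n_modules)
    iu = np.triu_indices(n_nodes, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = np.where(
        same,
        rng.normal(r_within, sd_within, size=iu[0].size),
        rng.normal(r_between, sd_between, size=iu[0].size),
    )
    vals = np.clip(vals, 0.0, 0.9)
    C = np.eye(n_nodes)
    C[iu] = vals
    C.T[iu] = vals
    w, V = np.linalg.eigh(C)
    spectral_scale = 2.5 * max(sd_within, sd_between, 0.05) * np.sqrt(n_nodes)
    if w.min() < -spectral_scale:
        warnings.warn(
            f"covariance strongly indefinite (min eigenvalue {w.min():.3f}); repairing"
        )
    if w.min() < 1e-6:
        w = np.clip(w, 1e-6, None)
        C = V @ (w[:, None] * V.T)
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        C = (C + C.T) / 2.0
        np.fill_diagonal(C, 1.0)
    return C


def gen_timeseries(
    coupling: np.ndarray | list[float],
    n_nodes: int = 111,
    T: int = 600,
    ar1: float = 0.4,
    nuisance_amp: float = 1.0,
    seed: int = 0,
    *,
    subject_ids: list[str] | None = None,
    tr: float = 1.0,
    n_modules: int = 4,
    r_within: float = 0.40,
    r_between_base: float = 0.25,
    r_between_gain: float = 0.10,
    coupling_scale: float = 2.0,
    sd_within: float = 0.06,
    sd_between: float = 0.08,
    loading_scale: float = 0.35,
) -> list[TimeSeriesBundle]:
    """Sample AR(1)-autocorrelated modular ROI time series per subject.

    The subject's coupling score shifts the between-module correlation level
    ``r_between = r_between_base + r_between_gain * tanh(coupling /
    coupling_scale)`` while the within-module level stays fixed; per-pair
    strengths are heterogeneous (``sd_within``/``sd_between``), so the two
    strength distributions overlap near the proportional-threshold cutoff
    and a higher coupling yields more inter-module shortcuts — hence higher
    expected global efficiency at any fixed density.  Frames are
    multivariate normal, filtered to AR(1) with coefficient ``ar1``
    (variance-preserving, so lag-0 cross-correlations keep the latent
    structure), then contaminated with motion/WM/CSF components (smooth
    random walks) scaled by ``nuisance_amp``.
    """
    coupling = np.asarray(coupling, dtype=float)
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not -1 < ar1 < 1:
        raise ValueError("ar1 must be in (-1, 1)")
    if T < 3:
        raise ValueError("need at least 3 frames")
    n = coupling.shape[0]
    if subject_ids is None:
        subject_ids = _subject_ids(n)
    if len(subject_ids) != n:
        raise ValueError("subject_ids length must match coupling")

    bundles = []
    for i, (sid, c) in enumerate(zip(subject_ids, coupling)):
        # per-subject stream keyed on (seed, i): stable under cohort resizing
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        r_between = float(
            np.clip(r_between_base + r_between_gain * np.tanh(c / coupling_scale), 0.02, 0.60)
        )
        C = _modular_covariance(
            rng, n_nodes, n_modules, r_within, r_between, sd_within, sd_between
        )
        L = np.linalg.cholesky(C + 1e-9 * np.eye(n_nodes))
        innov = rng.standard_normal((T, n_nodes)) @ L.T
        Y = np.empty_like(innov)
        # variance-preserving AR(1): x_t = ar1 x_{t-1} + sqrt(1-ar1^2) e_t
        Y[0] = innov[0]
        scale = np.sqrt(1.0 - ar1**2)
        for t in range(1, T):
            Y[t] = ar1 * Y[t - 1] + scale * innov[t]
        motion = np.column_stack([_smooth_walk(rng, T) for _ in range(6)])
        wm = _smooth_walk(rng, T)
        csf = _smooth_walk(rng, T)
        if nuisance_amp > 0:
            nuis = np.column_stack([motion, wm, csf])
            B = rng.standard_normal((8, n_nodes)) * loading_scale
            Y = Y + nuisance_amp * (nuis @ B)
        bundles.append(
            TimeSeriesBundle(subject_id=sid, Y=Y, motion=motion, wm=wm, csf=csf, tr=tr)
        )
    return bundles
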