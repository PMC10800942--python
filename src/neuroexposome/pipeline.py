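"""End-to-end orchestration: simulate -> prewhiten -> connectome -> features
-> fit -> explain.

Each stage reads only the previous stage's files from the working directory
and writes plain-text outputs, so stages are runnable standalone and the
whole chain is reproducible from one config.  ``run_all`` executes the
chain, collects the headline numbers (r, p, VE, importance ranking, sign
diagnostics) into a report, and writes a manifest with file hashes, seeds
and package versions.

The simulate stage also writes the latent ground truth (coupling and latent
efficiency) to ``latent_truth.csv`` — for recovery evaluation only; no
analysis stage reads it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .connectome import binarize_proportional, global_efficiency, pearson_matrix, scale_and_adjust
from .features import apply_lod_substitution, assemble_feature_matrix, feature_name
from .predictor import GradientBooster, HyperParams, SearchSpace, evaluate, loocv_predict, tune
from .attribution import beeswarm_export, global_importance, tree_shap
from .prewhiten import prewhiten_two_step
from .reference import load_parcel_names
from .synthetic import EffectSpec, gen_biomarkers, gen_cohort, gen_timeseries, plant_effect

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prewhiten", "connectome", "features", "fit", "explain")


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on. ``seed`` is mandatory."""

    seed: int
    n_subjects: int = 60
    female_frac: float = 0.57
    age_range: tuple[float, float] = (13.0, 25.0)
    media_corr: float = 0.3
    effect_targets: tuple[tuple[str, str], ...] = (("Pb", "urine"), ("Zn", "blood"))
    effect_signs: tuple[int, ...] = (-1, 1)
    effect_magnitudes: tuple[float, ...] = (1.0, 1.0)
    effect_link: str = "linear"
    n_nodes: int = 111
    n_frames: int = 600
    tr: float = 1.0
    ar1: float = 0.4
    nuisance_amp: float = 1.0
    density: float = 0.15
    scale_mode: str = "minmax"
    textbook_order: bool = False
    target: str = "ge_adj"
    n_iter: int = 500
    search_space: SearchSpace = field(default_factory=SearchSpace)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        self.age_range = tuple(self.age_range)
        self.effect_targets = tuple(tuple(t) for t in self.effect_targets)
        self.effect_signs = tuple(int(s) for s in self.effect_signs)
        self.effect_magnitudes = tuple(float(m) for m in self.effect_magnitudes)
        if isinstance(self.search_space, dict):
            self.search_space = SearchSpace(**{k: tuple(v) for k, v in self.search_space.items()})
        if self.target not in ("ge_adj", "ge_scaled"):
            raise ValueError("target must be ge_adj or ge_scaled")
        # stage-specific seeds derived once, deterministically
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(0,))
        states = ss.generate_state(len(STAGES))
        self.stage_seeds = {s: int(v % (2**31 - 1)) for s, v in zip(STAGES, states)}

    @property
    def effect(self) -> EffectSpec:
        return EffectSpec(
            target_features=self.effect_targets,
            signs=self.effect_signs,
            magnitudes=self.effect_magnitudes,
            link=self.effect_link,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("stage_seeds", None)
        d["search_space"] = dataclasses.asdict(self.search_space)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "seed" not in raw:
            raise ValueError(f"{path}: config must define a seed")
        known = {f.name for f in dataclasses.fields(cls) if f.name != "stage_seeds"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _subject_ids_in(workdir: Path) -> list[str]:
    return sorted(
        p.name.removesuffix("_timeseries.tsv")
        for p in (workdir / "timeseries").glob("*_timeseries.tsv")
    )


def stage_simulate(cfg: RunConfig, workdir: str | Path) -> None:
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seeds["simulate"]
    demo = gen_cohort(cfg.n_subjects, cfg.female_frac, cfg.age_range, seed=seed)
    panel = gen_biomarkers(None, demo, corr=cfg.media_corr, seed=seed + 1)
    truth = plant_effect(panel, demo, cfg.effect, seed=seed + 2)
    bundles = gen_timeseries(
        truth["coupling"].to_numpy(),
        n_nodes=cfg.n_nodes,
        T=cfg.n_frames,
        ar1=cfg.ar1,
        nuisance_amp=cfg.nuisance_amp,
        seed=seed + 3,
        subject_ids=[d.subject_id for d in demo],
        tr=cfg.tr,
    )
    nio.write_demographics(demo, workdir / "demographics.tsv")
    nio.write_biomarkers(panel, workdir / "biomarkers.tsv")
    node_names = load_parcel_names() if cfg.n_nodes == 111 else None
    for b in bundles:
        nio.write_timeseries_bundle(b, workdir / "timeseries", node_names=node_names)
    truth.to_csv(workdir / "latent_truth.csv", index=False)
    nio.write_json(
        {"config": _plain(cfg.to_dict()), "stage_seeds": cfg.stage_seeds},
        workdir / "generator_params.json",
    )


def stage_prewhiten(cfg: RunConfig, workdir: str | Path) -> None:
    workdir = Path(workdir)
    out = workdir / "conditioned"
    out.mkdir(exist_ok=True)
    phis = {}
    for sid in _subject_ids_in(workdir):
        bundle = nio.read_timeseries_bundle(sid, workdir / "timeseries", tr=cfg.tr)
        names = nio.node_names_for(sid, workdir / "timeseries")
        cond, model = prewhiten_two_step(bundle, textbook_order=cfg.textbook_order)
        pd.DataFrame(cond, columns=names).to_csv(out / f"{sid}_conditioned.tsv", sep="\t", index=False)
        phis[sid] = model.phi
    phi_df = pd.DataFrame(phis).T
    phi_df.index.name = "subject_id"
    phi_df.to_csv(workdir / "ar1_coefficients.csv")


def stage_connectome(cfg: RunConfig, workdir: str | Path) -> None:
    workdir = Path(workdir)
    demo = nio.read_demographics(workdir / "demographics.tsv")
    ges = []
    for d in demo:
        Y = pd.read_csv(workdir / "conditioned" / f"{d.subject_id}_conditioned.tsv", sep="\t")
        conn = pearson_matrix(Y.to_numpy(dtype=float), node_names=list(Y.columns))
        graph = binarize_proportional(conn, cfg.density)
        ges.append(global_efficiency(graph))
    table = scale_and_adjust(np.array(ges), demo, scale_mode=cfg.scale_mode)
    table.to_csv(workdir / "efficiency.csv", index=False)


def stage_features(cfg: RunConfig, workdir: str | Path) -> None:
    workdir = Path(workdir)
    panel = nio.read_biomarkers(workdir / "biomarkers.tsv")
    features = assemble_feature_matrix(apply_lod_substitution(panel))
    features.to_csv(workdir / "features.csv")


def _load_xy(cfg: RunConfig, workdir: Path) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.read_csv(workdir / "features.csv", index_col="subject_id")
    eff = pd.read_csv(workdir / "efficiency.csv").set_index("subject_id")
    common = X.index.intersection(eff.index)
    X = X.loc[common]
    y = eff.loc[common, cfg.target].to_numpy()
    return X, y


def stage_fit(cfg: RunConfig, workdir: str | Path) -> None:
    workdir = Path(workdir)
    X, y = _load_xy(cfg, workdir)
    seed = cfg.stage_seeds["fit"]
    best, score_table = tune(X, y, cfg.search_space, n_iter=cfg.n_iter, seed=seed)
    score_table.to_csv(workdir / "score_table.csv", index=False)
    nio.write_json(dataclasses.asdict(best), workdir / "best_params.json")
    preds = loocv_predict(X, y, best, seed=seed)
    pd.DataFrame(
        {"subject_id": X.index, "observed": y, "predicted": preds.to_numpy()}
    ).to_csv(workdir / "predictions.csv", index=False)
    ev = evaluate(preds.to_numpy(), y)
    nio.write_json(
        {"r": ev.r, "p": ev.p, "ve": ev.ve, "ve_percent": ev.ve_percent, "n": len(y)},
        workdir / "evaluation.json",
    )


def _final_model(cfg: RunConfig, workdir: Path) -> tuple[GradientBooster, pd.DataFrame]:
    X, y = _load_xy(cfg, workdir)
    hp = HyperParams(**nio.read_json(workdir / "best_params.json"))
    booster = GradientBooster(hp, seed=cfg.stage_seeds["fit"]).fit(X, y)
    return booster, X


def stage_explain(
    cfg: RunConfig, workdir: str | Path, figures: bool = True, per_fold: bool = False
) -> None:
    workdir = Path(workdir)
    booster, X = _final_model(cfg, workdir)
    attr = tree_shap(booster, X, background=X)
    attr.phi.to_csv(workdir / "attribution.csv")
    global_importance(attr).to_csv(workdir / "importance.csv", index=False)
    beeswarm_export(attr).to_csv(workdir / "beeswarm.csv", index=False)
    if per_fold:
        from .attribution import loocv_tree_shap

        eff = pd.read_csv(workdir / "efficiency.csv").set_index("subject_id")
        y = eff.loc[X.index, cfg.target].to_numpy()
        hp = HyperParams(**nio.read_json(workdir / "best_params.json"))
        loocv_tree_shap(X, y, hp, seed=cfg.stage_seeds["fit"]).to_csv(
            workdir / "attribution_loocv.csv", index=False
        )
    if figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .attribution import plot_beeswarm, plot_importance_bar

        figdir = workdir / "figures"
        figdir.mkdir(exist_ok=True)
        ax = plot_importance_bar(attr)
        ax.figure.savefig(figdir / "importance_bar.png", dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        ax = plot_beeswarm(attr)
        ax.figure.savefig(figdir / "beeswarm.png", dpi=120, bbox_inches="tight")
        plt.close(ax.figure)


_STAGE_FN = {
    "simulate": stage_simulate,
    "prewhiten": stage_prewhiten,
    "connectome": stage_connectome,
    "features": stage_features,
    "fit": stage_fit,
    "explain": stage_explain,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig, workdir: str | Path, figures: bool = False) -> dict:
    """Execute every stage in order and assemble the report bundle.

    Returns a dict with the evaluation (r, p, VE), the importance ranking,
    per-feature sign diagnostics for the configured effect features, and
    stage provenance (output hashes, seeds, versions).  Deterministic:
    rerunning with the same config reproduces the report bit-for-bit.
    """
    workdir = Path(workdir)
    for stage in STAGES:
        logger.info("running stage %s", stage)
        fn = _STAGE_FN[stage]
        try:
            if stage == "explain":
                fn(cfg, workdir, figures=figures)
            else:
                fn(cfg, workdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    evaluation = nio.read_json(workdir / "evaluation.json")
    importance = pd.read_csv(workdir / "importance.csv")
    bees = pd.read_csv(workdir / "beeswarm.csv")
    signs = (
        bees.drop_duplicates("feature")[["feature", "sign_spearman", "feature_rank"]]
        .set_index("feature")
        .to_dict("index")
    )
    planted = [feature_name(m, md) for m, md in cfg.effect_targets]
    tracked = ["evaluation.json", "importance.csv", "predictions.csv", "efficiency.csv",
               "features.csv", "attribution.csv", "beeswarm.csv", "biomarkers.tsv"]
    import xgboost

    report = {
        "evaluation": evaluation,
        "importance_top10": importance.head(10).to_dict("records"),
        "planted_features": {
            f: {
                "rank": signs[f]["feature_rank"] if f in signs else None,
                "sign_spearman": signs[f]["sign_spearman"] if f in signs else None,
            }
            for f in planted
        },
        "provenance": {
            "seed": cfg.seed,
            "stage_seeds": cfg.stage_seeds,
            "config": _plain(cfg.to_dict()),
            "hashes": {f: _sha256(workdir / f) for f in tracked},
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "xgboost": xgboost.__version__,
            },
        },
    }
    nio.write_json(report, workdir / "report.json")
    return report
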