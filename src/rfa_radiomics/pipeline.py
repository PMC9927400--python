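"""End-to-end orchestration: simulate -> preprocess/extract -> split ->
select -> train -> fuse/evaluate, with per-stage artifacts and derived seeds."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fuse_eval, models, select, split, synth
from .features import SELECTED_FEATURES, extract_feature_table, extraction_settings
from .preprocess import cube_preprocessor

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 17
    out_dir: str = "run"
    # synth
    n_lesions: int = 479
    texture_signal: str = "strong"
    effect_scale: float = 1.0
    image_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.25, 0.7, 0.7)
    # features
    n_bins: int = 32
    gldm_alpha: int = 0
    # split
    k_range: tuple[int, int] = (2, 8)
    n_groups: int = 5
    test_group: int | None = 1
    gmm_features: str = "selected"  # "selected" (fixed 9-name set) or "all"
    # select
    m_range: tuple[int, int] = (5, 15)
    selection_trees: int = 200
    # models
    rf_trees: int = 500
    smote_k: int = 5
    # evaluation
    stages: tuple[str, ...] = (
        "simulate", "extract", "split", "select", "train", "evaluate"
    )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def generator_config(self) -> synth.GeneratorConfig:
        return synth.GeneratorConfig(
            n_lesions=self.n_lesions,
            seed=self.seed,
            image_shape=tuple(self.image_shape),
            spacing_mm=tuple(self.spacing_mm),
            texture_signal=self.texture_signal,
            effect_scale=self.effect_scale,
        )


def _stage_seed(config: RunConfig, stage: str) -> int:
    digest = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class RunArtifacts:
    config: RunConfig
    cases: list = field(default_factory=list)
    clinical: pd.DataFrame | None = None
    feature_table: pd.DataFrame | None = None
    assignment: split.SplitAssignment | None = None
    rankings: list[select.RankingResult] = field(default_factory=list)
    consensus: select.ConsensusSelection | None = None
    screening: models.ScreeningResult | None = None
    models: dict[str, models.FittedModel] = field(default_factory=dict)
    design: dict[str, pd.DataFrame] = field(default_factory=dict)
    scores: dict[str, pd.Series] = field(default_factory=dict)
    report: fuse_eval.EvaluationReport | None = None


def run_all(config: RunConfig, write: bool = True) -> RunArtifacts:
    """Execute the configured stages in order; later stages require earlier ones."""
    art = RunArtifacts(config=config)
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.json", "w") as fh:
            json.dump({**asdict(config), "config_hash": config.hash()}, fh, indent=1)

    timings: dict[str, float] = {}

    def _timed(stage: str, fn):
        t0 = time.perf_counter()
        fn()
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.1fs", stage, timings[stage])

    if "simulate" in config.stages:
        _timed("simulate", lambda: _simulate(config, art))
    if "extract" in config.stages:
        _timed("extract", lambda: _extract(config, art, out if write else None))
    if "split" in config.stages:
        _timed("split", lambda: _split(config, art, out if write else None))
    if "select" in config.stages:
        _timed("select", lambda: _select(config, art, out if write else None))
    if "train" in config.stages:
        _timed("train", lambda: _train(config, art))
    if "evaluate" in config.stages:
        _timed("evaluate", lambda: _evaluate(config, art, out if write else None))

    if write:
        with open(out / "timings.json", "w") as fh:
            json.dump(timings, fh, indent=1)
    return art


def run_from_tables(
    config: RunConfig,
    feature_table: pd.DataFrame,
    clinical: pd.DataFrame,
    stages: tuple[str, ...] = ("split", "select", "train", "evaluate"),
    write: bool = True,
) -> RunArtifacts:
    """Resume the pipeline from persisted tables (features.csv + clinical.csv).

    Earlier analysis stages are re-run deterministically (stage seeds derive
    from the config seed), so each CLI verb can depend only on the tables.
    """
    art = RunArtifacts(config=config)
    art.feature_table = feature_table
    art.clinical = clinical
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    order = ("split", "select", "train", "evaluate")
    last = max(order.index(s) for s in stages)
    for stage in order[: last + 1]:
        if stage == "split":
            _split(config, art, out if write else None)
        elif stage == "select":
            _select(config, art, out if write else None)
        elif stage == "train":
            _train(config, art)
        elif stage == "evaluate":
            _evaluate(config, art, out if write else None)
    return art


def _simulate(config: RunConfig, art: RunArtifacts) -> None:
    cases, manifest = synth.generate_cohort(config.generator_config())
    art.cases = cases
    art.clinical = synth.clinical_frame(cases)


def _extract(config: RunConfig, art: RunArtifacts, out: Path | None) -> None:
    if not art.cases:
        raise RuntimeError("extract stage requires simulate (or a loaded cohort)")
    art.feature_table = extract_feature_table(
        art.cases,
        n_bins=config.n_bins,
        gldm_alpha=config.gldm_alpha,
        preprocessor=cube_preprocessor,
    )
    if out is not None:
        art.feature_table.to_csv(out / "features.csv")
        with open(out / "features_settings.json", "w") as fh:
            json.dump(dict(extraction_settings(config.n_bins, config.gldm_alpha)), fh)


def _split(config: RunConfig, art: RunArtifacts, out: Path | None) -> None:
    if art.feature_table is None:
        raise RuntimeError("split stage requires extract")
    cols = (
        [c for c in SELECTED_FEATURES if c in art.feature_table.columns]
        if config.gmm_features == "selected"
        else list(art.feature_table.columns)
    )
    feats = art.feature_table[cols]
    gmm = split.fit_gmm(feats, k_range=config.k_range, seed=_stage_seed(config, "split"))
    art.assignment = split.stratified_group_split(
        gmm,
        feats,
        art.clinical["label"],
        n_groups=config.n_groups,
        seed=_stage_seed(config, "split"),
        test_group=config.test_group,
    )
    if out is not None:
        art.assignment.table.to_csv(out / "split.csv")


def _select(config: RunConfig, art: RunArtifacts, out: Path | None) -> None:
    if art.assignment is None:
        raise RuntimeError("select stage requires split")
    train_ids = art.assignment.train_ids
    X = art.feature_table.loc[train_ids]
    y = (art.clinical.loc[train_ids, "label"] == "nonCR").to_numpy(int)
    seed = _stage_seed(config, "select")
    depth = max(config.m_range[1], 15)
    art.rankings = [
        select.mrmr_rank(X, y, criterion, depth=depth, seed=seed)
        for criterion in select.CRITERIA
    ]
    art.consensus = select.consensus_select(
        art.rankings,
        X,
        y,
        m_range=config.m_range,
        seed=seed,
        n_estimators=config.selection_trees,
    )
    if out is not None:
        pd.DataFrame(
            {r.criterion: pd.Series(r.order) for r in art.rankings}
        ).to_csv(out / "rankings.csv", index_label="rank")
        with open(out / "consensus.json", "w") as fh:
            json.dump(
                {
                    "frequency": art.consensus.frequency,
                    "chosen_set": art.consensus.chosen_set,
                    "chosen_m": art.consensus.chosen_m,
                    "cv_scores": art.consensus.cv_scores,
                },
                fh,
                indent=1,
            )


def _train(config: RunConfig, art: RunArtifacts) -> None:
    if art.consensus is None:
        raise RuntimeError("train stage requires select")
    train_ids = art.assignment.train_ids
    clinical_train = art.clinical.loc[train_ids]
    labels_train = clinical_train["label"]
    seed = _stage_seed(config, "train")

    screening = models.univariate_screen(clinical_train, labels_train)
    screening = models.multivariate_screen(
        clinical_train, labels_train, screening.retained_univariate, result=screening
    )
    art.screening = screening
    clin_vars = screening.retained_multivariate or screening.retained_univariate
    if not clin_vars:
        log.warning("no clinical variable retained; training on all covariates")
        clin_vars = list(models.CONTINUOUS_VARS) + ["gender", "location", "distance1",
                                                    "distance2", "pneumothorax", "iah"]
    X_clin = models.design_matrix(art.clinical, clin_vars)
    X_rad = art.feature_table[art.consensus.chosen_set]

    art.models = {
        "clinical": models.train_rf(
            X_clin.loc[train_ids], labels_train.to_numpy(), "clinical",
            seed=seed, n_estimators=config.rf_trees, smote_k=config.smote_k,
        ),
        "radiomics": models.train_rf(
            X_rad.loc[train_ids], labels_train.to_numpy(), "radiomics",
            seed=seed, n_estimators=config.rf_trees, smote_k=config.smote_k,
        ),
    }
    art.design = {"clinical": X_clin, "radiomics": X_rad}


def _evaluate(config: RunConfig, art: RunArtifacts, out: Path | None) -> None:
    if not getattr(art, "models", None):
        raise RuntimeError("evaluate stage requires train")
    test_ids = art.assignment.test_ids
    train_ids = art.assignment.train_ids
    labels = art.clinical["label"]

    test_scores = {
        kind: models.predict(model, art.design[kind].loc[test_ids])
        for kind, model in art.models.items()
    }
    train_scores = {
        kind: models.predict(model, art.design[kind].loc[train_ids])
        for kind, model in art.models.items()
    }
    # best omega is chosen on the training fold; the test-set grid is kept
    # as a report table only (tuning omega on the test set would bias the
    # fused AUC upward)
    _, best = fuse_eval.weight_scan(
        train_scores["radiomics"], train_scores["clinical"], labels.loc[train_ids]
    )
    grid, _ = fuse_eval.weight_scan(
        test_scores["radiomics"], test_scores["clinical"], labels.loc[test_ids]
    )
    test_scores["fused"] = fuse_eval.fuse(
        test_scores["radiomics"], test_scores["clinical"], best
    )
    train_scores["fused"] = fuse_eval.fuse(
        train_scores["radiomics"], train_scores["clinical"], best
    )
    report = fuse_eval.evaluate_models(
        test_scores, labels.loc[test_ids], train_scores, labels.loc[train_ids]
    )
    report.weight_grid = grid
    report.best_weights = best
    art.scores = test_scores
    art.report = report
    if out is not None:
        write_report(report, out)
        pd.DataFrame(test_scores).to_csv(out / "test_scores.csv")
        fuse_eval.plot_roc(test_scores, labels.loc[test_ids], out / "roc.png")


def write_report(report: fuse_eval.EvaluationReport, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, default=float)
    if report.weight_grid is not None:
        report.weight_grid.to_csv(out_dir / "weight_grid.csv", index=False)


def read_report(out_dir: Path) -> dict:
    with open(Path(out_dir) / "report.json") as fh:
        return json.load(fh)
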