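"""End-to-end pipeline runs: synthetic cohort -> tissue annotation ->
metastasis scoring -> slide features -> risk models -> survival.

A single :class:`PipelineConfig` drives every stage; every random draw
traces to a seed derived from ``config.seed`` and recorded in the run
manifest.  Stages execute in order and intermediate products are kept on
the result object so downstream stages (and the report) can be re-run
without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import eval_survival, met_classifier, risk_models, slide_features, synthgen
from ._nnet import TrainingSchedule
from .met_classifier import MET_TRAINING_SCHEDULE
from .tiling import CLASS_ORDER, TileImage, tile_slide
from .tissue_classifier import annotate_slide, cancer_region_jaccard, train_tissue_classifier

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report", "demo_config"]


@dataclass
class PipelineConfig:
    """Study conditions for one synthetic end-to-end run."""

    # cohort
    n_patients: int = 40
    n_slides: int = 47
    n_single_slide_patients: int = 34
    metastasis_fraction: float = 0.2
    planted_hazard_ratio: float = 4.0
    # slides
    grid: tuple[int, int] = (8, 8)
    tile_px: int = 64
    # tissue classifier
    tiles_per_class: int = 120
    tissue_hidden: tuple[int, ...] = (48,)
    tissue_lr: float = 0.05
    tissue_max_epochs: int = 40
    # met classifier
    met_hidden: tuple[int, ...] = (8,)
    met_lr: float = 0.05
    met_ensemble: int = 3  # seed-replicates per fold; tile scores averaged
    confidence_threshold: float = 0.95
    # risk modelling
    nested_threshold_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    inner_k: int = 10
    outer_trees: int = 500
    inner_trees: int = 100
    run_zoo: bool = False
    zoo_threshold_grid: tuple[float, ...] = (risk_models.REPLICATION_THRESHOLD,)
    # synthetic slides already live on the analysis grid, so no further
    # downsampling and no per-tile stain normalization are applied
    downsample: int = 1
    seed: int = 0

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> PipelineConfig:
    """The scaled-down demonstration conditions."""
    return PipelineConfig(seed=seed)


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: list
    tissue_model: object
    class_maps: dict
    score_maps: dict
    feature_table: pd.DataFrame
    reduced_table: pd.DataFrame
    nested_predictions: pd.DataFrame
    nested_manifest: dict
    patient_risk: dict
    metrics: dict
    survival: dict
    zoo_table: pd.DataFrame | None
    zoo_best: dict | None
    manifest: dict


def _derive_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on a synthetic cohort and return all products."""
    seeds = {
        stage: _derive_seed(config.seed, stage)
        for stage in (
            "cohort", "tissue_tiles", "tissue_train", "layout",
            "folds", "met_train", "impute", "nested",
        )
    }

    # -- stage: synthetic cohort ------------------------------------------
    cohort = synthgen.make_cohort(
        synthgen.CohortConfig(
            n_patients=config.n_patients,
            n_slides=config.n_slides,
            n_single_slide_patients=config.n_single_slide_patients,
            metastasis_fraction=config.metastasis_fraction,
            planted_hazard_ratio=config.planted_hazard_ratio,
            seed=seeds["cohort"],
        )
    )
    patient_of_slide = {s: p.patient_id for p in cohort for s in p.slide_ids}
    label_of_patient = {p.patient_id: int(p.metastasis) for p in cohort}

    # -- stage: tissue classifier training --------------------------------
    # ground-truth annotation tiles are drawn from the cohort's own slide
    # population, so both outcome groups' textures are represented in
    # proportion to the metastasis fraction
    rng = np.random.default_rng(seeds["tissue_tiles"])
    shifted = synthgen.shifted_textures(synthgen.DEFAULT_TEXTURES, metastatic=True)
    train_tiles: list[TileImage] = []
    train_labels: list[str] = []
    for cls in CLASS_ORDER:
        for _ in range(config.tiles_per_class):
            met_source = rng.random() < config.metastasis_fraction
            params = (shifted if met_source else synthgen.DEFAULT_TEXTURES)[cls]
            t = synthgen.make_texture_tile(
                params, size=config.tile_px, seed=int(rng.integers(0, 2**31 - 1))
            )
            train_tiles.append(t)
            train_labels.append(cls)
    tissue_schedule = TrainingSchedule(
        learning_rate=config.tissue_lr,
        max_epochs=config.tissue_max_epochs,
        per_class_accuracy_stop=0.99,
        seed=seeds["tissue_train"],
    )
    tissue_model = train_tissue_classifier(
        train_tiles, train_labels, tissue_schedule, hidden_dims=config.tissue_hidden
    )

    # -- stage: render + annotate slides ----------------------------------
    layout_rng = np.random.default_rng(seeds["layout"])
    class_maps: dict[str, object] = {}
    tilings: dict[str, object] = {}
    truth: dict[str, list] = {}
    for p in cohort:
        textures = synthgen.shifted_textures(synthgen.DEFAULT_TEXTURES, p.metastasis)
        for sid in p.slide_ids:
            slide, annots, _ = synthgen.make_synthetic_slide(
                layout_seed=int(layout_rng.integers(0, 2**31 - 1)),
                texture_set=textures,
                grid=config.grid,
                tile_px=config.tile_px,
                slide_id=sid,
            )
            tiling = tile_slide(
                slide,
                tile_size=config.tile_px,
                downsample=config.downsample,
                slide_id=sid,
            )
            tilings[sid] = tiling
            truth[sid] = annots
            class_maps[sid] = annotate_slide(tissue_model, slide, slide_id=sid, tiling=tiling)

    # -- stage: metastasis association classifiers ------------------------
    folds = met_classifier.grouped_kfold(
        [p.patient_id for p in cohort],
        {p.patient_id: p.slide_ids for p in cohort},
        k=5,
        seed=seeds["folds"],
    )
    met_schedule = TrainingSchedule(
        learning_rate=config.met_lr,
        momentum=MET_TRAINING_SCHEDULE.momentum,
        batch_size=MET_TRAINING_SCHEDULE.batch_size,
        max_epochs=MET_TRAINING_SCHEDULE.max_epochs,
        per_class_accuracy_stop=None,
        lr_decay_factor=MET_TRAINING_SCHEDULE.lr_decay_factor,
        lr_decay_after_epochs=MET_TRAINING_SCHEDULE.lr_decay_after_epochs,
        l2_penalty=MET_TRAINING_SCHEDULE.l2_penalty,
        seed=seeds["met_train"],
    )
    selected: dict[tuple[str, str], np.ndarray] = {}
    for sid, cmap in class_maps.items():
        for comp in met_classifier.COMPARTMENTS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected[(sid, comp)] = met_classifier.select_high_confidence_tiles(
                    cmap, comp, threshold=config.confidence_threshold
                )

    def _tiles_at(sid: str, mask: np.ndarray) -> list[TileImage]:
        return [t for t in tilings[sid].tiles if mask[t.grid_row, t.grid_col]]

    score_maps: dict[tuple[str, str], met_classifier.MetScoreMap] = {}
    for comp in met_classifier.COMPARTMENTS:
        for fold in range(folds.k):
            fit_tiles: list[TileImage] = []
            fit_labels: list[int] = []
            for sid in folds.training_slides(fold):
                lbl = label_of_patient[folds.patient_of_slide[sid]]
                tiles = _tiles_at(sid, selected[(sid, comp)])
                fit_tiles += tiles
                fit_labels += [lbl] * len(tiles)
            if len(set(fit_labels)) < 2:
                warnings.warn(f"fold {fold}: single-class training set for {comp}")
                continue
            # small seed-ensemble per fold: averaging tile scores damps the
            # run-to-run calibration offset of individual networks
            models = []
            for rep in range(max(1, config.met_ensemble)):
                rep_schedule = TrainingSchedule(
                    **{**asdict(met_schedule), "seed": _derive_seed(met_schedule.seed, f"{comp}:{fold}:{rep}")}
                )
                models.append(
                    met_classifier.train_met_classifier(
                        fit_tiles, fit_labels, rep_schedule, hidden_dims=config.met_hidden
                    )
                )
            for sid in folds.validation_slides(fold):
                tiles = _tiles_at(sid, selected[(sid, comp)])
                if tiles:
                    mean_scores = np.mean([m.score(tiles) for m in models], axis=0)
                else:
                    mean_scores = np.zeros(0)
                scores = np.zeros(tilings[sid].grid_shape)
                mask = np.zeros(tilings[sid].grid_shape, dtype=bool)
                for t, s in zip(tiles, mean_scores):
                    scores[t.grid_row, t.grid_col] = s
                    mask[t.grid_row, t.grid_col] = True
                score_maps[(sid, comp)] = met_classifier.MetScoreMap(
                    scores=scores, valid_mask=mask, compartment=comp, slide_id=sid
                )

    # -- stage: slide features ---------------------------------------------
    slide_ids = sorted(patient_of_slide)

    def _map_or_empty(sid: str, comp: str) -> met_classifier.MetScoreMap:
        # slides from a skipped (single-class) training fold carry no
        # scores; they enter feature extraction as an empty compartment
        if (sid, comp) in score_maps:
            return score_maps[(sid, comp)]
        shape = tilings[sid].grid_shape
        return met_classifier.MetScoreMap(
            scores=np.zeros(shape), valid_mask=np.zeros(shape, bool),
            compartment=comp, slide_id=sid,
        )

    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid in slide_ids:
            cmap = slide_features.neighbor_filter(_map_or_empty(sid, "CANCER"))
            smap = slide_features.neighbor_filter(_map_or_empty(sid, "STROMA"))
            rows[sid] = slide_features.extract_slide_features(cmap, smap)
    feature_table = pd.DataFrame(rows).T
    feature_table.index.name = "slide_id"
    dead = [c for c in feature_table.columns if feature_table[c].isna().all()]
    filled = feature_table.copy()
    filled[dead] = 0.0  # features never observed under these conditions
    feature_table_imputed = slide_features.impute_missing(filled, seed=seeds["impute"])
    reduced = slide_features.reduced_feature_table(feature_table_imputed)

    # -- stage: risk models -------------------------------------------------
    slide_series = pd.Series({s: patient_of_slide[s] for s in slide_ids})
    label_series = pd.Series(
        {s: label_of_patient[patient_of_slide[s]] for s in slide_ids}
    )
    nested_preds, nested_manifest = risk_models.nested_loocv(
        reduced,
        label_series,
        slide_series,
        threshold_grid=config.nested_threshold_grid,
        inner_k=config.inner_k,
        seed=seeds["nested"],
        n_estimators=config.outer_trees,
        inner_n_estimators=config.inner_trees,
    )
    patient_risk = risk_models.aggregate_patient_risk(
        nested_preds["prediction"].to_dict(), patient_of_slide
    )

    zoo_table = zoo_best = None
    if config.run_zoo:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zoo_table, zoo_best = risk_models.run_model_zoo_loocv(
                feature_table_imputed,
                label_series,
                slide_series,
                threshold_grid=config.zoo_threshold_grid,
            )

    # -- stage: evaluation / survival ---------------------------------------
    y_true = np.array([label_of_patient[p] for p in patient_risk])
    y_pred = np.array([patient_risk[p] for p in patient_risk])
    conf = eval_survival.ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )
    metrics = eval_survival.confusion_metrics(conf).as_dict()
    metrics["n_high_risk"] = int(y_pred.sum())
    metrics["n_low_risk"] = int((1 - y_pred).sum())
    metrics["median_cancer_jaccard"] = float(
        np.median(
            [
                cancer_region_jaccard(
                    class_maps[sid], truth[sid], tile_size=config.tile_px,
                    downsample=config.downsample,
                )
                for sid in slide_ids
            ]
        )
    )

    clin = synthgen.cohort_to_frame(cohort).set_index("patient_id")
    clin["risk_group"] = pd.Series(patient_risk)
    survival: dict = {}
    # detectability of the planted hazard effect in this cohort draw
    if 0 < clin["metastasis"].sum() < len(clin):
        _, pl_stat, pl_p = eval_survival.km_logrank(
            clin["time_months"].values, clin["event"].values.astype(bool),
            clin["metastasis"].values,
        )
        survival["planted_logrank_p"] = pl_p
    if 0 < clin["risk_group"].sum() < len(clin):
        curves, stat, p = eval_survival.km_logrank(
            clin["time_months"].values, clin["event"].values.astype(bool),
            clin["risk_group"].values,
        )
        survival["logrank_statistic"] = stat
        survival["logrank_p"] = p
        try:
            cox = eval_survival.cox_ph(clin)
            survival["cox_summary"] = cox
            survival["risk_group_hr"] = float(cox.loc["risk_group", "hazard_ratio"])
            survival["risk_group_wald_p"] = float(cox.loc["risk_group", "wald_p"])
        except Exception as exc:  # separation / convergence on tiny cohorts
            survival["cox_error"] = str(exc)
    else:
        survival["degenerate_risk_groups"] = True

    manifest = {
        "config_hash": config.content_hash(),
        "config": asdict(config),
        "seeds": seeds,
        "fold_of_slide": folds.fold_of_slide,
        "nested_selected_thresholds": {
            k: v["selected_threshold"] for k, v in nested_manifest.items()
        },
        "n_features": int(feature_table.shape[1]),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return PipelineResult(
        config=config,
        cohort=cohort,
        tissue_model=tissue_model,
        class_maps=class_maps,
        score_maps=score_maps,
        feature_table=feature_table_imputed,
        reduced_table=reduced,
        nested_predictions=nested_preds,
        nested_manifest=nested_manifest,
        patient_risk=patient_risk,
        metrics=metrics,
        survival=survival,
        zoo_table=zoo_table,
        zoo_best=zoo_best,
        manifest=manifest,
    )


def write_report(result: PipelineResult) -> str:
    """Human-readable run summary (byte-reproducible from the same outputs)."""
    lines = [
        "PanNET metastasis-risk pipeline report",
        "=" * 40,
        f"config hash: {result.manifest['config_hash']}",
        f"patients: {len(result.cohort)}  slides: {len(result.nested_predictions)}",
        "",
        f"feature schema ({result.feature_table.shape[1]} features):",
    ]
    lines += [f"  {name}" for name in result.feature_table.columns]
    lines.append("")
    lines.append("nested LOOCV selected thresholds per left-out patient:")
    for pid, thr in sorted(result.manifest["nested_selected_thresholds"].items()):
        lines.append(f"  {pid}: {thr}")
    lines.append("")
    lines.append("patient-level classification metrics:")
    for k, v in result.metrics.items():
        lines.append(f"  {k}: {v:.4f}" if isinstance(v, float) else f"  {k}: {v}")
    if result.metrics.get("n_high_risk", 0) == 0 or result.metrics.get("n_low_risk", 0) == 0:
        lines.append("  WARNING: one risk group is empty")
    lines.append("")
    lines.append("survival analysis:")
    for k, v in result.survival.items():
        if isinstance(v, float):
            lines.append(f"  {k}: {v:.5f}")
        elif isinstance(v, pd.DataFrame):
            lines.append(f"  {k}:")
            lines += ["    " + ln for ln in v.to_string().splitlines()]
        else:
            lines.append(f"  {k}: {v}")
    if result.zoo_best is not None:
        lines.append("")
        lines.append(
            "model zoo best configuration: "
            f"{result.zoo_best['model']} / {result.zoo_best['subset']} / "
            f"t>{result.zoo_best['threshold']} "
            f"(slide accuracy {result.zoo_best['accuracy']:.4f})"
        )
    return "\n".join(lines) + "\n"


def save_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Persist the run products (CSV tables, JSON manifest, report)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.feature_table.to_csv(out / "slide_features.csv")
    result.nested_predictions.to_csv(out / "nested_predictions.csv")
    pd.Series(result.patient_risk, name="risk_group").rename_axis("patient_id").to_csv(
        out / "patient_risk.csv"
    )
    synthgen.cohort_to_frame(result.cohort).to_csv(out / "cohort.csv", index=False)
    (out / "run_manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
    (out / "report.txt").write_text(write_report(result))
    return out
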