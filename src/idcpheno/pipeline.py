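"""End-to-end pipeline orchestration with a single config and a run manifest.

Stages run in the field-workflow order: segment -> colorize -> extract ->
train/score -> assess -> trials.  Every output lands in one directory and a
``manifest.json`` records the package version, seeds, stage parameters,
per-stage summary statistics and SHA-256 checksums of every file written, so
two runs with the same config are byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from importlib.metadata import PackageNotFoundError, version as _dist_version

from idcpheno.accuracy import (
    build_error_matrix,
    equalized_random_sample,
    label_points_from_truth,
)
from idcpheno.colors import classify_canopy_colors
from idcpheno.features import extract_plot_features
from idcpheno.io import (
    read_class_raster,
    read_orthomosaic,
    read_plot_polygons,
    write_class_raster,
)
from idcpheno.scoring import (
    FEATURES,
    adjacent_misclassification_fraction,
    binned_accuracy,
    evaluate,
    split_train_validation,
    train_neural_network,
    train_random_forest,
)
from idcpheno.segmentation import segment_canopy
from idcpheno.trials import compare_lsds, lsd_results_frame, trial_lsd_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full pipeline run."""

    raster: str
    plots: str
    scores: str  # CSV with plot_id + visual score column
    out_dir: str
    truth_raster: str | None = None  # optional: enables automatic assessment
    score_col: str = "visual_score"
    k_segment: int = 5
    k_colors: int = 3
    seed: int = 0
    recode_threshold: float = 0.0
    validation_fraction: float = 0.33
    model: str = "rf"  # "rf" | "nn"
    n_sample_points: int = 500
    alpha: float = 0.20
    lsd_mode: str = "paper"

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {json.dumps(getattr(self, f.name))}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = json.loads(val.strip())
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = _dist_version("idcpheno")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest: dict = {
        "package_version": pkg_version,
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    def _stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    def _done(name, t0, **summary):
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **summary,
        }

    # ---- io ---------------------------------------------------------------
    t0 = _stage("io")
    try:
        raster = read_orthomosaic(config.raster)
        plots = read_plot_polygons(config.plots, raster=raster)
        scores_df = pd.read_csv(config.scores)
        if "plot_id" not in scores_df or config.score_col not in scores_df:
            raise ValueError(
                f"scores CSV needs columns plot_id and {config.score_col}"
            )
    except Exception as exc:  # noqa: BLE001 - stage context requested
        raise StageError("io", exc) from exc
    _done("io", t0, n_plots=len(plots), raster_shape=list(raster.shape))

    # ---- segment ----------------------------------------------------------
    t0 = _stage("segment")
    try:
        mask, index, seg_model = segment_canopy(
            raster, k=config.k_segment, seed=config.seed,
            threshold=config.recode_threshold,
        )
        write_class_raster(out / "mask.tif", mask.mask, mask.transform, mask.crs,
                           description=json.dumps(mask.provenance))
    except Exception as exc:
        raise StageError("segment", exc) from exc
    _done("segment", t0, plant_fraction=float(mask.mask.mean()),
          centroids=[float(c) for c in np.atleast_1d(seg_model.centroids)],
          n_degenerate_index_pixels=index.n_degenerate)

    # ---- colorize ---------------------------------------------------------
    t0 = _stage("colorize")
    try:
        colors, color_model = classify_canopy_colors(
            raster, mask, k=config.k_colors, seed=config.seed
        )
        write_class_raster(out / "colors.tif", colors.labels, colors.transform,
                           colors.crs, description=json.dumps(colors.provenance))
        (out / "colors_provenance.json").write_text(
            json.dumps(colors.provenance, indent=2)
        )
    except Exception as exc:
        raise StageError("colorize", exc) from exc
    _done("colorize", t0, cluster_labels=colors.provenance["cluster_labels"])

    # ---- extract ----------------------------------------------------------
    t0 = _stage("extract")
    try:
        features = extract_plot_features(colors, mask, plots)
        features.to_csv(out / "features.csv", index=False)
    except Exception as exc:
        raise StageError("extract", exc) from exc
    _done("extract", t0, n_plots=len(features),
          mean_coverage=float(features["canopy_coverage"].mean()))

    # ---- train / score ----------------------------------------------------
    t0 = _stage("train")
    try:
        data = features.merge(
            scores_df[["plot_id", config.score_col]], on="plot_id", how="inner"
        ).rename(columns={config.score_col: "score"})
        data = data.dropna(subset=FEATURES + ["score"])
        data["score"] = data["score"].astype(int)
        data = split_train_validation(
            data, validation_fraction=config.validation_fraction, seed=config.seed
        )
        train = data[data["partition"] == "train"]
        valid = data[data["partition"] == "validation"]
        if config.model == "rf":
            clf = train_random_forest(train, seed=config.seed)
        elif config.model == "nn":
            clf = train_neural_network(train, seed=config.seed)
        else:
            raise ValueError(f"unknown model {config.model!r}")
        cm = evaluate(clf, valid)
        acc2, _ = binned_accuracy(
            valid["score"].to_numpy(), clf.predict(valid[FEATURES].to_numpy())
        )
        preds = features.dropna(subset=FEATURES).copy()
        preds["uas_score"] = clf.predict(preds[FEATURES].to_numpy()).astype(int)
        preds = preds[["plot_id", "trial_id", "entry_id", "block_id", "uas_score"]]
        preds.to_csv(out / "predictions.csv", index=False)
        cm.counts.to_csv(out / "confusion_counts.csv")
        (out / "confusion_report.txt").write_text(cm.report())
    except Exception as exc:
        raise StageError("train", exc) from exc
    _done("train", t0, model=config.model,
          validation_accuracy_pct=cm.overall_accuracy,
          binned_accuracy_pct=acc2,
          adjacent_misclassification_fraction=
          adjacent_misclassification_fraction(cm),
          n_train=len(train), n_validation=len(valid))

    # ---- assess -----------------------------------------------------------
    if config.truth_raster is not None:
        t0 = _stage("assess")
        try:
            truth, _, _ = read_class_raster(config.truth_raster)
            truth_mask = (truth > 0).astype(np.uint8)
            points = equalized_random_sample(
                mask.mask, config.n_sample_points, seed=config.seed
            )
            points = label_points_from_truth(points, truth_mask)
            em = build_error_matrix(points=points, classes=[0, 1])
            points.to_csv(out / "sample_points.csv", index=False)
            em.counts.to_csv(out / "error_matrix.csv")
            (out / "error_matrix_report.txt").write_text(em.report())
        except Exception as exc:
            raise StageError("assess", exc) from exc
        _done("assess", t0, overall_accuracy_pct=em.overall_accuracy,
              user_accuracy_pct=em.user_accuracy.to_dict(),
              producer_accuracy_pct=em.producer_accuracy.to_dict())

    # ---- trials -----------------------------------------------------------
    t0 = _stage("trials")
    try:
        merged = scores_df.merge(preds, on="plot_id", suffixes=("", "_pred"))
        for col in ("trial_id", "entry_id", "block_id"):
            if col not in merged:
                raise ValueError(f"scores CSV or predictions lack column {col}")
        vis = trial_lsd_table(merged, config.score_col, "visual",
                              alpha=config.alpha, mode=config.lsd_mode)
        uas = trial_lsd_table(merged, "uas_score", "uas",
                              alpha=config.alpha, mode=config.lsd_mode)
        comp = compare_lsds(vis, uas)
        pd.concat([lsd_results_frame(vis), lsd_results_frame(uas)]).to_csv(
            out / "trials.csv", index=False
        )
        comp.table.to_csv(out / "lsd_comparison.csv", index=False)
    except Exception as exc:
        raise StageError("trials", exc) from exc
    _done("trials", t0, n_trials=comp.n_trials, n_uas_lower=comp.n_uas_lower,
          mean_lsd_difference=comp.mean_difference)

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
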