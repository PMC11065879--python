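"""End-to-end orchestration: simulate -> migrate -> featurize -> train
-> predict -> postprocess -> validate.

Each stage writes its artifacts into a run directory and the run
manifest records seeds, configuration and the sample counts at every
filter stage, so a rerun with the same configuration reproduces
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ClassifierConfig,
    ClassifierResult,
    SoybeanClassifier,
    export_soybean_map,
    majority_filter,
)
from .features import extract_features, feature_manifest, select_features
from .io import (
    frame_to_optical,
    frame_to_sar,
    optical_to_frame,
    read_table,
    sar_to_frame,
    write_table,
)
from .metrics import ConfusionMatrix, accuracy_metrics
from .migration import MigrationConfig, MigrationResult, SoybeanMigration
from .points import read_geojson, write_geojson
from .prep import TemporalGrid
from .raster import Raster, read_ascii_grid, write_ascii_grid
from .synthetic import Scene, simulate_region


@dataclass
class PipelineConfig:
    """Single configuration object for a full run (YAML-serializable)."""

    seed: int = 1
    # scene
    n_per_crop: dict[str, int] = field(
        default_factory=lambda: {"soybean": 200, "corn": 200,
                                 "rice": 200, "peanut": 200}
    )
    n_reference: int = 80
    separation: float = 1.0
    noise_sigma: float | None = None
    # temporal grid / smoothing
    grid_start_doy: int = 90
    grid_end_doy: int = 318
    grid_step_days: int = 10
    sg_window: int = 7
    sg_order: int = 2
    osavi_standard: bool = False
    # migration thresholds
    soy_percentile: float = 90.0
    nonsoy_percentile: float = 95.0
    n_mc: int = 100_000
    min_reference: int = 30
    # classification protocol
    rf_seed: int = 999
    feature_fraction: float = 0.5
    # demonstration map
    map_size_px: int = 60
    map_patch_px: int = 6

    @property
    def grid(self) -> TemporalGrid:
        return TemporalGrid(self.grid_start_doy, self.grid_end_doy,
                            self.grid_step_days)

    def migration_config(self) -> MigrationConfig:
        return MigrationConfig(
            grid=self.grid, sg_window=self.sg_window, sg_order=self.sg_order,
            osavi_standard=self.osavi_standard,
            soy_percentile=self.soy_percentile,
            nonsoy_percentile=self.nonsoy_percentile,
            n_mc=self.n_mc, min_reference=self.min_reference, seed=self.seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig, rundir: Path) -> Scene:
    scene = simulate_region(
        dict(cfg.n_per_crop), cfg.seed, n_reference=cfg.n_reference,
        separation=cfg.separation, noise_sigma=cfg.noise_sigma,
    )
    write_geojson(scene.points, rundir / "points.geojson")
    write_table(optical_to_frame(scene.optical), rundir / "optical.csv")
    write_table(sar_to_frame(scene.sar), rundir / "sar.csv")
    pd.DataFrame(
        {"id": list(scene.truth), "crop": list(scene.truth.values())}
    ).to_csv(rundir / "truth.csv", index=False)
    (rundir / "reference_ids.json").write_text(
        json.dumps(scene.reference_ids))
    write_ascii_grid(scene.landcover, rundir / "landcover.asc")
    return scene


def load_scene(rundir: Path) -> Scene:
    points = read_geojson(rundir / "points.geojson")
    optical = frame_to_optical(read_table(rundir / "optical.csv"))
    sar = frame_to_sar(read_table(rundir / "sar.csv"))
    truth_df = pd.read_csv(rundir / "truth.csv")
    truth = dict(zip(truth_df["id"], truth_df["crop"]))
    reference_ids = json.loads((rundir / "reference_ids.json").read_text())
    landcover = read_ascii_grid(rundir / "landcover.asc")
    year = points[0].year if points else 2019
    region = points[0].region if points else "R1"
    return Scene(points=points, optical=optical, sar=sar, truth=truth,
                 reference_ids=reference_ids, landcover=landcover,
                 year=year, region=region)


def stage_migrate(cfg: PipelineConfig, rundir: Path,
                  scene: Scene) -> MigrationResult:
    result = SoybeanMigration.from_scene(scene, cfg.migration_config()).fit()
    result.save(rundir)
    write_geojson(result.labelled_points, rundir / "labelled_points.geojson")
    return result


def stage_featurize(cfg: PipelineConfig, rundir: Path,
                    scene: Scene, migration: MigrationResult) -> pd.DataFrame:
    ids = [r.point.id for r in migration.records]
    table = extract_features(
        ids, scene.optical, scene.sar, cfg.grid,
        window=cfg.sg_window, order=cfg.sg_order,
        osavi_standard=cfg.osavi_standard,
    )
    write_table(table.reset_index(names="id"), rundir / "features.csv")
    (rundir / "feature_manifest.json").write_text(
        json.dumps(feature_manifest(table), indent=1))
    return table


def stage_train(cfg: PipelineConfig, rundir: Path, features: pd.DataFrame,
                migration: MigrationResult) -> ClassifierResult:
    labels = {
        r.point.id: r.decision for r in migration.records
        if r.decision != "cropland_unknown" and r.point.id in features.index
    }
    train_tab = features.loc[list(labels)]
    y = [labels[i] for i in train_tab.index]
    selected = select_features(
        train_tab, y, fraction=cfg.feature_fraction, seed=cfg.rf_seed
    )
    clf = SoybeanClassifier(
        train_tab, pd.Series(y, index=train_tab.index),
        config=ClassifierConfig(seed=cfg.rf_seed, split_seed=cfg.seed,
                                feature_fraction=cfg.feature_fraction),
    )
    result = clf.fit(selected_features=selected)
    record = {
        "tree_count": result.tree_count,
        "accuracy_curve": {str(k): v for k, v in result.accuracy_curve.items()},
        "selected_features": result.feature_names,
        "train_ids": result.train_ids,
        "test_ids": result.test_ids,
        "rf_seed": cfg.rf_seed,
    }
    (rundir / "classifier.json").write_text(
        json.dumps(record, indent=1, sort_keys=True))
    return result


def _demonstration_map(
    cfg: PipelineConfig, scene: Scene, features: pd.DataFrame,
    clf: ClassifierResult, seed: int,
) -> tuple[Raster, Raster]:
    """Rasterized scene: crop patches whose pixels borrow sample features.

    Returns (predicted raster, truth raster); truth encodes soybean=1.
    """
    rng = np.random.default_rng(seed + 17)
    n = cfg.map_size_px
    n_patch = max(1, n // cfg.map_patch_px)
    crops = sorted(set(scene.truth.values()))
    ids_by_crop = {
        c: [i for i in features.index if scene.truth.get(i) == c]
        for c in crops
    }
    seeds_rc = rng.random((n_patch * n_patch, 2)) * n
    seed_crop = rng.choice(crops, size=seeds_rc.shape[0])
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    pix = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    d2 = ((pix[:, None, :] - seeds_rc[None, :, :]) ** 2).sum(axis=2)
    patch = np.argmin(d2, axis=1)
    pix_crop = seed_crop[patch]
    chosen = np.array(
        [rng.choice(ids_by_crop[c]) for c in pix_crop], dtype=object
    )
    template = Raster(data=np.zeros((n, n)), x_origin=0, y_origin=n * 10.0,
                      cell_size=10.0, nodata=-9999)
    stack = {
        c: features.loc[list(chosen), c].to_numpy().reshape(n, n)
        for c in clf.feature_names
    }
    predicted = clf.predict_raster(stack, template)
    truth = template.copy_with(
        (pix_crop == "soybean").astype(float).reshape(n, n))
    return predicted, truth


def stage_predict_postprocess(
    cfg: PipelineConfig, rundir: Path, scene: Scene,
    features: pd.DataFrame, clf: ClassifierResult,
) -> dict[str, Raster]:
    pre, truth_map = _demonstration_map(cfg, scene, features, clf, cfg.seed)
    post = majority_filter(pre)
    write_ascii_grid(pre, rundir / "map_raw.asc")
    write_ascii_grid(post, rundir / "map_filtered.asc")
    write_ascii_grid(export_soybean_map(post), rundir / "map_soybean.asc")
    write_ascii_grid(truth_map, rundir / "map_truth.asc")
    return {"pre": pre, "post": post, "truth": truth_map}


def stage_validate(
    cfg: PipelineConfig, rundir: Path, scene: Scene,
    features: pd.DataFrame, clf: ClassifierResult,
    maps: dict[str, Raster],
) -> dict:
    test_ids = [i for i in clf.test_ids if i in features.index]
    pred = clf.predict(features.loc[test_ids])
    truth_lbl = pd.Series(
        ["soybean" if scene.truth[i] == "soybean" else "non_soybean"
         for i in test_ids], index=test_ids,
    )
    migrated_lbl = clf.model.labels.loc[test_ids]
    cm_truth = ConfusionMatrix.from_labels(truth_lbl, pred)
    cm_heldout = ConfusionMatrix.from_labels(migrated_lbl, pred)
    valid = maps["truth"].data != maps["truth"].nodata
    map_pred = maps["post"].data[valid] == 1
    map_true = maps["truth"].data[valid] == 1
    cm_map = ConfusionMatrix(
        tp=int(np.sum(map_pred & map_true)),
        fp=int(np.sum(map_pred & ~map_true)),
        fn=int(np.sum(~map_pred & map_true)),
        tn=int(np.sum(~map_pred & ~map_true)),
    )
    changed = int(np.sum(maps["pre"].data != maps["post"].data))
    report = {
        "held_out_vs_truth": accuracy_metrics(cm_truth),
        "held_out_vs_migrated_labels": accuracy_metrics(cm_heldout),
        "map_vs_truth": accuracy_metrics(cm_map),
        "map_pixels_changed_by_filter": changed,
        "n_test": len(test_ids),
    }
    (rundir / "metrics.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    return report


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and return the validation report."""
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(rundir / "config.yaml")
    scene = stage_simulate(cfg, rundir)
    migration = stage_migrate(cfg, rundir, scene)
    features = stage_featurize(cfg, rundir, scene, migration)
    clf = stage_train(cfg, rundir, features, migration)
    maps = stage_predict_postprocess(cfg, rundir, scene, features, clf)
    report = stage_validate(cfg, rundir, scene, features, clf, maps)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "rf_seed": cfg.rf_seed,
        "stage_counts": migration.stage_counts,
        "tree_count": clf.tree_count,
        "n_features_selected": len(clf.feature_names),
        "precision_vs_truth": migration.precision_against(scene.truth),
    }
    (rundir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return report
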