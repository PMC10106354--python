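"""End-to-end orchestration: scene -> features -> segments -> land cover ->
indicators -> composite -> report, with YAML configuration and file outputs.

Every stage is also callable directly from the library; this module wires
them together, tags failures with the stage that raised them, and writes
the artifact directory (rasters, tables, legend, effective config, log).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls_mod
from .classify import NN_FEATURES, RuleThresholds, train_nn
from .features import TextureParams, ndvi, ndwi, texture_mean_euclidean
from .grid import (
    GridGeometry,
    Raster,
    read_geojson_polygons,
    read_geojson_polyline,
    read_raster,
    slope_degrees,
    write_geojson_polygons,
    write_geojson_polyline,
    write_raster,
)
from .indicators import IndicatorConfig, all_indicators, connectivity_indicator
from .landcover import CLASS_IDS, LandCoverMap
from .mca import MCAConfig, combine_wlc, reclassify, zonal_report
from .scene import (
    BuildingSpec,
    FarmSpec,
    PalmCrownSpec,
    RiverSpec,
    SceneBundle,
    SceneConfig,
    WaterBodySpec,
    generate_scene,
    training_samples,
)
from .segmentation import SegmentationParams, SegmentMap, extract_features, segment_image

__all__ = [
    "load_config",
    "scene_config_from_dict",
    "classify_scene",
    "evaluate_scene",
    "run_pipeline",
    "write_scene",
    "read_scene",
]


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged, not silenced
                raise StageError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def scene_config_from_dict(d: dict) -> SceneConfig:
    d = dict(d or {})
    kwargs = {}
    if "seed" in d:
        kwargs["seed"] = int(d["seed"])
    if "geometry" in d:
        kwargs["geometry"] = GridGeometry(**d["geometry"])
    for key, cls in (
        ("palm_crown", PalmCrownSpec),
        ("building_spec", BuildingSpec),
        ("river_spec", RiverSpec),
        ("farm_spec", FarmSpec),
    ):
        if key in d:
            kwargs[key] = cls(**d[key])
    if "water_spec" in d:
        kwargs["water_spec"] = [WaterBodySpec(**w) for w in d["water_spec"]]
    for key in ("spectra", "class_fractions", "tile_cells"):
        if key in d:
            kwargs[key] = d[key]
    return SceneConfig(**kwargs)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _params_from_config(cfg: dict):
    seg = SegmentationParams(**cfg.get("segmentation", {}))
    tex = TextureParams(**cfg.get("texture", {}))
    thr_d = dict(cfg.get("thresholds", {}))
    if "building_red_range" in thr_d:
        thr_d["building_red_range"] = tuple(thr_d["building_red_range"])
    thr = RuleThresholds(**thr_d)
    ind_d = dict(cfg.get("indicators", {}))
    for key in (
        "erosion_bounds_deg",
        "riparian_river_bounds_m",
        "clarity_bounds",
        "sinuosity_bounds",
        "connectivity_bounds_m",
        "natural_classes",
    ):
        if key in ind_d:
            ind_d[key] = tuple(ind_d[key])
    ind = IndicatorConfig(**ind_d)
    mca_d = dict(cfg.get("mca", {}))
    for key in ("reclass_breaks", "summary3_edges"):
        if key in mca_d:
            mca_d[key] = tuple(mca_d[key])
    mca = MCAConfig(**mca_d)
    return seg, tex, thr, ind, mca


# ---------------------------------------------------------------------------
# scene bundle I/O
# ---------------------------------------------------------------------------

def write_scene(bundle: SceneBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster(bundle.ortho, out / "ortho.tif")
    write_raster(bundle.dsm, out / "dsm.tif")
    write_raster(bundle.dtm, out / "dtm.tif")
    write_raster(bundle.truth.classes, out / "truth.tif")
    write_geojson_polygons(bundle.farms, out / "farms.geojson")
    write_geojson_polygons(bundle.water_bodies, out / "water_bodies.geojson")
    write_geojson_polyline(bundle.channel, out / "channel.geojson")
    with open(out / "legend.json", "w") as fh:
        json.dump(CLASS_IDS, fh, indent=2)


def read_scene(scene_dir, config: SceneConfig | None = None) -> SceneBundle:
    p = Path(scene_dir)
    truth_path = p / "truth.tif"
    truth = (
        LandCoverMap(read_raster(truth_path)) if truth_path.exists() else None
    )
    # channel / water bodies / farms may legitimately be absent from a survey
    channel = (
        read_geojson_polyline(p / "channel.geojson")
        if (p / "channel.geojson").exists()
        else None
    )
    water = (
        read_geojson_polygons(p / "water_bodies.geojson", role="water_body")
        if (p / "water_bodies.geojson").exists()
        else None
    )
    farms = (
        read_geojson_polygons(p / "farms.geojson", role="farm")
        if (p / "farms.geojson").exists()
        else None
    )
    return SceneBundle(
        ortho=read_raster(p / "ortho.tif", require_bands=("red", "green", "nir")),
        dsm=read_raster(p / "dsm.tif"),
        dtm=read_raster(p / "dtm.tif"),
        truth=truth,
        farms=farms,
        channel=channel,
        water_bodies=water,
        config=config or SceneConfig(),
    )


# ---------------------------------------------------------------------------
# classification driver
# ---------------------------------------------------------------------------

@_stage("classification")
def classify_scene(
    bundle: SceneBundle,
    seg_params: SegmentationParams = SegmentationParams(),
    tex_params: TextureParams = TextureParams(),
    thresholds: RuleThresholds = RuleThresholds(),
    n_training_per_class: int = 30,
    training: pd.DataFrame | None = None,
    segmap: SegmentMap | None = None,
) -> tuple[LandCoverMap, SegmentMap]:
    """Segment the orthomosaic and run the full rule hierarchy.

    ``training`` (columns row/col/label) defaults to seeded samples drawn
    from the bundle's ground truth; for real surveys it would come from
    manual interpretation.
    """
    tex = texture_mean_euclidean(bundle.ortho, tex_params)
    if segmap is None:
        segmap = segment_image(bundle.ortho, seg_params)
    feats = extract_features(
        segmap.labels, bundle.ortho, texture=tex, dsm=bundle.dsm, dtm=bundle.dtm
    )
    segmap = SegmentMap(segmap.labels, feats, segmap.merge_log)
    if training is None:
        training = training_samples(bundle, n_per_class=n_training_per_class)
    seg_ids = segmap.labels.values[training["row"], training["col"]]
    train_df = feats.loc[seg_ids].reset_index(drop=True)
    train_df["label"] = training["label"].to_numpy()
    model = train_nn(train_df, NN_FEATURES)
    lc = cls_mod.classify_segments(segmap, thresholds=thresholds, nn_model=model)
    return lc, segmap


def evaluate_scene(
    seed: int,
    scene_config: SceneConfig | None = None,
    seg_params: SegmentationParams = SegmentationParams(),
    thresholds: RuleThresholds = RuleThresholds(),
) -> dict:
    """Generate one synthetic scene, classify it, score it against truth.

    Returns overall accuracy, kappa and per-class producer/user accuracy of
    the full-map confusion matrix — the quality-bar measurement used by the
    end-to-end checks.
    """
    cfg = scene_config or SceneConfig(seed=seed)
    if cfg.seed != seed:
        cfg = SceneConfig(seed=seed)
    bundle = generate_scene(cfg)
    lc, _ = classify_scene(bundle, seg_params=seg_params, thresholds=thresholds)
    cm = cls_mod.confusion_matrix(bundle.truth, lc)
    return cls_mod.accuracy_metrics(cm)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config_path, out_dir=None) -> Path:
    """Execute every stage per the YAML config; returns the artifact dir."""
    cfg = load_config(config_path)
    seg_p, tex_p, thr, ind_cfg, mca_cfg = _params_from_config(cfg)
    out = Path(out_dir or cfg.get("output_dir", "palmsust_out"))
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        log.append(f"{stage}: t+{time.perf_counter() - t0:.2f}s")

    scene_cfg_d = cfg.get("scene", {})
    if scene_cfg_d.get("paths"):
        paths = scene_cfg_d["paths"]
        bundle = read_scene(paths["dir"])
    else:
        sc = scene_config_from_dict(scene_cfg_d.get("synthetic", {}))
        if "seed" in cfg and "seed" not in scene_cfg_d.get("synthetic", {}):
            sc = scene_config_from_dict({**scene_cfg_d.get("synthetic", {}), "seed": cfg["seed"]})
        bundle = generate_scene(sc)
        write_scene(bundle, out / "scene")
    tick("scene")

    nd_v = ndvi(bundle.ortho)
    nd_w = ndwi(bundle.ortho)
    tex = texture_mean_euclidean(bundle.ortho, tex_p)
    write_raster(nd_v, out / "ndvi.tif")
    write_raster(nd_w, out / "ndwi.tif")
    write_raster(tex, out / "texture.tif")
    tick("features")

    lc, segmap = classify_scene(
        bundle,
        seg_params=seg_p,
        tex_params=tex_p,
        thresholds=thr,
        n_training_per_class=int(cfg.get("n_training_per_class", 30)),
    )
    write_raster(segmap.labels, out / "segments.tif")
    segmap.features.to_csv(out / "segment_features.csv")
    write_raster(lc.classes, out / "landcover.tif")
    with open(out / "legend.json", "w") as fh:
        json.dump(CLASS_IDS, fh, indent=2)
    tick("segmentation+classification")

    if bundle.truth is not None:
        pts = cls_mod.sample_validation_points(
            bundle.truth,
            n=int(cfg.get("n_validation_points", 45)),
            seed=int(cfg.get("seed", bundle.config.seed)),
        )
        cm = cls_mod.confusion_matrix(bundle.truth, lc, points=pts)
        metrics = cls_mod.accuracy_metrics(cm)
        pd.DataFrame(
            cm.counts, index=cm.class_names, columns=cm.class_names
        ).to_csv(out / "confusion_matrix.csv")
        acc_rows = {
            "overall": metrics["overall"],
            "kappa": metrics["kappa"],
            **{f"producer_{k}": v for k, v in metrics["producer"].items()},
            **{f"user_{k}": v for k, v in metrics["user"].items()},
        }
        pd.Series(acc_rows).to_csv(out / "accuracy.csv", header=False)
    tick("accuracy")

    slope = slope_degrees(bundle.dtm)
    layers = all_indicators(
        lc, bundle.ortho, slope, bundle.channel, bundle.water_bodies, ind_cfg
    )
    for layer in layers:
        write_raster(layer.scores, out / f"indicator_{layer.name}.tif")
    tick("indicators")

    composite = combine_wlc(layers, mca_cfg)
    five, three = reclassify(composite, mca_cfg)
    write_raster(composite, out / "composite.tif")
    write_raster(five, out / "composite_5class.tif")
    write_raster(three, out / "composite_3class.tif")
    if bundle.farms is not None and bundle.farms.polygons:
        report = zonal_report(composite, layers, bundle.farms, mca_cfg)
        report.farm_indicator_means.to_csv(out / "farm_indicator_means.csv")
        report.farm_class_percent.to_csv(out / "farm_class_percent.csv")
        report.area_indicator_percent.to_csv(out / "area_indicator_percent.csv")
        report.area_composite_percent.to_csv(out / "area_composite_percent.csv")
    tick("aggregation+report")

    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                **cfg,
                "segmentation": asdict(seg_p),
                "texture": asdict(tex_p),
                "seed": int(cfg.get("seed", bundle.config.seed)),
            },
            fh,
            sort_keys=True,
        )
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return out
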