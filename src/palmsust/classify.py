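"""Hierarchical rule-based segment classification and accuracy assessment.

Segments are first split into vegetation and non-vegetation on mean NDVI.
Non-vegetation is subdivided: water by mean NDWI, buildings by a conjunction
of high rectangular fit, positive height above terrain and a red-roof band
range, the residual as bare soil. Vegetation segments are discriminated into
oil palm, crops and other (natural) vegetation by a 1-nearest-neighbour
classifier in a standardized feature space (band means, texture mean, height
above terrain). Adjacent same-class segments are merged afterwards.

Accuracy is assessed by cross-tabulating predictions against reference
labels at randomly distributed validation points: overall accuracy, Cohen's
kappa, and per-class user (precision) and producer (recall) accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .grid import Raster
from .landcover import CLASS_IDS, CLASSES, LandCoverMap
from .segmentation import SegmentMap

__all__ = [
    "RuleThresholds",
    "ConfusionMatrix",
    "NNModel",
    "train_nn",
    "classify_segments",
    "sample_validation_points",
    "confusion_matrix",
    "accuracy_metrics",
]

VEG_CLASSES = ("oil_palm", "crops", "other_vegetation")
NN_FEATURES = ("mean_red", "mean_green", "mean_nir", "mean_texture", "mean_height")


@dataclass(frozen=True)
class RuleThresholds:
    """Threshold expressions of the classification hierarchy.

    The hierarchy itself is fixed; the cutoffs are protocol parameters kept
    in configuration (NDVI >= ``ndvi_veg`` means vegetation, etc.).
    """

    ndvi_veg: float = 0.3
    ndwi_water: float = 0.0
    building_rectfit_min: float = 0.8
    building_height_min_m: float = 2.0
    building_red_range: tuple[float, float] = (160.0, 220.0)

    def __post_init__(self) -> None:
        lo, hi = self.building_red_range
        if not lo < hi:
            raise ValueError("building_red_range must satisfy low < high")


@dataclass
class ConfusionMatrix:
    """k x k counts; rows are reference classes, columns predictions."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class NNModel:
    """1-nearest-neighbour classifier in standardized feature space."""

    feature_names: tuple[str, ...]
    center: np.ndarray
    spread: np.ndarray
    train_x: np.ndarray  # standardized
    train_y: np.ndarray  # class ids
    _index: NearestNeighbors = field(repr=False, default=None)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x = (features[list(self.feature_names)].to_numpy(float) - self.center) / self.spread
        dist, _ = self._index.kneighbors(x, n_neighbors=1)
        # resolve ties at the minimum distance toward the lowest legend id
        out = np.empty(len(x), dtype=np.int64)
        radius = dist[:, 0] + 1e-12
        for i, (xi, r) in enumerate(zip(x, radius)):
            d = np.sqrt(((self.train_x - xi) ** 2).sum(axis=1))
            out[i] = self.train_y[d <= r].min()
        return out


def train_nn(samples: pd.DataFrame, feature_names: tuple[str, ...] = NN_FEATURES) -> NNModel:
    """Fit the nearest-neighbour model on labelled training segments.

    ``samples`` must carry one row per training segment with the feature
    columns plus a ``label`` column naming its vegetation class. Features
    are standardized to zero mean and unit spread over the training set so
    no band dominates the Euclidean metric.
    """
    for cls in VEG_CLASSES:
        if not (samples["label"] == cls).any():
            raise ValueError(f"no training samples for class {cls!r}")
    x = samples[list(feature_names)].to_numpy(float)
    center = x.mean(axis=0)
    spread = x.std(axis=0)
    spread[spread == 0] = 1.0
    xs = (x - center) / spread
    y = samples["label"].map(CLASS_IDS).to_numpy(np.int64)
    index = NearestNeighbors(n_neighbors=1).fit(xs)
    return NNModel(tuple(feature_names), center, spread, xs, y, index)


def classify_segments(
    segmap: SegmentMap,
    ndvi_mean: pd.Series | None = None,
    ndwi_mean: pd.Series | None = None,
    thresholds: RuleThresholds = RuleThresholds(),
    nn_model: NNModel | None = None,
) -> LandCoverMap:
    """Apply the rule hierarchy to a segment map and paint a land cover map.

    ``ndvi_mean``/``ndwi_mean`` are per-segment mean index values; if omitted
    they are derived from the feature table's band means (the mean of a
    ratio is approximated by the ratio of means within a segment).
    """
    feats = segmap.features
    if ndvi_mean is None:
        ndvi_mean = (feats["mean_nir"] - feats["mean_red"]) / (
            feats["mean_nir"] + feats["mean_red"]
        )
    if ndwi_mean is None:
        ndwi_mean = (feats["mean_green"] - feats["mean_nir"]) / (
            feats["mean_green"] + feats["mean_nir"]
        )
    k = len(feats)
    cls = np.full(k, CLASS_IDS["bare_soil"], dtype=np.int64)

    veg = ndvi_mean.to_numpy() >= thresholds.ndvi_veg
    nonveg = ~veg
    water = nonveg & (ndwi_mean.to_numpy() >= thresholds.ndwi_water)
    lo, hi = thresholds.building_red_range
    built = (
        nonveg
        & ~water
        & (feats["rect_fit"].to_numpy() >= thresholds.building_rectfit_min)
        & (feats["mean_height"].to_numpy() >= thresholds.building_height_min_m)
        & (feats["mean_red"].to_numpy() >= lo)
        & (feats["mean_red"].to_numpy() <= hi)
    )
    cls[water] = CLASS_IDS["water"]
    cls[built] = CLASS_IDS["built_up"]

    if veg.any():
        if nn_model is None:
            raise ValueError("vegetation present but no trained NN model given")
        cls[veg] = nn_model.predict(feats.loc[veg])

    out = cls[segmap.labels.values]
    return LandCoverMap(Raster(segmap.labels.geometry, out, nodata=0))


def sample_validation_points(
    reference: LandCoverMap, n: int = 45, seed: int = 0
) -> pd.DataFrame:
    """Uniform random distinct cells over the map's valid area (seeded)."""
    if n < 1:
        raise ValueError("need at least one validation point")
    rr, cc = np.nonzero(reference.valid())
    if n > rr.size:
        raise ValueError(f"requested {n} points but only {rr.size} cells available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rr.size, size=n, replace=False)
    geom = reference.classes.geometry
    return pd.DataFrame(
        {
            "row": rr[idx],
            "col": cc[idx],
            "x": geom.origin_x + (cc[idx] + 0.5) * geom.cell_size,
            "y": geom.origin_y - (rr[idx] + 0.5) * geom.cell_size,
            "reference": [
                reference.legend[int(v)] for v in reference.classes.values[rr[idx], cc[idx]]
            ],
        }
    )


def confusion_matrix(
    reference: LandCoverMap, predicted: LandCoverMap, points: pd.DataFrame | None = None
) -> ConfusionMatrix:
    """Cross-tabulate prediction against reference, at points or full-map."""
    k = len(CLASSES)
    counts = np.zeros((k, k), dtype=np.int64)
    if points is not None:
        r = reference.classes.values[points["row"], points["col"]]
        p = predicted.classes.values[points["row"], points["col"]]
    else:
        ok = reference.valid() & predicted.valid()
        r = reference.classes.values[ok]
        p = predicted.classes.values[ok]
    r = np.asarray(r, dtype=np.int64).ravel()
    p = np.asarray(p, dtype=np.int64).ravel()
    ok = (r > 0) & (p > 0)
    counts = np.bincount((r[ok] - 1) * k + (p[ok] - 1), minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """Overall accuracy, Cohen's kappa, per-class user/producer accuracy.

    Ratios with a zero marginal are reported as NaN and ignored by callers
    summarising over classes.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    overall = diag.sum() / total
    p_e = float((rows * cols).sum()) / total**2
    kappa = (overall - p_e) / (1 - p_e) if p_e != 1 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        producer = np.where(rows > 0, diag / rows, np.nan)
        user = np.where(cols > 0, diag / cols, np.nan)
    return {
        "overall": float(overall),
        "kappa": float(kappa),
        "producer": dict(zip(cm.class_names, producer)),
        "user": dict(zip(cm.class_names, user)),
    }
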