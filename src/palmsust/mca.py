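"""Weighted-linear-combination aggregation, reclassification and reporting.

The composite sustainability surface is the weighted mean of the criterion
layers defined at each cell, with weights renormalized over the defined
layers (water-only criteria must not drag terrestrial cells down). The
composite is reclassified into five equal-width classes over the attainable
[0, 3] range for mapping, and into a three-class low/medium/high summary
for study-area statistics. Farm-level reporting gives per-farm indicator
means (not-applicable where a farm lacks the criterion's features) and the
percentage of each farm's area per composite class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DEFAULT_NODATA, PolygonSet, Raster, rasterize
from .indicators import IndicatorLayer

__all__ = [
    "MCAConfig",
    "SustainabilityReport",
    "combine_wlc",
    "reclassify",
    "zonal_report",
]

FIVE_CLASS_NAMES = ("very_low", "low", "medium", "high", "very_high")
THREE_CLASS_NAMES = ("low", "medium", "high")


def _default_weights() -> dict[str, float]:
    # equal importance across the five indicators; the two riparian
    # criterion layers are halves of the one riparian indicator
    return {
        "erosion": 1.0,
        "riparian_river": 0.5,
        "riparian_standing": 0.5,
        "water_clarity": 1.0,
        "channel_modification": 1.0,
        "connectivity": 1.0,
    }


@dataclass
class MCAConfig:
    weights: dict[str, float] = field(default_factory=_default_weights)
    reclass_breaks: tuple[float, ...] = (0.0, 0.6, 1.2, 1.8, 2.4, 3.0)
    summary3_edges: tuple[float, float] = (1.5, 2.5)

    def __post_init__(self) -> None:
        if all(w == 0 for w in self.weights.values()):
            raise ValueError("weights must not all be zero")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if any(a >= b for a, b in zip(self.reclass_breaks, self.reclass_breaks[1:])):
            raise ValueError("reclass breaks must be strictly increasing")


@dataclass
class SustainabilityReport:
    farm_indicator_means: pd.DataFrame  # farms x indicators, NaN = not applicable
    farm_class_percent: pd.DataFrame  # farms x 5 composite classes, rows sum to 100
    area_indicator_percent: pd.DataFrame  # indicators x 3 score classes
    area_composite_percent: pd.Series  # 5 composite classes over the study area


def combine_wlc(layers: list[IndicatorLayer], cfg: MCAConfig = MCAConfig()) -> Raster:
    """Per-cell weighted mean of defined layers, weights renormalized."""
    if not layers:
        raise ValueError("need at least one indicator layer")
    geom = layers[0].scores.geometry
    num = np.zeros(geom.shape)
    den = np.zeros(geom.shape)
    for layer in layers:
        if layer.scores.geometry != geom:
            raise ValueError("misaligned indicator layers")
        w = cfg.weights.get(layer.name, 1.0)
        if w == 0 or layer.empty:
            continue
        num[layer.mask] += w * layer.scores.values[layer.mask]
        den[layer.mask] += w
    out = np.full(geom.shape, DEFAULT_NODATA)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return Raster(geom, out, nodata=DEFAULT_NODATA)


def reclassify(composite: Raster, cfg: MCAConfig = MCAConfig()) -> tuple[Raster, Raster]:
    """Five-class map by ``reclass_breaks`` and three-class summary map."""
    vals = composite.values
    ok = composite.mask()
    if ok.any() and (vals[ok].min() < cfg.reclass_breaks[0] - 1e-9 or
                     vals[ok].max() > cfg.reclass_breaks[-1] + 1e-9):
        raise ValueError("composite values outside the reclassification range")
    five = np.zeros(vals.shape, dtype=np.int64)
    five[ok] = np.clip(
        np.searchsorted(cfg.reclass_breaks[1:-1], vals[ok], side="right") + 1, 1, 5
    )
    e1, e2 = cfg.summary3_edges
    three = np.zeros(vals.shape, dtype=np.int64)
    three[ok] = np.where(vals[ok] < e1, 1, np.where(vals[ok] < e2, 2, 3))
    return (
        Raster(composite.geometry, five, nodata=0),
        Raster(composite.geometry, three, nodata=0),
    )


def _percent(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    return counts / total * 100.0 if total > 0 else np.full_like(counts, np.nan, dtype=float)


def zonal_report(
    composite: Raster,
    layers: list[IndicatorLayer],
    farms: PolygonSet,
    cfg: MCAConfig = MCAConfig(),
) -> SustainabilityReport:
    """Farm-level and study-area summaries of indicators and composite."""
    geom = composite.geometry
    farm_raster = rasterize(farms, geom, burn="id").values
    five, three = reclassify(composite, cfg)
    comp_ok = composite.mask()

    ind_means = {}
    for fid in farms.ids():
        inside = farm_raster == fid
        row = {}
        for layer in layers:
            m = layer.mask & inside
            row[layer.name] = float(layer.scores.values[m].mean()) if m.any() else np.nan
        ind_means[fid] = row
    farm_means = pd.DataFrame(ind_means).T
    farm_means.index.name = "farm"

    pct_rows = {}
    for fid in farms.ids():
        inside = (farm_raster == fid) & comp_ok
        counts = np.array([(five.values[inside] == c).sum() for c in range(1, 6)])
        pct_rows[fid] = _percent(counts)
    farm_pct = pd.DataFrame(pct_rows, index=FIVE_CLASS_NAMES).T
    farm_pct.index.name = "farm"

    area_rows = {}
    for layer in layers:
        vals = layer.scores.values[layer.mask]
        # indicator scores may include coefficient-scaled values; bin by the
        # three-class summary edges used for the composite
        e1, e2 = cfg.summary3_edges
        counts = np.array(
            [(vals < e1).sum(), ((vals >= e1) & (vals < e2)).sum(), (vals >= e2).sum()]
        )
        area_rows[layer.name] = _percent(counts)
    area_ind = pd.DataFrame(area_rows, index=THREE_CLASS_NAMES).T
    area_ind.index.name = "indicator"

    comp_counts = np.array([(five.values == c).sum() for c in range(1, 6)])
    area_comp = pd.Series(_percent(comp_counts), index=FIVE_CLASS_NAMES, name="percent")

    return SustainabilityReport(farm_means, farm_pct, area_ind, area_comp)
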