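"""Per-criterion sustainability score layers.

Each indicator scores cells 1 (low), 2 (medium) or 3 (high sustainability)
inside its own applicability mask and is nodata elsewhere:

* erosion — slope classes on bare soil and oil palm cells;
* riparian (river) — presence of natural vegetation within the 20/30/40 m
  distance bands of the channel;
* riparian (standing water) — natural vegetation within 100 m of ponds/lakes;
* water clarity — per-water-body mean red digital number, a turbidity proxy;
* channel modification — channel sinuosity class painted on river cells;
* connectivity — distance-to-natural-vegetation class multiplied by a land
  cover quality coefficient in {0, 0.5, 1}, so scores fall in
  {0, 0.5, 1, 1.5, 2, 3}.

Interval conventions are lower-open/upper-closed on the "better" side and
are unit-tested at every printed boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import (
    DEFAULT_NODATA,
    MultiBandRaster,
    Polyline,
    PolygonSet,
    Raster,
    distance_raster,
    geometry_distance,
    rasterize,
)
from .landcover import LandCoverMap

__all__ = [
    "IndicatorConfig",
    "IndicatorLayer",
    "erosion_indicator",
    "riparian_river_indicator",
    "riparian_standing_indicator",
    "water_clarity_indicator",
    "sinuosity",
    "channel_modification_indicator",
    "connectivity_indicator",
    "all_indicators",
]


@dataclass
class IndicatorConfig:
    erosion_bounds_deg: tuple[float, float] = (10.0, 25.0)
    riparian_river_bounds_m: tuple[float, float, float] = (20.0, 30.0, 40.0)
    standing_buffer_m: float = 100.0
    clarity_bounds: tuple[float, float, float, float] = (67.1, 104.5, 142.0, 179.5)
    sinuosity_bounds: tuple[float, float] = (1.05, 1.30)
    connectivity_bounds_m: tuple[float, float] = (25.0, 50.0)
    natural_classes: tuple[str, ...] = ("other_vegetation",)
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "oil_palm": 0.5,
            "crops": 0.5,
            "other_vegetation": 1.0,
            "water": 1.0,
            "built_up": 0.0,
            "bare_soil": 0.0,
        }
    )

    def __post_init__(self) -> None:
        for bounds in (
            self.erosion_bounds_deg,
            self.riparian_river_bounds_m,
            self.clarity_bounds,
            self.sinuosity_bounds,
            self.connectivity_bounds_m,
        ):
            if any(b >= c for b, c in zip(bounds, bounds[1:])):
                raise ValueError(f"bounds {bounds} must be strictly increasing")
        bad = {k: v for k, v in self.coefficients.items() if v not in (0.0, 0.5, 1.0)}
        if bad:
            raise ValueError(f"coefficients must be 0, 0.5 or 1.0; got {bad}")


@dataclass
class IndicatorLayer:
    name: str
    scores: Raster
    mask: np.ndarray

    def __post_init__(self) -> None:
        vals = self.scores.values
        if np.any(vals[~self.mask] != self.scores.nodata):
            raise ValueError("scores outside the applicability mask")

    @property
    def empty(self) -> bool:
        return not self.mask.any()


def _layer(name: str, geom, score: np.ndarray, mask: np.ndarray) -> IndicatorLayer:
    out = np.full(geom.shape, DEFAULT_NODATA)
    out[mask] = score[mask]
    return IndicatorLayer(name, Raster(geom, out, nodata=DEFAULT_NODATA), mask)


def erosion_indicator(
    lc: LandCoverMap, slope: Raster, cfg: IndicatorConfig = IndicatorConfig()
) -> IndicatorLayer:
    """Slope-steepness classes on erosion-prone covers (bare soil, oil palm)."""
    if slope.geometry != lc.classes.geometry:
        raise ValueError("misaligned rasters")
    lo, hi = cfg.erosion_bounds_deg
    mask = lc.mask_of("bare_soil", "oil_palm") & slope.mask()
    s = slope.values
    score = np.where(s <= lo, 3.0, np.where(s <= hi, 2.0, 1.0))
    return _layer("erosion", lc.classes.geometry, score, mask)


def riparian_river_indicator(
    lc: LandCoverMap, channel: Polyline | None, cfg: IndicatorConfig = IndicatorConfig()
) -> IndicatorLayer:
    """Natural-vegetation presence in the river's riparian distance bands.

    Within 40 m of the channel (water cells excluded), natural vegetation
    scores 3 wherever it stands; other covers score by how far the
    encroachment sits from the channel: <=20 m is worst (1), 20-30 m is 2,
    30-40 m is 3.
    """
    geom = lc.classes.geometry
    if channel is None:
        return _layer("riparian_river", geom, np.zeros(geom.shape), np.zeros(geom.shape, bool))
    d1, d2, d3 = cfg.riparian_river_bounds_m
    dist = geometry_distance(channel, geom)
    mask = (dist <= d3) & ~lc.mask_of("water") & lc.valid()
    score = np.where(dist <= d1, 1.0, np.where(dist <= d2, 2.0, 3.0))
    score[lc.mask_of(*cfg.natural_classes)] = 3.0
    return _layer("riparian_river", geom, score, mask)


def riparian_standing_indicator(
    lc: LandCoverMap,
    water_bodies: PolygonSet | None,
    cfg: IndicatorConfig = IndicatorConfig(),
) -> IndicatorLayer:
    """Natural-vegetation presence within the standing-water buffer (100 m)."""
    geom = lc.classes.geometry
    if water_bodies is None or not water_bodies.polygons:
        return _layer("riparian_standing", geom, np.zeros(geom.shape), np.zeros(geom.shape, bool))
    dist = geometry_distance(water_bodies, geom)
    mask = (dist <= cfg.standing_buffer_m) & ~lc.mask_of("water") & lc.valid()
    score = np.where(lc.mask_of(*cfg.natural_classes), 3.0, 1.0)
    return _layer("riparian_standing", geom, score, mask)


def water_clarity_indicator(
    lc: LandCoverMap,
    img: MultiBandRaster,
    water_bodies: PolygonSet | None,
    cfg: IndicatorConfig = IndicatorConfig(),
) -> IndicatorLayer:
    """Turbidity class per standing water body from its mean red value.

    The body-level mean is painted across all of the body's water cells;
    means outside the calibrated range clamp to the nearest class.
    """
    geom = lc.classes.geometry
    if water_bodies is None or not water_bodies.polygons:
        return _layer("water_clarity", geom, np.zeros(geom.shape), np.zeros(geom.shape, bool))
    b_lo, b1, b2, b_hi = cfg.clarity_bounds
    body_raster = rasterize(water_bodies, geom, burn="id")
    red = img.band("red").astype(float)
    water = lc.mask_of("water")
    score = np.zeros(geom.shape)
    mask = np.zeros(geom.shape, bool)
    for pid in water_bodies.ids():
        cells = (body_raster.values == pid) & water
        if not cells.any():
            raise ValueError(f"water body {pid} contains no classified water cells")
        mean_red = float(red[cells].mean())
        if mean_red <= b1:
            s = 3.0  # clear: at or below the high-sustainability bound
        elif mean_red <= b2:
            s = 2.0
        else:
            s = 1.0
        score[cells] = s
        mask |= cells
    return _layer("water_clarity", geom, score, mask)


def sinuosity(channel: Polyline) -> float:
    """Along-channel length over straight-line endpoint distance (>= 1)."""
    seg = np.diff(channel.vertices, axis=0)
    arc = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    chord = float(np.hypot(*(channel.vertices[-1] - channel.vertices[0])))
    if chord == 0:
        raise ValueError("channel endpoints coincide; sinuosity undefined")
    return arc / chord


def channel_modification_indicator(
    lc: LandCoverMap,
    channel: Polyline | None,
    cfg: IndicatorConfig = IndicatorConfig(),
) -> IndicatorLayer:
    """Sinuosity class of the channel, painted on its river cells."""
    geom = lc.classes.geometry
    if channel is None:
        return _layer("channel_modification", geom, np.zeros(geom.shape), np.zeros(geom.shape, bool))
    s_lo, s_hi = cfg.sinuosity_bounds
    s = sinuosity(channel)
    score_val = 1.0 if s <= s_lo else (2.0 if s <= s_hi else 3.0)
    half_width = (channel.width_m or 0.0) / 2.0 + geom.cell_size
    dist = geometry_distance(channel, geom)
    mask = lc.mask_of("water") & (dist <= half_width)
    score = np.full(geom.shape, score_val)
    return _layer("channel_modification", geom, score, mask)


def connectivity_indicator(
    lc: LandCoverMap,
    cfg: IndicatorConfig = IndicatorConfig(),
    river_mask: np.ndarray | None = None,
) -> IndicatorLayer:
    """Proximity-to-natural-vegetation class times a land quality coefficient.

    Distance bands give 3 (<= 25 m), 2 (25-50 m) or 1 (> 50 m); the band
    score is multiplied by the cover's conservation-quality coefficient
    (1 for natural vegetation and the river, 0.5 for oil palm and crops,
    0 for bare soil and built-up areas).
    """
    geom = lc.classes.geometry
    nat = lc.mask_of(*cfg.natural_classes)
    if not nat.any():
        raise ValueError("no natural vegetation in scene; connectivity undefined")
    d1, d2 = cfg.connectivity_bounds_m
    dist = distance_raster(Raster(geom, nat, nodata=0)).values
    base = np.where(dist <= d1, 3.0, np.where(dist <= d2, 2.0, 1.0))
    coeff = np.zeros(geom.shape)
    for name, c in cfg.coefficients.items():
        coeff[lc.mask_of(name)] = c
    if river_mask is not None:
        coeff[river_mask] = 1.0
    mask = lc.valid()
    return _layer("connectivity", geom, base * coeff, mask)


def all_indicators(
    lc: LandCoverMap,
    img: MultiBandRaster,
    slope: Raster,
    channel: Polyline | None,
    water_bodies: PolygonSet | None,
    cfg: IndicatorConfig = IndicatorConfig(),
) -> list[IndicatorLayer]:
    """The six criterion layers in canonical order."""
    return [
        erosion_indicator(lc, slope, cfg),
        riparian_river_indicator(lc, channel, cfg),
        riparian_standing_indicator(lc, water_bodies, cfg),
        water_clarity_indicator(lc, img, water_bodies, cfg),
        channel_modification_indicator(lc, channel, cfg),
        connectivity_indicator(lc, cfg),
    ]
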