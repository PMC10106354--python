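"""Seeded synthetic UAV scene generator with known ground truth.

Emulates the survey products of a smallholder oil palm landscape at
~25 cm ground sampling distance: a red/green/NIR orthomosaic, DSM and DTM
surfaces, farm parcels, a mildly meandering river and standing water bodies
of configurable turbidity, plus a per-cell ground-truth land cover map.

The layout is blocky on purpose: land classes are assigned to parcels of
contiguous tiles, oil palms are stamped as circular high-NIR crowns on a
planted grid with strong within-crown texture, buildings are rectangles with
red-brown roof spectra and positive height above terrain, and spectra are
drawn from per-class Gaussians. The per-class spectral means are chosen so
NDVI separates vegetation from soil/water, NDWI is positive only on water,
and texture/height separate the three vegetation classes — i.e. the scene
realises the assumptions the rule hierarchy relies on. What it does *not*
emulate: shadows, BRDF effects, seasonal variation, mixed pixels from
photogrammetric blur, or georeferencing error.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import integrate, ndimage
from shapely.geometry import Point, Polygon

from .grid import GridGeometry, MultiBandRaster, Polyline, PolygonSet, Raster
from .landcover import CLASS_IDS, LandCoverMap

__all__ = ["SceneConfig", "SceneBundle", "generate_scene", "truth_sinuosity", "training_samples"]


# per-class (mean, sd) digital numbers on a 0-255-like scale
DEFAULT_SPECTRA: dict[str, dict[str, tuple[float, float]]] = {
    "oil_palm": {"red": (60, 8), "green": (90, 8), "nir": (200, 10)},
    "crops": {"red": (70, 5), "green": (110, 5), "nir": (170, 5)},
    "other_vegetation": {"red": (50, 10), "green": (80, 10), "nir": (160, 12)},
    "water": {"red": (115, 3), "green": (100, 3), "nir": (35, 3)},
    "built_up": {"red": (180, 4), "green": (90, 4), "nir": (110, 4)},
    "bare_soil": {"red": (150, 6), "green": (110, 6), "nir": (130, 6)},
}

DEFAULT_FRACTIONS = {
    "oil_palm": 0.35,
    "crops": 0.20,
    "other_vegetation": 0.20,
    "bare_soil": 0.15,
    "built_up": 0.03,
    "water": 0.07,
}


@dataclass
class PalmCrownSpec:
    radius_m: float = 1.75
    spacing_m: float = 4.0
    texture_amplitude: float = 30.0  # within-crown NIR modulation sd
    crown_height_m: float = 9.0


@dataclass
class BuildingSpec:
    count: int = 5
    side_m: tuple[float, float] = (9.0, 11.0)
    roof_red_mean: float = 180.0
    height_m: float = 3.0


@dataclass
class RiverSpec:
    width_m: float = 4.0
    amplitude_m: float = 12.0
    wavelength_m: float = 80.0
    mean_red: float = 115.0


@dataclass
class WaterBodySpec:
    center: tuple[float, float]
    radius_m: float
    mean_red: float


@dataclass
class FarmSpec:
    n_x: int = 2
    n_y: int = 2
    margin_m: float = 2.0


@dataclass
class SceneConfig:
    seed: int = 1
    geometry: GridGeometry = field(
        default_factory=lambda: GridGeometry(0.0, 128.0, 0.25, 512, 512)
    )
    spectra: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_SPECTRA))
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    palm_crown: PalmCrownSpec = field(default_factory=PalmCrownSpec)
    building_spec: BuildingSpec = field(default_factory=BuildingSpec)
    river_spec: RiverSpec = field(default_factory=RiverSpec)
    water_spec: list[WaterBodySpec] = field(
        default_factory=lambda: [
            WaterBodySpec(center=(30.0, 100.0), radius_m=10.0, mean_red=70.0),
            WaterBodySpec(center=(100.0, 30.0), radius_m=10.0, mean_red=150.0),
        ]
    )
    farm_spec: FarmSpec = field(default_factory=FarmSpec)
    tile_cells: int = 64  # layout granularity for land-class parcels

    def __post_init__(self) -> None:
        if sum(self.class_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("class fractions sum above 1")


@dataclass
class SceneBundle:
    ortho: MultiBandRaster
    dsm: Raster
    dtm: Raster
    truth: LandCoverMap
    farms: PolygonSet
    channel: Polyline
    water_bodies: PolygonSet
    config: SceneConfig


def _river_centerline_x(y: np.ndarray, cfg: SceneConfig) -> np.ndarray:
    """Map-x of the channel centreline as a function of map-y."""
    geom = cfg.geometry
    x_mid = geom.origin_x + geom.n_cols * geom.cell_size / 2.0
    r = cfg.river_spec
    if r.amplitude_m == 0:
        return np.full_like(np.asarray(y, dtype=float), x_mid)
    return x_mid + r.amplitude_m * np.sin(2 * np.pi * np.asarray(y, float) / r.wavelength_m)


def truth_sinuosity(bundle: SceneBundle) -> float:
    """Arc/chord ratio of the generating sinusoidal centreline.

    Integrates sqrt(1 + x'(y)^2) over the channel's north-south run; with
    zero meander amplitude the ratio is exactly 1.
    """
    cfg = bundle.config
    r = cfg.river_spec
    geom = cfg.geometry
    height = geom.n_rows * geom.cell_size
    if r.amplitude_m == 0:
        return 1.0
    k = 2 * np.pi / r.wavelength_m
    arc, _ = integrate.quad(
        lambda y: np.hypot(1.0, r.amplitude_m * k * np.cos(k * y)), 0.0, height,
        limit=400,
    )
    return float(arc / height)


def generate_scene(cfg: SceneConfig | None = None) -> SceneBundle:
    """Render a full scene bundle; identical config and seed give identical output."""
    cfg = cfg or SceneConfig()
    geom = cfg.geometry
    nr, nc = geom.shape
    cs = geom.cell_size
    rng = np.random.default_rng(cfg.seed)
    xs, ys = geom.cell_centers()

    truth = np.zeros((nr, nc), dtype=np.int64)

    # --- water overlay: meandering river + standing bodies -----------------
    x_c = _river_centerline_x(ys, cfg)
    river_mask = np.abs(xs - x_c) <= cfg.river_spec.width_m / 2.0
    y_line = geom.origin_y - (np.arange(nr) + 0.5) * cs
    channel = Polyline(
        np.column_stack([_river_centerline_x(y_line, cfg), y_line]),
        width_m=cfg.river_spec.width_m,
    )
    bodies = {}
    body_masks: list[np.ndarray] = []
    for i, wb in enumerate(cfg.water_spec, start=1):
        bodies[i] = Point(wb.center).buffer(wb.radius_m, quad_segs=64)
        body_masks.append(
            (xs - wb.center[0]) ** 2 + (ys - wb.center[1]) ** 2 <= wb.radius_m**2
        )
    water_bodies = PolygonSet(bodies, role="water_body")
    water_mask = river_mask.copy()
    for m in body_masks:
        water_mask |= m
    truth[water_mask] = CLASS_IDS["water"]

    # --- tile assignment of the terrestrial classes ------------------------
    t = cfg.tile_cells
    n_ty, n_tx = -(-nr // t), -(-nc // t)
    land_classes = ["oil_palm", "crops", "other_vegetation", "bare_soil"]
    total = nr * nc
    quota = {
        c: cfg.class_fractions[c] * total
        + (cfg.class_fractions.get("built_up", 0.0) * total if c == "bare_soil" else 0.0)
        for c in land_classes
    }
    tiles = [(ty, tx) for ty in range(n_ty) for tx in range(n_tx)]
    order = rng.permutation(len(tiles))
    filled = {c: 0.0 for c in land_classes}
    for ti in order:
        ty, tx = tiles[ti]
        sl = np.s_[ty * t : min((ty + 1) * t, nr), tx * t : min((tx + 1) * t, nc)]
        free = truth[sl] == 0
        n_free = int(free.sum())
        if n_free == 0:
            continue
        # class with the largest remaining relative deficit
        cls = max(land_classes, key=lambda c: (quota[c] - filled[c]) / max(quota[c], 1))
        block = truth[sl]
        block[free] = CLASS_IDS[cls]
        truth[sl] = block
        filled[cls] += n_free

    # --- buildings on bare soil --------------------------------------------
    soil_id = CLASS_IDS["bare_soil"]
    buildings: list[tuple[int, int, int, int]] = []  # r0, r1, c0, c1 (cells)
    tries = 0
    while len(buildings) < cfg.building_spec.count and tries < 4000:
        tries += 1
        w_m = rng.uniform(*cfg.building_spec.side_m)
        h_m = rng.uniform(*cfg.building_spec.side_m)
        w, h = int(round(w_m / cs)), int(round(h_m / cs))
        r0 = rng.integers(0, nr - h)
        c0 = rng.integers(0, nc - w)
        patch = truth[r0 : r0 + h, c0 : c0 + w]
        if np.all(patch == soil_id):
            truth[r0 : r0 + h, c0 : c0 + w] = CLASS_IDS["built_up"]
            buildings.append((r0, r0 + h, c0, c0 + w))

    # --- terrain and surfaces ----------------------------------------------
    dtm = (
        0.05 * (xs - geom.origin_x)
        + 3.0
        * np.sin(2 * np.pi * (xs - geom.origin_x) / 50.0)
        * np.sin(2 * np.pi * (geom.origin_y - ys) / 50.0)
    )
    # one steep knoll so the erosion criterion sees slopes above 25 degrees
    kx, ky = geom.origin_x + nc * cs * 0.22, geom.origin_y - nr * cs * 0.30
    dtm = dtm + 9.0 * np.exp(-(((xs - kx) ** 2 + (ys - ky) ** 2) / (2 * 8.0**2)))

    height = np.zeros((nr, nc))
    smooth = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), 8)
    smooth /= max(smooth.std(), 1e-9)
    height[truth == CLASS_IDS["other_vegetation"]] = (
        12.0 + 1.5 * smooth[truth == CLASS_IDS["other_vegetation"]]
    )
    height[truth == CLASS_IDS["crops"]] = 0.5

    # --- spectra -------------------------------------------------------------
    bands = {}
    id_of = {CLASS_IDS[c]: c for c in CLASS_IDS}
    for bn in ("red", "green", "nir"):
        out = np.zeros((nr, nc))
        for cname, spec in cfg.spectra.items():
            mean, sd = spec[bn]
            if cname == "built_up" and bn == "red":
                mean = cfg.building_spec.roof_red_mean
            m = truth == CLASS_IDS[cname]
            if m.any():
                out[m] = mean + sd * rng.standard_normal(int(m.sum()))
        bands[bn] = out

    # water body red means are a turbidity control knob, not a class constant
    red_sd = cfg.spectra["water"]["red"][1]
    bands["red"][river_mask] = cfg.river_spec.mean_red + red_sd * rng.standard_normal(
        int(river_mask.sum())
    )
    for wb, m in zip(cfg.water_spec, body_masks):
        m = m & ~river_mask
        bands["red"][m] = wb.mean_red + red_sd * rng.standard_normal(int(m.sum()))

    # --- oil palm crowns: planted grid, high NIR, strong texture ------------
    palm_mask = truth == CLASS_IDS["oil_palm"]
    if palm_mask.any():
        pc = cfg.palm_crown
        spacing = max(int(round(pc.spacing_m / cs)), 1)
        radius = pc.radius_m / cs
        rad_i = int(np.ceil(radius))
        yy, xx = np.mgrid[-rad_i : rad_i + 1, -rad_i : rad_i + 1]
        d2 = (xx**2 + yy**2) / max(radius**2, 1e-9)
        crown = d2 <= 1.0
        dome = np.sqrt(np.clip(1.0 - d2, 0.0, None))
        # understory between crowns: still vegetated but flatter and darker
        bands["nir"][palm_mask] -= 20.0
        for r0 in range(spacing // 2, nr, spacing):
            for c0 in range(spacing // 2, nc, spacing):
                r_sl = slice(max(r0 - rad_i, 0), min(r0 + rad_i + 1, nr))
                c_sl = slice(max(c0 - rad_i, 0), min(c0 + rad_i + 1, nc))
                k_r = slice(r_sl.start - (r0 - rad_i), r_sl.stop - (r0 - rad_i))
                k_c = slice(c_sl.start - (c0 - rad_i), c_sl.stop - (c0 - rad_i))
                sub_palm = palm_mask[r_sl, c_sl]
                sub_crown = crown[k_r, k_c] & sub_palm
                if not sub_crown.any():
                    continue
                n_cells = int(sub_crown.sum())
                nir = bands["nir"][r_sl, c_sl]
                nir[sub_crown] += 20.0 + pc.texture_amplitude * rng.standard_normal(n_cells)
                bands["nir"][r_sl, c_sl] = nir
                hh = height[r_sl, c_sl]
                hh[sub_crown] = np.maximum(
                    hh[sub_crown], pc.crown_height_m * dome[k_r, k_c][sub_crown]
                )
                height[r_sl, c_sl] = hh

    # natural vegetation gets moderate NIR texture (canopy heterogeneity)
    nat_mask = truth == CLASS_IDS["other_vegetation"]
    bands["nir"][nat_mask] += 12.0 * rng.standard_normal(int(nat_mask.sum()))

    for bn in bands:
        bands[bn] = np.clip(bands[bn], 0.0, None)

    for r0, r1, c0, c1 in buildings:
        height[r0:r1, c0:c1] = cfg.building_spec.height_m
    dsm = dtm + height + rng.uniform(0.0, 0.03, size=(nr, nc))

    # --- farm parcels ---------------------------------------------------------
    fs = cfg.farm_spec
    ext_x = nc * cs
    ext_y = nr * cs
    farm_polys = {}
    fid = 1
    for iy in range(fs.n_y):
        for ix in range(fs.n_x):
            x0 = geom.origin_x + ix * ext_x / fs.n_x + fs.margin_m
            x1 = geom.origin_x + (ix + 1) * ext_x / fs.n_x - fs.margin_m
            y1 = geom.origin_y - iy * ext_y / fs.n_y - fs.margin_m
            y0 = geom.origin_y - (iy + 1) * ext_y / fs.n_y + fs.margin_m
            farm_polys[fid] = Polygon(
                [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
            )
            fid += 1
    farms = PolygonSet(farm_polys, role="farm")

    ortho = MultiBandRaster(geom, bands)
    return SceneBundle(
        ortho=ortho,
        dsm=Raster(geom, dsm),
        dtm=Raster(geom, dtm),
        truth=LandCoverMap(Raster(geom, truth, nodata=0)),
        farms=farms,
        channel=channel,
        water_bodies=water_bodies,
        config=cfg,
    )


def training_samples(
    bundle: SceneBundle, n_per_class: int = 30, seed: int | None = None
) -> pd.DataFrame:
    """Seeded random ground-truth cells for the three vegetation classes.

    Samples are drawn at least one palm-crown radius inside their class
    region (boundary cells are eroded away) so they represent pure cover.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    cfg = bundle.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    margin = max(int(np.ceil(cfg.palm_crown.radius_m / cfg.geometry.cell_size)), 1)
    selem = np.ones((2 * margin + 1, 2 * margin + 1), bool)
    rows: list[dict] = []
    for cname in ("oil_palm", "crops", "other_vegetation"):
        mask = bundle.truth.mask_of(cname)
        if not mask.any():
            raise ValueError(f"class {cname!r} absent from scene")
        core = ndimage.binary_erosion(mask, structure=selem)
        if not core.any():
            core = mask
        rr, cc = np.nonzero(core)
        take = min(n_per_class, rr.size)
        idx = rng.choice(rr.size, size=take, replace=False)
        for i in idx:
            rows.append({"row": int(rr[i]), "col": int(cc[i]), "label": cname})
    return pd.DataFrame(rows)
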