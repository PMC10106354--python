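"""Grid/vector data model and raster-vector primitives.

All coordinates are in a projected CRS with metre units. Cell (0, 0) sits at
the top-left (north-west) corner of the grid: ``origin_x``/``origin_y`` are the
map coordinates of that outer corner, rows increase southwards (decreasing y)
and columns increase eastwards. Raster-vector operations sample at cell
centres throughout, so a cell belongs to a polygon iff its centre does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import LineString, Polygon, shape as shapely_shape

__all__ = [
    "GridGeometry",
    "Raster",
    "MultiBandRaster",
    "Polyline",
    "PolygonSet",
    "read_raster",
    "write_raster",
    "read_geojson_polygons",
    "read_geojson_polyline",
    "write_geojson_polygons",
    "write_geojson_polyline",
    "rasterize",
    "distance_raster",
    "slope_degrees",
    "buffer_mask",
]

DEFAULT_NODATA = -9999.0

# GeoTIFF tag ids understood by GDAL/QGIS
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridGeometry:
    """Square-cell grid anchored at the top-left outer corner."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of every cell centre as (x, y) 2-D arrays."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class Raster:
    """Single-band raster; nodata cells are flagged, never used in arithmetic."""

    geometry: GridGeometry
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"array shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata


@dataclass
class MultiBandRaster:
    """Co-registered named bands sharing one grid geometry."""

    geometry: GridGeometry
    bands: dict[str, np.ndarray]
    nodata: float = DEFAULT_NODATA

    REQUIRED = ("red", "green", "nir")

    def __post_init__(self) -> None:
        for name, arr in self.bands.items():
            arr = np.asarray(arr)
            if arr.shape != self.geometry.shape:
                raise ValueError(f"band {name!r} shape mismatch")
            self.bands[name] = arr
        missing = [b for b in self.REQUIRED if b not in self.bands]
        if missing:
            raise ValueError(f"missing required bands: {missing}")

    def band(self, name: str) -> np.ndarray:
        if name not in self.bands:
            raise KeyError(f"band {name!r} not present (have {list(self.bands)})")
        return self.bands[name]


@dataclass
class Polyline:
    """Open channel centreline with an optional bank-to-bank width."""

    vertices: np.ndarray
    width_m: float | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2:
            raise ValueError("polyline needs at least two (x, y) vertices")
        if np.any(np.all(np.diff(self.vertices, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")

    def to_shapely(self) -> LineString:
        return LineString(self.vertices)

    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))


@dataclass
class PolygonSet:
    """Identified polygons playing one role (farm, water_body, ...)."""

    polygons: dict[int, Polygon] = field(default_factory=dict)
    role: str = "farm"

    def __post_init__(self) -> None:
        for pid, poly in self.polygons.items():
            if not poly.is_valid:
                raise ValueError(f"polygon {pid} is invalid (self-intersecting?)")

    def ids(self) -> list[int]:
        return sorted(self.polygons)

    def union(self) -> Polygon:
        return shapely.union_all(list(self.polygons.values()))


# ---------------------------------------------------------------------------
# raster I/O (GeoTIFF via tifffile, standard geo tags)
# ---------------------------------------------------------------------------

def _geo_tags(geom: GridGeometry, nodata: float, integer: bool) -> list:
    # GDAL_NODATA is ASCII; integer rasters need an integer literal
    nd = repr(int(nodata)) if integer else repr(float(nodata))
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (geom.cell_size, geom.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geom.origin_x, geom.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", None, nd),
    ]


def write_raster(r: Raster | MultiBandRaster, path) -> None:
    """Write a GeoTIFF with pixel scale, tiepoint and nodata tags.

    Band names and the CRS label go into the ImageDescription as JSON so a
    round trip preserves them; integer arrays are written as integers.
    """
    if isinstance(r, MultiBandRaster):
        names = list(r.bands)
        data = np.stack([r.bands[n] for n in names])
        kwargs = {"planarconfig": "separate", "photometric": "minisblack"}
    else:
        names = None
        data = r.values
        kwargs = {}
    meta = {"band_names": names, "crs_label": r.geometry.crs_label}
    tifffile.imwrite(
        str(path),
        data,
        extratags=_geo_tags(
            r.geometry, r.nodata, np.issubdtype(np.asarray(data).dtype, np.integer)
        ),
        description=json.dumps(meta),
        **kwargs,
    )


def read_raster(path, require_bands: tuple[str, ...] = ()) -> Raster | MultiBandRaster:
    """Read a GeoTIFF written by :func:`write_raster` (or any GDAL-style file).

    A file with named bands returns a :class:`MultiBandRaster`; a plain
    single-band file returns a :class:`Raster`. ``require_bands`` lets callers
    fail early with a descriptive message when e.g. ``nir`` is absent.
    """
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = tf.asarray()
        try:
            scale = page.tags[_TAG_PIXEL_SCALE].value
            tiepoint = page.tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: not a georeferenced raster") from exc
        if abs(scale[0] - scale[1]) > 1e-9:
            raise ValueError(f"{path}: non-square cells {scale[:2]}")
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in page.tags:
            nodata = float(page.tags[_TAG_GDAL_NODATA].value)
        meta = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except json.JSONDecodeError:
                meta = {}
    band_names = meta.get("band_names")
    crs = meta.get("crs_label", "unknown")
    if arr.ndim == 3:
        n_rows, n_cols = arr.shape[1:]
    else:
        n_rows, n_cols = arr.shape
    geom = GridGeometry(
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        cell_size=float(scale[0]),
        n_rows=n_rows,
        n_cols=n_cols,
        crs_label=crs,
    )
    if arr.ndim == 3:
        if not band_names or len(band_names) != arr.shape[0]:
            raise ValueError(f"{path}: multi-band file lacks band names")
        bands = dict(zip(band_names, arr))
        missing = [b for b in require_bands if b not in bands]
        if missing:
            raise ValueError(f"{path}: missing required bands {missing}")
        return MultiBandRaster(geom, bands, nodata=nodata)
    if require_bands:
        raise ValueError(f"{path}: single band file, required bands {require_bands}")
    return Raster(geom, arr, nodata=nodata)


# ---------------------------------------------------------------------------
# vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

def write_geojson_polygons(polys: PolygonSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"id": pid, "role": polys.role},
            "geometry": json.loads(shapely.to_geojson(polys.polygons[pid])),
        }
        for pid in polys.ids()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson_polygons(path, role: str = "farm") -> PolygonSet:
    with open(path) as fh:
        gj = json.load(fh)
    polys = {}
    for i, feat in enumerate(gj["features"]):
        pid = int(feat.get("properties", {}).get("id", i))
        polys[pid] = shapely_shape(feat["geometry"])
    return PolygonSet(polys, role=role)


def write_geojson_polyline(line: Polyline, path) -> None:
    feat = {
        "type": "Feature",
        "properties": {"width_m": line.width_m},
        "geometry": json.loads(shapely.to_geojson(line.to_shapely())),
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feat]}, fh)


def read_geojson_polyline(path) -> Polyline:
    with open(path) as fh:
        gj = json.load(fh)
    feat = gj["features"][0]
    coords = np.asarray(feat["geometry"]["coordinates"], dtype=float)
    width = feat.get("properties", {}).get("width_m")
    return Polyline(coords, width_m=width)


# ---------------------------------------------------------------------------
# raster-vector primitives
# ---------------------------------------------------------------------------

def rasterize(
    polys: PolygonSet,
    geom: GridGeometry,
    burn: str | float = "id",
    nodata: float = DEFAULT_NODATA,
) -> Raster:
    """Burn polygons onto the grid by cell-centre membership.

    ``burn='id'`` writes each polygon's id; a numeric value burns that
    constant. Later ids overwrite earlier ones where polygons overlap.
    """
    if not polys.polygons:
        raise ValueError("empty polygon set")
    xs, ys = geom.cell_centers()
    out = np.full(geom.shape, nodata, dtype=float)
    for pid in polys.ids():
        inside = shapely.contains_xy(polys.polygons[pid], xs, ys)
        out[inside] = pid if burn == "id" else float(burn)
    return Raster(geom, out, nodata=nodata)


def distance_raster(targets: Raster) -> Raster:
    """Centre-to-centre Euclidean distance (m) to the nearest True cell."""
    mask = targets.values.astype(bool)
    if not mask.any():
        raise ValueError("distance_raster needs at least one target cell")
    dist = ndimage.distance_transform_edt(~mask) * targets.geometry.cell_size
    return Raster(targets.geometry, dist, nodata=DEFAULT_NODATA)


def slope_degrees(dtm: Raster) -> Raster:
    """Slope in degrees by Horn's 3x3 method, edge cells edge-replicated.

    Nodata cells propagate: any cell whose 3x3 neighbourhood touches nodata
    is emitted as nodata.
    """
    valid = dtm.mask()
    if not valid.any():
        raise ValueError("all-nodata DTM")
    z = np.pad(dtm.values.astype(float), 1, mode="edge")
    cs = dtm.geometry.cell_size
    # Horn weights: dz/dx = ((c+2f+i) - (a+2d+g)) / (8*cs) on the 3x3 stencil
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    bad = ndimage.binary_dilation(~valid, structure=np.ones((3, 3), bool))
    slope[bad] = DEFAULT_NODATA
    return Raster(dtm.geometry, slope, nodata=DEFAULT_NODATA)


def buffer_mask(
    line_or_polys: Polyline | PolygonSet, geom: GridGeometry, dist_m: float
) -> Raster:
    """True where the cell centre lies within ``dist_m`` of the geometry."""
    if dist_m <= 0:
        raise ValueError("buffer distance must be positive")
    if isinstance(line_or_polys, Polyline):
        target = line_or_polys.to_shapely()
    else:
        if not line_or_polys.polygons:
            raise ValueError("empty polygon set")
        target = line_or_polys.union()
    xs, ys = geom.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    within = shapely.dwithin(target, pts, dist_m).reshape(geom.shape)
    return Raster(geom, within, nodata=0)


def geometry_distance(
    target: Polyline | PolygonSet, geom: GridGeometry
) -> np.ndarray:
    """Exact map distance (m) from every cell centre to a vector geometry."""
    shp = target.to_shapely() if isinstance(target, Polyline) else target.union()
    xs, ys = geom.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    return shapely.distance(shp, pts).reshape(geom.shape)
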