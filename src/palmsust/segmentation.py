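"""Multiresolution region-merging segmentation (Fractal Net Evolution).

Bottom-up merging starts from single-cell segments. A pair of adjacent
segments may fuse only while the increase in heterogeneity stays below the
squared scale parameter. Heterogeneity combines a colour term (weighted
growth in size-weighted per-band standard deviation) and a shape term
(compactness + smoothness), mixed by the shape and compactness weights.

Merging proceeds by *local mutual best fitting*: in each pass every segment
identifies its minimum-cost admissible neighbour, and exactly those pairs
that choose each other merge. Mutual-best pairs form a matching, so a whole
pass merges simultaneously and vectorizes over the region-adjacency graph;
passes repeat until no admissible mutual pair remains. Ties are broken by
ordering edges on (cost, min id, max id), which makes the result
deterministic. Every executed merge is logged with its cost so tests can
audit the scale-threshold contract.

Adjacency and perimeter use 4-connectivity; the smoothness term uses the
axis-aligned bounding box, while :func:`rectangular_fit` uses the
minimum-area rotated rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

from .grid import GridGeometry, MultiBandRaster, Raster

__all__ = [
    "SegmentationParams",
    "SegmentMap",
    "fusion_cost",
    "segment_image",
    "rectangular_fit",
    "extract_features",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Controls of the region-merging segmentation.

    ``scale`` sets the merge threshold (``scale ** 2``); ``shape_weight``
    mixes shape vs colour heterogeneity; ``compactness_weight`` mixes the
    compactness vs smoothness shape terms. ``band_weights`` default to equal.
    """

    scale: float = 40.0
    shape_weight: float = 0.1
    compactness_weight: float = 0.5
    band_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        if not 0 <= self.shape_weight < 1:
            raise ValueError("shape_weight must lie in [0, 1)")
        if not 0 <= self.compactness_weight <= 1:
            raise ValueError("compactness_weight must lie in [0, 1]")


@dataclass
class SegmentFeatures:
    """Scalar description of one segment, as consumed by the fusion cost."""

    n: int
    band_mean: dict[str, float]
    band_std: dict[str, float]
    perimeter_m: float
    bbox: tuple[int, int, int, int]  # rmin, rmax, cmin, cmax (cell indices)


@dataclass
class SegmentMap:
    labels: Raster  # integer segment id per cell
    features: pd.DataFrame  # indexed by segment id
    merge_log: list[tuple[int, int, float]] = field(default_factory=list)

    def n_segments(self) -> int:
        return int(len(np.unique(self.labels.values)))


def _bbox_perimeter_m(bbox, cell_size: float) -> float:
    rmin, rmax, cmin, cmax = bbox
    return 2.0 * ((rmax - rmin + 1) + (cmax - cmin + 1)) * cell_size


def fusion_cost(
    a: SegmentFeatures,
    b: SegmentFeatures,
    p: SegmentationParams,
    shared_boundary_m: float,
    cell_size: float = 1.0,
) -> float:
    """Heterogeneity increase of merging two adjacent segments.

    ``f = (1 - shape_weight) * h_color + shape_weight * h_shape`` where the
    colour term sums, over bands, the growth of size-weighted standard
    deviation, and the shape term mixes compactness (perimeter over sqrt
    area) and smoothness (perimeter over bounding-box perimeter) deviations.
    ``shared_boundary_m`` is the length of the common edge, removed twice
    from the merged perimeter.
    """
    if shared_boundary_m <= 0:
        raise ValueError("segments must be adjacent (shared boundary > 0)")
    n_a, n_b = a.n, b.n
    n_m = n_a + n_b
    bands = list(a.band_mean)
    weights = p.band_weights or {bn: 1.0 for bn in bands}
    h_color = 0.0
    for bn in bands:
        s_a = a.band_mean[bn] * n_a
        s_b = b.band_mean[bn] * n_b
        q_a = (a.band_std[bn] ** 2 + a.band_mean[bn] ** 2) * n_a
        q_b = (b.band_std[bn] ** 2 + b.band_mean[bn] ** 2) * n_b
        var_m = max((q_a + q_b) / n_m - ((s_a + s_b) / n_m) ** 2, 0.0)
        h_color += weights.get(bn, 1.0) * (
            n_m * np.sqrt(var_m) - (n_a * a.band_std[bn] + n_b * b.band_std[bn])
        )
    l_a, l_b = a.perimeter_m, b.perimeter_m
    l_m = l_a + l_b - 2.0 * shared_boundary_m
    bbox_m = (
        min(a.bbox[0], b.bbox[0]),
        max(a.bbox[1], b.bbox[1]),
        min(a.bbox[2], b.bbox[2]),
        max(a.bbox[3], b.bbox[3]),
    )
    h_cmpct = (
        np.sqrt(n_m) * l_m - (np.sqrt(n_a) * l_a + np.sqrt(n_b) * l_b)
    )
    h_smooth = (
        n_m * l_m / _bbox_perimeter_m(bbox_m, cell_size)
        - n_a * l_a / _bbox_perimeter_m(a.bbox, cell_size)
        - n_b * l_b / _bbox_perimeter_m(b.bbox, cell_size)
    )
    h_shape = p.compactness_weight * h_cmpct + (1 - p.compactness_weight) * h_smooth
    return float((1 - p.shape_weight) * h_color + p.shape_weight * h_shape)


# ---------------------------------------------------------------------------
# vectorized merging
# ---------------------------------------------------------------------------

def _initial_edges(n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """4-connectivity edges of the pixel grid, each with boundary weight 1."""
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    hu = idx[:, :-1].ravel()
    hv = idx[:, 1:].ravel()
    vu = idx[:-1, :].ravel()
    vv = idx[1:, :].ravel()
    u = np.concatenate([hu, vu])
    v = np.concatenate([hv, vv])
    return u, v, np.ones(u.size, dtype=np.int64)


def _edge_costs(u, v, w, state, p: SegmentationParams, bw: np.ndarray, cell_size: float):
    n, S, Q, P, rmin, rmax, cmin, cmax = state
    n_a = n[u]; n_b = n[v]
    n_m = n_a + n_b
    S_m = S[:, u] + S[:, v]
    Q_m = Q[:, u] + Q[:, v]
    var = np.maximum(Q / np.maximum(n, 1) - (S / np.maximum(n, 1)) ** 2, 0.0)
    sig = np.sqrt(var)
    var_m = np.maximum(Q_m / n_m - (S_m / n_m) ** 2, 0.0)
    sig_m = np.sqrt(var_m)
    h_color = np.einsum(
        "b,be->e",
        bw,
        n_m * sig_m - (n_a * sig[:, u] + n_b * sig[:, v]),
    )
    l_a = P[u] * cell_size
    l_b = P[v] * cell_size
    l_m = (P[u] + P[v] - 2 * w) * cell_size
    h_cmpct = np.sqrt(n_m) * l_m - (np.sqrt(n_a) * l_a + np.sqrt(n_b) * l_b)
    b_a = 2.0 * ((rmax[u] - rmin[u] + 1) + (cmax[u] - cmin[u] + 1)) * cell_size
    b_b = 2.0 * ((rmax[v] - rmin[v] + 1) + (cmax[v] - cmin[v] + 1)) * cell_size
    b_m = 2.0 * (
        (np.maximum(rmax[u], rmax[v]) - np.minimum(rmin[u], rmin[v]) + 1)
        + (np.maximum(cmax[u], cmax[v]) - np.minimum(cmin[u], cmin[v]) + 1)
    ) * cell_size
    h_smooth = n_m * l_m / b_m - n_a * l_a / b_a - n_b * l_b / b_b
    h_shape = p.compactness_weight * h_cmpct + (1 - p.compactness_weight) * h_smooth
    return (1 - p.shape_weight) * h_color + p.shape_weight * h_shape


def segment_image(img: MultiBandRaster, p: SegmentationParams = SegmentationParams()) -> SegmentMap:
    """Segment a multiband image by iterated mutual-best-fit region merging.

    Returns integer labels (compact, starting at 0), a per-segment feature
    table with spectral statistics and geometry, and a log of every merge
    with the fusion cost that admitted it.
    """
    geom = img.geometry
    nr, nc = geom.shape
    cell_size = geom.cell_size
    band_names = sorted(img.bands)
    bands = np.stack([img.bands[bn].astype(float) for bn in band_names])
    weights = p.band_weights or {}
    bw = np.array([weights.get(bn, 1.0) for bn in band_names], dtype=float)

    n_px = nr * nc
    labels = np.arange(n_px, dtype=np.int64)
    # per-segment accumulators
    n = np.ones(n_px, dtype=np.int64)
    S = bands.reshape(len(band_names), -1).copy()
    Q = S**2
    P = np.full(n_px, 4, dtype=np.int64)  # perimeter in cell-edge units
    rr, cc = np.divmod(np.arange(n_px), nc)
    rmin = rr.copy(); rmax = rr.copy(); cmin = cc.copy(); cmax = cc.copy()
    u, v, w = _initial_edges(nr, nc)

    threshold = p.scale**2
    merge_log: list[tuple[int, int, float]] = []
    # map compact labels back to an original-cell representative for logging
    rep = np.arange(n_px, dtype=np.int64)

    while u.size:
        state = (n, S, Q, P, rmin, rmax, cmin, cmax)
        cost = _edge_costs(u, v, w, state, p, bw, cell_size)
        adm = cost < threshold
        if not adm.any():
            break
        au, av, ac = u[adm], v[adm], cost[adm]
        # deterministic order: (cost, min id, max id); rank = position
        order = np.lexsort((av, au, ac))
        au, av, ac = au[order], av[order], ac[order]
        ranks = np.arange(au.size)
        best = np.full(n.size, au.size, dtype=np.int64)
        np.minimum.at(best, au, ranks)
        np.minimum.at(best, av, ranks)
        mutual = (best[au] == ranks) & (best[av] == ranks)
        if not mutual.any():
            break
        mu, mv, mc = au[mutual], av[mutual], ac[mutual]
        merge_log.extend(zip(rep[mu].tolist(), rep[mv].tolist(), mc.tolist()))
        # merge matching: relabel every v-side segment into its u-side partner
        parent = np.arange(n.size, dtype=np.int64)
        parent[mv] = mu
        new_of_old = np.unique(parent[parent], return_inverse=True)[1]
        k = int(new_of_old.max()) + 1
        labels = new_of_old[labels]
        n2 = np.zeros(k, dtype=np.int64)
        np.add.at(n2, new_of_old, n)
        S2 = np.zeros((S.shape[0], k))
        Q2 = np.zeros_like(S2)
        np.add.at(S2.T, new_of_old, S.T)
        np.add.at(Q2.T, new_of_old, Q.T)
        P2 = np.zeros(k, dtype=np.int64)
        np.add.at(P2, new_of_old, P)
        shared = w[adm][order][mutual]
        np.subtract.at(P2, new_of_old[mu], 2 * shared)
        big = np.iinfo(np.int64).max
        rmin2 = np.full(k, big); rmax2 = np.full(k, -big)
        cmin2 = np.full(k, big); cmax2 = np.full(k, -big)
        np.minimum.at(rmin2, new_of_old, rmin)
        np.maximum.at(rmax2, new_of_old, rmax)
        np.minimum.at(cmin2, new_of_old, cmin)
        np.maximum.at(cmax2, new_of_old, cmax)
        # representative: smallest original-cell id in the segment
        rep2 = np.full(k, n_px, dtype=np.int64)
        np.minimum.at(rep2, new_of_old, rep)
        # rebuild edges on the coarsened graph
        nu = new_of_old[u]
        nv = new_of_old[v]
        keep = nu != nv
        nu, nv, nw = nu[keep], nv[keep], w[keep]
        lo = np.minimum(nu, nv)
        hi = np.maximum(nu, nv)
        key = lo * k + hi
        uniq, inv = np.unique(key, return_inverse=True)
        w2 = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(w2, inv, nw)
        u, v, w = uniq // k, uniq % k, w2
        n, S, Q, P = n2, S2, Q2, P2
        rmin, rmax, cmin, cmax = rmin2, rmax2, cmin2, cmax2
        rep = rep2

    # compact final labels (already compact) into a raster + feature table
    label_raster = Raster(geom, labels.reshape(nr, nc).astype(np.int64), nodata=-1)
    features = extract_features(label_raster, img)
    return SegmentMap(label_raster, features, merge_log)


# ---------------------------------------------------------------------------
# per-segment features
# ---------------------------------------------------------------------------

def rectangular_fit(cells_rc: np.ndarray, cell_size: float = 1.0) -> float:
    """Segment area over the area of its minimum-area enclosing rectangle.

    The rectangle is fitted to the convex hull of the segment's *cell
    corners* (rotating calipers via shapely), so a solid axis-aligned
    rectangle of cells scores exactly 1.
    """
    cells_rc = np.asarray(cells_rc)
    if cells_rc.size == 0:
        raise ValueError("empty segment")
    rows = cells_rc[:, 0]
    cols = cells_rc[:, 1]
    corners: list[tuple[float, float]] = []
    for r in np.unique(rows):
        cs = cols[rows == r]
        lo, hi = cs.min(), cs.max() + 1
        corners += [(lo, r), (lo, r + 1), (hi, r), (hi, r + 1)]
    hull = MultiPoint(corners).convex_hull
    rect = shapely.minimum_rotated_rectangle(hull)
    area = cells_rc.shape[0] * 1.0  # cell units; ratio is scale-free
    return float(min(area / rect.area, 1.0))


def _perimeter_edges(labels: np.ndarray) -> np.ndarray:
    """Per-segment exposed cell-edge count under 4-connectivity."""
    k = labels.max() + 1
    per = np.zeros(k, dtype=np.int64)
    # outer border contributes one edge per border cell side
    np.add.at(per, labels[0, :], 1)
    np.add.at(per, labels[-1, :], 1)
    np.add.at(per, labels[:, 0], 1)
    np.add.at(per, labels[:, -1], 1)
    for a, b in (
        (labels[:, :-1].ravel(), labels[:, 1:].ravel()),
        (labels[:-1, :].ravel(), labels[1:, :].ravel()),
    ):
        diff = a != b
        np.add.at(per, a[diff], 1)
        np.add.at(per, b[diff], 1)
    return per


def extract_features(
    labels: Raster,
    img: MultiBandRaster,
    texture: Raster | None = None,
    dsm: Raster | None = None,
    dtm: Raster | None = None,
    with_rect_fit: bool = True,
) -> pd.DataFrame:
    """Per-segment feature table: size, spectral stats, geometry, height.

    ``mean_height`` is mean(dsm - dtm) over the segment when both surfaces
    are given. Incremental statistics maintained during merging must agree
    with this direct recomputation.
    """
    for r in (texture, dsm, dtm):
        if r is not None and r.geometry != labels.geometry:
            raise ValueError("misaligned raster geometries")
    if img.geometry != labels.geometry:
        raise ValueError("misaligned raster geometries")
    lab = labels.values.astype(np.int64)
    flat = lab.ravel()
    k = int(flat.max()) + 1
    counts = np.bincount(flat, minlength=k)
    cell_size = labels.geometry.cell_size
    data: dict[str, np.ndarray] = {"n": counts}
    for bn in sorted(img.bands):
        vals = img.bands[bn].astype(float).ravel()
        s = np.bincount(flat, weights=vals, minlength=k)
        q = np.bincount(flat, weights=vals**2, minlength=k)
        mean = s / counts
        var = np.maximum(q / counts - mean**2, 0.0)
        data[f"mean_{bn}"] = mean
        data[f"std_{bn}"] = np.sqrt(var)
    data["perimeter_m"] = _perimeter_edges(lab) * cell_size
    rr, cc = np.indices(lab.shape)
    rmin = np.full(k, lab.shape[0]); rmax = np.full(k, -1)
    cmin = np.full(k, lab.shape[1]); cmax = np.full(k, -1)
    np.minimum.at(rmin, flat, rr.ravel())
    np.maximum.at(rmax, flat, rr.ravel())
    np.minimum.at(cmin, flat, cc.ravel())
    np.maximum.at(cmax, flat, cc.ravel())
    data["bbox_perimeter_m"] = (
        2.0 * ((rmax - rmin + 1) + (cmax - cmin + 1)) * cell_size
    )
    if texture is not None:
        data["mean_texture"] = (
            np.bincount(flat, weights=texture.values.astype(float).ravel(), minlength=k)
            / counts
        )
    if dsm is not None and dtm is not None:
        height = (dsm.values.astype(float) - dtm.values.astype(float)).ravel()
        data["mean_height"] = np.bincount(flat, weights=height, minlength=k) / counts
    if with_rect_fit:
        order = np.argsort(flat, kind="stable")
        sorted_lab = flat[order]
        bounds = np.searchsorted(sorted_lab, np.arange(k + 1))
        rc = np.column_stack([rr.ravel()[order], cc.ravel()[order]])
        fits = np.empty(k)
        for s_id in range(k):
            fits[s_id] = rectangular_fit(rc[bounds[s_id] : bounds[s_id + 1]], cell_size)
        data["rect_fit"] = fits
    df = pd.DataFrame(data, index=pd.RangeIndex(k, name="segment"))
    return df
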