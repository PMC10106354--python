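"""Spectral indices and moving-window texture used as classification features.

NDVI separates vegetation from non-vegetation; NDWI separates open water from
the rest. Texture is the mean Euclidean distance between the window's centre
cell and every other cell in the window — on a single band this reduces to
the mean absolute difference — and discriminates structurally rough canopy
(oil palm fronds) from smooth covers (crops, water) at high resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DEFAULT_NODATA, MultiBandRaster, Raster

__all__ = ["TextureParams", "ndvi", "ndwi", "texture_mean_euclidean"]


@dataclass(frozen=True)
class TextureParams:
    window: int = 41
    band: str = "nir"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("texture window must be odd and >= 3")


def _normalized_diff(a: np.ndarray, b: np.ndarray, geom) -> Raster:
    a = a.astype(float)
    b = b.astype(float)
    denom = a + b
    out = np.full(a.shape, DEFAULT_NODATA)
    ok = denom != 0
    out[ok] = (a[ok] - b[ok]) / denom[ok]
    return Raster(geom, out, nodata=DEFAULT_NODATA)


def ndvi(img: MultiBandRaster) -> Raster:
    """(NIR - Red) / (NIR + Red); nodata where the sum is zero."""
    return _normalized_diff(img.band("nir"), img.band("red"), img.geometry)


def ndwi(img: MultiBandRaster) -> Raster:
    """(Green - NIR) / (Green + NIR); nodata where the sum is zero."""
    return _normalized_diff(img.band("green"), img.band("nir"), img.geometry)


def texture_mean_euclidean(img: MultiBandRaster, p: TextureParams = TextureParams()) -> Raster:
    """Mean Euclidean distance texture over a ``window x window`` neighbourhood.

    For each cell c the statistic is mean_{j != c} |v_j - v_c| over the window
    (centre excluded: its distance to itself is identically zero and would only
    rescale the image). Edges are handled by replicate padding so the output
    keeps the input's extent.

    The window is swept as explicit offsets, accumulating |shifted - centre|;
    at the default 41 x 41 window this stays a few seconds on a 512 x 512
    scene without approximation.
    """
    band = img.band(p.band).astype(float)
    r = p.window // 2
    padded = np.pad(band, r, mode="edge")
    acc = np.zeros_like(band)
    n = p.window * p.window - 1
    h, w = band.shape
    for dy in range(p.window):
        for dx in range(p.window):
            if dy == r and dx == r:
                continue
            acc += np.abs(padded[dy : dy + h, dx : dx + w] - band)
    return Raster(img.geometry, acc / n, nodata=DEFAULT_NODATA)
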