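"""Land cover legend and categorical map container shared across stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Raster

__all__ = ["CLASSES", "CLASS_IDS", "NODATA_CLASS", "LandCoverMap"]

# legend order is fixed: it also fixes confusion-matrix orientation and the
# nearest-neighbour tie-break (lowest id wins)
CLASSES: tuple[str, ...] = (
    "oil_palm",
    "crops",
    "other_vegetation",
    "water",
    "built_up",
    "bare_soil",
)
CLASS_IDS: dict[str, int] = {name: i + 1 for i, name in enumerate(CLASSES)}
NODATA_CLASS = 0


@dataclass
class LandCoverMap:
    """Categorical raster over the six land cover classes; 0 is nodata."""

    classes: Raster
    legend: dict[int, str] = field(
        default_factory=lambda: {v: k for k, v in CLASS_IDS.items()}
    )

    def __post_init__(self) -> None:
        vals = np.unique(self.classes.values)
        known = set(self.legend) | {NODATA_CLASS}
        unknown = [int(v) for v in vals if int(v) not in known]
        if unknown:
            raise ValueError(f"class ids {unknown} missing from legend")

    def mask_of(self, *names: str) -> np.ndarray:
        ids = [CLASS_IDS[n] for n in names]
        return np.isin(self.classes.values, ids)

    def valid(self) -> np.ndarray:
        return self.classes.values != NODATA_CLASS

    def class_fractions(self) -> dict[str, float]:
        vals = self.classes.values
        total = int((vals != NODATA_CLASS).sum())
        return {
            name: float((vals == cid).sum()) / total
            for name, cid in CLASS_IDS.items()
        }
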