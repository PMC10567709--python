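"""Land-cover classification shared by the density and emission-factor tables.

Fifteen natural-vegetation classes plus cropland, following the
Sanderson-style land-cover/use scheme used in bottom-up termite
inventories.  The per-class emission factors (ug CH4 g^-1 termite h^-1)
and termite biomass densities (g dry weight m^-2) ship as a packaged CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .grid import GridSpec

# Natural-vegetation classes, in table order.  Cropland is handled as a
# per-cell areal fraction on top of these, not as a map class.
NATURAL_CLASSES: tuple[str, ...] = (
    "tropical_evergreen_forest",
    "tropical_deciduous_forest",
    "temperate_broadleaf_evergreen_forest",
    "temperate_needleleaf_evergreen_forest",
    "temperate_deciduous_forest",
    "boreal_evergreen_forest",
    "boreal_deciduous_forest",
    "mixed_forest",
    "savanna",
    "grassland",
    "dense_shrubland",
    "open_shrubland",
    "tundra",
    "desert",
    "polar_desert",
)

CROPLAND = "cropland"

ALL_CLASSES: tuple[str, ...] = NATURAL_CLASSES + (CROPLAND,)

#: Classes whose termite density is zero everywhere (cold-limited).
ZERO_DENSITY_CLASSES: frozenset[str] = frozenset({"tundra", "polar_desert"})

MISSING_CODE = -1  # ocean / no-data in integer-coded maps


def load_landcover_table() -> pd.DataFrame:
    """The packaged per-class emission-factor / density table, indexed by class."""
    with resources.files("termiteflux.data").joinpath("landcover_table.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("class")


@dataclass
class LandCoverMap:
    """Per-cell categorical layer over the natural-vegetation classes.

    ``codes`` holds indices into ``classes`` (int), with
    :data:`MISSING_CODE` for ocean / no-data cells.
    """

    spec: GridSpec
    codes: np.ndarray
    classes: tuple[str, ...] = NATURAL_CLASSES

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.shape != self.spec.shape:
            raise ValueError("codes shape does not match grid")
        valid = (self.codes == MISSING_CODE) | (
            (self.codes >= 0) & (self.codes < len(self.classes))
        )
        if not valid.all():
            raise ValueError("land-cover codes outside the class table")

    def code_of(self, name: str) -> int:
        return self.classes.index(name)

    def cells_of(self, name: str) -> np.ndarray:
        """Boolean mask of cells carrying class ``name``."""
        return self.codes == self.code_of(name)

    @property
    def missing(self) -> np.ndarray:
        return self.codes == MISSING_CODE

    def census(self) -> dict[str, int]:
        """Cell count per class present on the map."""
        out: dict[str, int] = {}
        for i, name in enumerate(self.classes):
            n = int(np.sum(self.codes == i))
            if n:
                out[name] = n
        return out

    def per_class_lookup(self, table: dict[str, float] | pd.Series) -> np.ndarray:
        """Map a per-class scalar table onto the grid (NaN where missing)."""
        lut = np.array([float(table[name]) for name in self.classes])
        out = np.full(self.spec.shape, np.nan)
        ok = self.codes != MISSING_CODE
        out[ok] = lut[self.codes[ok]]
        return out
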