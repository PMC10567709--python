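"""Termite biomass density mapping (g dry weight m^-2).

Outside the tropics, density is a fixed per-land-cover value from the
packaged table.  In tropical forest classes it tracks vegetation
productivity through the empirical relationship

    density = a * exp(b * GPP),   a = 1.21 g m^-2, b = 0.0008 (g C m^-2 yr^-1)^-1,

so CO2 fertilization of GPP propagates into termite biomass.  Cropland
keeps its constant tabulated density in all variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, GridField, area_field
from .landcover import LandCoverMap, load_landcover_table, NATURAL_CLASSES, CROPLAND

logger = logging.getLogger(__name__)

GPP_DENSITY_A = 1.21
GPP_DENSITY_B = 0.0008

#: Classes whose density responds to GPP by default: the two tropical
#: forest classes (tabulated at 11 and 8 g m^-2 in the no-GPP variant).
DEFAULT_GPP_CLASSES = frozenset(
    {"tropical_evergreen_forest", "tropical_deciduous_forest"}
)

__all__ = [
    "GPP_DENSITY_A",
    "GPP_DENSITY_B",
    "DEFAULT_GPP_CLASSES",
    "DensityTable",
    "DensityConfig",
    "lookup_density",
    "tropical_density",
    "density_field",
    "total_biomass",
]


@dataclass(frozen=True)
class DensityTable:
    """Per-class termite biomass density (g m^-2), cropland included."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values:
            table = load_landcover_table()["density_g_per_m2"].to_dict()
            object.__setattr__(self, "values", {k: float(v) for k, v in table.items()})
        if any(v < 0 for v in self.values.values()):
            raise ValueError("densities must be non-negative")

    @property
    def cropland_density(self) -> float:
        return self.values[CROPLAND]

    def __getitem__(self, cls: str) -> float:
        if cls not in self.values:
            raise KeyError(f"unknown land-cover class {cls!r}")
        return self.values[cls]


def lookup_density(cls: str, table: DensityTable | None = None) -> float:
    """Tabulated termite density (g m^-2) for one land-cover/use class."""
    return (table or DensityTable())[cls]


@dataclass(frozen=True)
class DensityConfig:
    """How density is mapped.

    ``use_gpp`` toggles the GPP relationship in ``gpp_responsive_classes``
    (off = the land-use-only estimator variant); ``a``/``b`` are the
    coefficients of the exponential GPP-density relationship.
    """

    gpp_responsive_classes: frozenset[str] = DEFAULT_GPP_CLASSES
    use_gpp: bool = True
    a: float = GPP_DENSITY_A
    b: float = GPP_DENSITY_B

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("GPP-density coefficients must be positive")


def tropical_density(gpp, config: DensityConfig | None = None):
    """GPP-driven termite density, ``a * exp(b * GPP)`` in g m^-2.

    Accepts a scalar or array of annual GPP (g C m^-2 yr^-1); the output
    is uncapped.
    """
    config = config or DensityConfig()
    gpp_arr = np.asarray(gpp, dtype=float)
    if np.any(~np.isfinite(gpp_arr)) or np.any(gpp_arr < 0):
        raise ValueError("GPP must be finite and non-negative")
    out = config.a * np.exp(config.b * gpp_arr)
    return float(out) if np.isscalar(gpp) else out


def density_field(
    landcover: LandCoverMap,
    gpp_field: GridField | None,
    habitat_mask: np.ndarray,
    config: DensityConfig | None = None,
    table: DensityTable | None = None,
) -> GridField:
    """Natural-vegetation termite density on the grid (g m^-2).

    Zero outside habitat; the GPP relationship applies on the responsive
    classes when ``use_gpp`` (falling back, with a warning, to the table
    wherever GPP is missing); tabulated values elsewhere.  Cropland is
    weighted in separately by the emission engine.
    """
    config = config or DensityConfig()
    table = table or DensityTable()
    spec = landcover.spec
    habitat_mask = np.asarray(habitat_mask, dtype=bool)
    if habitat_mask.shape != spec.shape:
        raise ValueError("habitat mask is not aligned with the land-cover grid")
    if config.use_gpp and gpp_field is not None and gpp_field.spec != spec:
        raise ValueError("GPP field is not aligned with the land-cover grid")

    lut = {name: table[name] for name in landcover.classes}
    values = landcover.per_class_lookup(lut)
    if config.use_gpp:
        responsive = np.zeros(spec.shape, dtype=bool)
        for name in config.gpp_responsive_classes:
            responsive |= landcover.cells_of(name)
        if gpp_field is None:
            gpp_missing = responsive
        else:
            gpp_missing = responsive & gpp_field.missing
            ok = responsive & ~gpp_field.missing
            values[ok] = config.a * np.exp(config.b * gpp_field.values[ok])
        if np.any(gpp_missing & habitat_mask):
            n = int(np.sum(gpp_missing & habitat_mask))
            logger.warning(
                "GPP missing at %d tropical habitat cell(s); using tabulated density",
                n,
            )
            warnings.warn(
                f"GPP missing at {n} tropical habitat cell(s); "
                "falling back to tabulated density",
                stacklevel=2,
            )
    values = np.where(habitat_mask, values, 0.0)
    values = np.nan_to_num(values, nan=0.0)
    return GridField(spec, values, "g m-2")


def total_biomass(
    density: GridField,
    cropland_fraction: GridField,
    habitat_mask: np.ndarray,
    cropland_density: float | None = None,
) -> float:
    """Global termite biomass (Tg dry weight) over habitat cells.

    Each habitat cell contributes
    ``[(1 - f) * rho_nat + f * rho_crop] * area``; the result is scaled
    g -> Tg (1e-12) with km^2 -> m^2 (1e6).
    """
    spec = density.spec
    habitat_mask = np.asarray(habitat_mask, dtype=bool)
    if cropland_fraction.spec != spec or habitat_mask.shape != spec.shape:
        raise ValueError("inputs are not aligned")
    if cropland_density is None:
        cropland_density = DensityTable().cropland_density
    f = cropland_fraction.values[habitat_mask]
    rho = density.values[habitat_mask]
    areas = area_field(spec)[habitat_mask]
    grams = np.sum(((1.0 - f) * rho + f * cropland_density) * areas) * 1e6
    return float(grams * 1e-12)
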