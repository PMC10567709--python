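"""Climate-envelope termite habitat masks and areas.

Termite presence is cold-limited: a cell is potential habitat when its
minimum monthly mean temperature (a climatological mean) is strictly
above a threshold, -8 degrees C by default.  Actual habitat discounts
the potential area by the cropland areal fraction; cropland itself still
emits (with its own density and emission factor) — the two bookkeepings
are deliberately distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, GridField, area_field

DEFAULT_THRESHOLD_C = -8.0

__all__ = [
    "DEFAULT_THRESHOLD_C",
    "HabitatResult",
    "min_monthly_temperature",
    "potential_habitat_mask",
    "habitat_areas",
    "climatology_monthly",
]


@dataclass
class HabitatResult:
    """Potential and actual habitat for one year.

    ``actual_area_field`` holds the per-cell habitat area (km^2) net of
    cropland; totals are in km^2.  The mask is False wherever any input
    month was missing, so ocean cells can never be habitat.
    """

    potential_mask: np.ndarray
    actual_area_field: GridField
    potential_area_total: float
    actual_area_total: float
    year: int | None = None

    def __post_init__(self) -> None:
        if self.actual_area_total > self.potential_area_total * (1 + 1e-12):
            raise ValueError("actual habitat area cannot exceed potential")

    def totals_csv_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [self.year],
                "potential_area_km2": [self.potential_area_total],
                "actual_area_km2": [self.actual_area_total],
            }
        )


def min_monthly_temperature(months: Sequence[GridField]) -> GridField:
    """Per-cell minimum over twelve aligned monthly fields (deg C).

    A cell is missing in the result if any month is missing there.
    """
    if len(months) != 12:
        raise ValueError(f"expected 12 monthly fields, got {len(months)}")
    spec = months[0].spec
    for m in months[1:]:
        if m.spec != spec:
            raise ValueError("monthly fields are on different grids")
    stack = np.stack([m.values for m in months])
    return GridField(spec, np.min(stack, axis=0), months[0].units)


def climatology_monthly(
    monthly_by_year: dict[int, Sequence[GridField]], year: int, window: int = 20
) -> list[GridField]:
    """Trailing-window climatological monthly means for one target year.

    Averages each calendar month over the ``window`` years ending at
    ``year`` (inclusive), falling back to however many earlier years are
    available at the start of a series.
    """
    years = [y for y in sorted(monthly_by_year) if year - window < y <= year]
    if not years:
        raise ValueError(f"no driver years available at or before {year}")
    spec = monthly_by_year[years[0]][0].spec
    out = []
    for m in range(12):
        mean = np.mean(np.stack([monthly_by_year[y][m].values for y in years]), axis=0)
        out.append(GridField(spec, mean, monthly_by_year[years[0]][m].units))
    return out


def potential_habitat_mask(
    tmin: GridField, threshold: float = DEFAULT_THRESHOLD_C
) -> np.ndarray:
    """Boolean habitat mask: strictly ``tmin > threshold``.

    The comparison is strict, so a cell at exactly the threshold is not
    habitat; missing cells are never habitat.  Cold-adapted-free classes
    (tundra, polar desert) are additionally excluded downstream by their
    zero termite density, not here.
    """
    with np.errstate(invalid="ignore"):
        return (tmin.values > threshold) & ~tmin.missing


def habitat_areas(
    mask: np.ndarray,
    cropland_fraction: GridField,
    spec: GridSpec,
    year: int | None = None,
) -> HabitatResult:
    """Potential and actual (cropland-discounted) habitat areas.

    actual per-cell area = mask * cell_area * (1 - cropland fraction).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spec.shape or cropland_fraction.spec != spec:
        raise ValueError("mask / cropland grids are not aligned")
    f = cropland_fraction.values
    f_hab = f[mask]
    if np.any(~np.isfinite(f_hab)):
        raise ValueError("cropland fraction missing inside habitat")
    if np.any((f_hab < 0.0) | (f_hab > 1.0)):
        raise ValueError("cropland fraction outside [0, 1]")
    areas = area_field(spec)
    potential = float(np.sum(areas[mask]))
    actual_values = np.zeros(spec.shape)
    actual_values[mask] = areas[mask] * (1.0 - f_hab)
    actual_values[cropland_fraction.missing & ~mask] = np.nan
    actual = float(np.nansum(actual_values))
    return HabitatResult(
        potential_mask=mask,
        actual_area_field=GridField(spec, actual_values, "km2"),
        potential_area_total=potential,
        actual_area_total=actual,
        year=year,
    )
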