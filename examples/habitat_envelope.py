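"""Potential vs actual termite habitat under the -8 degC envelope.

A cell is potential habitat when its coldest climatological month stays
strictly above -8 degC; actual habitat additionally discounts the
cropland fraction of each cell.
"""

import numpy as np

from termiteflux import (
    WorldConfig,
    gen_monthly_temperature,
    gen_cropland_fraction,
    min_monthly_temperature,
    potential_habitat_mask,
    habitat_areas,
)

world = WorldConfig(year_start=2001, year_end=2020, warming_rate=0.3, seed=7)

for year in (2001, 2020):
    months = gen_monthly_temperature(world, year)
    tmin = min_monthly_temperature(months)
    mask = potential_habitat_mask(tmin)  # strict: exactly -8.0 is excluded
    res = habitat_areas(mask, gen_cropland_fraction(world, year), world.spec, year)
    n_land = int(np.sum(~tmin.missing))
    print(f"{year}: habitat cells {int(mask.sum())}/{n_land} land cells, "
          f"potential {res.potential_area_total / 1e6:.1f}e6 km2, "
          f"actual {res.actual_area_total / 1e6:.1f}e6 km2")

print()
print("Warming moves the envelope poleward (potential area grows);")
print("cropland expansion eats into it (actual stays below potential).")
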