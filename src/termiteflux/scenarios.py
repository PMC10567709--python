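"""Multi-year runs: historical series, future presets, variants, trends.

A scenario run walks a year range, builds each year's driver bundle
(habitat climatology, land cover, cropland, GPP), runs the EF ensemble,
and collects an annual series of global totals, habitat areas and
biomass.  Four estimator variants span the methodological uncertainty:

* ``control`` — GPP-responsive tropical density, EFs sampled from the
  observation distribution;
* ``sanderson_ef`` — fixed per-class EF table instead of sampling;
* ``landuse_density`` — density from land use only (no GPP response);
* ``sanderson_ef_and_landuse_density`` — both substitutions.

Two different spreads show up in results and are kept distinct: the
ensemble s.d. across EF draws within one year, and the interannual s.d.
of annual means across a decadal window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .grid import GridSpec
from .synthetic import (
    WorldConfig,
    EFGeneratorConfig,
    gen_monthly_temperature,
    gen_landcover,
    gen_cropland_fraction,
    gen_gpp,
    gen_ef_sample,
    gen_region_mask,
)
from .habitat import (
    climatology_monthly,
    min_monthly_temperature,
    potential_habitat_mask,
    habitat_areas,
    DEFAULT_THRESHOLD_C,
)
from .density import DensityConfig, DensityTable, density_field, total_biomass
from .emission_factors import prescribed_ef_table
from .engine import DriverBundle, run_member, run_ensemble

logger = logging.getLogger(__name__)

VARIANTS = (
    "control",
    "sanderson_ef",
    "landuse_density",
    "sanderson_ef_and_landuse_density",
)

__all__ = [
    "VARIANTS",
    "ScenarioConfig",
    "AnnualSeries",
    "assemble_drivers",
    "run_scenario",
    "decadal_stats",
    "scenario_delta",
    "mitigation_like",
    "high_end_like",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One multi-year estimation run over a synthetic world."""

    world: WorldConfig = field(default_factory=WorldConfig)
    variant: str = "control"
    n_members: int = 1000
    seed: int = 0
    climatology_window: int = 20
    threshold: float = DEFAULT_THRESHOLD_C
    ef_config: EFGeneratorConfig = field(default_factory=EFGeneratorConfig)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")

    @property
    def density_config(self) -> DensityConfig:
        use_gpp = self.variant in ("control", "sanderson_ef")
        return DensityConfig(use_gpp=use_gpp)

    @property
    def uses_prescribed_ef(self) -> bool:
        return self.variant in ("sanderson_ef", "sanderson_ef_and_landuse_density")

    def to_dict(self) -> dict:
        return {
            "world": self.world.to_dict(),
            "variant": self.variant,
            "n_members": self.n_members,
            "seed": self.seed,
            "climatology_window": self.climatology_window,
            "threshold": self.threshold,
            "ef": {
                "n": self.ef_config.n,
                "target_mean": self.ef_config.target_mean,
                "target_sd": self.ef_config.target_sd,
                "upper_bound": self.ef_config.upper_bound,
                "lower_bound": self.ef_config.lower_bound,
                "zero_fraction": self.ef_config.zero_fraction,
                "seed": self.ef_config.seed,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        known = {
            "world",
            "variant",
            "n_members",
            "seed",
            "climatology_window",
            "threshold",
            "ef",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario-config key(s): {sorted(unknown)}")
        kwargs: dict = {}
        if "world" in d:
            kwargs["world"] = WorldConfig.from_dict(d["world"])
        if "ef" in d:
            kwargs["ef_config"] = EFGeneratorConfig(**d["ef"])
        for k in ("variant", "n_members", "seed", "climatology_window", "threshold"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class AnnualSeries:
    """Tidy per-year results of a scenario run."""

    table: pd.DataFrame
    variant: str = "control"

    COLUMNS = (
        "year",
        "mean_Tg",
        "ensemble_sd_Tg",
        "potential_area_km2",
        "actual_area_km2",
        "biomass_Tg",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"annual series missing column(s): {sorted(missing)}")
        if self.table["year"].duplicated().any():
            raise ValueError("one record per year required")
        if (self.table["ensemble_sd_Tg"] < 0).any():
            raise ValueError("ensemble s.d. must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, variant: str = "control") -> "AnnualSeries":
        return cls(pd.read_csv(path), variant=variant)


def _year_seed(base_seed: int, year: int) -> int:
    """Deterministic per-year ensemble seed; adding years to a run never
    perturbs the seeds of existing ones."""
    ss = np.random.SeedSequence([int(base_seed), int(year)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def assemble_drivers(
    world: WorldConfig,
    year: int,
    climatology_window: int = 20,
    monthly_cache: dict | None = None,
    use_gpp: bool = True,
) -> DriverBundle:
    """Build one year's driver bundle from the synthetic world.

    The habitat climatology is the trailing ``climatology_window``-year
    mean of the monthly temperatures (truncated at the series start).
    """
    if monthly_cache is None:
        monthly_cache = {}
    first = max(world.year_start, year - climatology_window + 1)
    for y in range(first, year + 1):
        if y not in monthly_cache:
            monthly_cache[y] = gen_monthly_temperature(world, y)
    climatology = climatology_monthly(monthly_cache, year, climatology_window)
    return DriverBundle(
        year=year,
        temperature_months=climatology,
        landcover=gen_landcover(world),
        cropland_fraction=gen_cropland_fraction(world, year),
        gpp=gen_gpp(world, year) if use_gpp else None,
        region_mask=gen_region_mask(world.spec),
    )


def run_scenario(config: ScenarioConfig) -> AnnualSeries:
    """Run the habitat -> density -> ensemble pipeline for every year."""
    world = config.world
    density_config = config.density_config
    table = DensityTable()
    ef_dataset = None if config.uses_prescribed_ef else gen_ef_sample(config.ef_config)
    prescribed = prescribed_ef_table() if config.uses_prescribed_ef else None
    monthly_cache: dict = {}
    records = []
    for year in world.years:
        drivers = assemble_drivers(
            world,
            year,
            config.climatology_window,
            monthly_cache,
            use_gpp=density_config.use_gpp,
        )
        tmin = min_monthly_temperature(drivers.temperature_months)
        mask = potential_habitat_mask(tmin, config.threshold)
        hab = habitat_areas(mask, drivers.cropland_fraction, world.spec, year)
        rho = density_field(drivers.landcover, drivers.gpp, mask, density_config, table)
        biomass = total_biomass(rho, drivers.cropland_fraction, mask, table.cropland_density)
        if config.uses_prescribed_ef:
            _, total, _ = run_member(
                drivers,
                prescribed,
                density_config,
                table,
                config.threshold,
                variant=config.variant,
            )
            mean_tg, sd_tg = total, 0.0
        else:
            res = run_ensemble(
                drivers,
                ef_dataset,
                n=config.n_members,
                seed=_year_seed(config.seed, year),
                density_config=density_config,
                table=table,
                threshold=config.threshold,
            )
            mean_tg, sd_tg = res.mean, res.sd
        # drop stale years so the cache stays bounded by the window
        for y in list(monthly_cache):
            if y <= year - config.climatology_window:
                del monthly_cache[y]
        logger.info(
            "year %d: %.3f +- %.3f Tg CH4, habitat %.3g km2",
            year,
            mean_tg,
            sd_tg,
            hab.actual_area_total,
        )
        records.append(
            {
                "year": year,
                "mean_Tg": mean_tg,
                "ensemble_sd_Tg": sd_tg,
                "potential_area_km2": hab.potential_area_total,
                "actual_area_km2": hab.actual_area_total,
                "biomass_Tg": biomass,
            }
        )
    return AnnualSeries(pd.DataFrame.from_records(records), variant=config.variant)


def decadal_stats(
    series: AnnualSeries, start_year: int, end_year: int
) -> tuple[float, float]:
    """Mean and interannual s.d. of annual ensemble-mean totals in a window.

    This is variability across years (e.g. a "2011-2020" decadal mean),
    not the within-year ensemble spread.
    """
    t = series.table
    window = t[(t["year"] >= start_year) & (t["year"] <= end_year)]
    if len(window) < 2:
        raise ValueError(
            f"window [{start_year}, {end_year}] must contain at least 2 series years"
        )
    vals = window["mean_Tg"].to_numpy()
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def scenario_delta(
    series: AnnualSeries,
    base_window: tuple[int, int],
    end_window: tuple[int, int],
) -> float:
    """Change in decadal-mean emission between two windows (Tg CH4 yr^-1)."""
    base_mean, _ = decadal_stats(series, *base_window)
    end_mean, _ = decadal_stats(series, *end_window)
    return end_mean - base_mean


def mitigation_like(spec: GridSpec | None = None, seed: int = 0) -> WorldConfig:
    """Future preset with mild warming and near-flat CO2 fertilization,
    mimicking a mitigation-oriented pathway."""
    return WorldConfig(
        spec=spec or GridSpec.coarse(),
        year_start=2021,
        year_end=2100,
        warming_rate=0.1,
        cropland_trend=0.005,
        co2_fertilization_rate=0.005,
        seed=seed,
    )


def high_end_like(spec: GridSpec | None = None, seed: int = 0) -> WorldConfig:
    """Future preset with strong warming and sustained CO2 fertilization,
    mimicking a high-emission pathway."""
    return WorldConfig(
        spec=spec or GridSpec.coarse(),
        year_start=2021,
        year_end=2100,
        warming_rate=0.45,
        cropland_trend=0.01,
        co2_fertilization_rate=0.04,
        seed=seed,
    )
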