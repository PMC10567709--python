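"""Per-cell CH4 flux, global/regional totals, and the Monte-Carlo ensemble.

The core bookkeeping: emission = termite biomass density x emission
factor.  A cell inside the habitat envelope emits

    [(1 - f) * rho_nat * EF_nat + f * rho_crop * EF_crop] * 8760 * 1e-6

in g CH4 m^-2 yr^-1, where f is the cropland areal fraction, densities
are g m^-2, EFs are ug CH4 g^-1 termite h^-1, 8760 = 24 h x 365 d
converts hourly to annual (leap days ignored) and 1e-6 converts ug to g.
Global totals are area-weighted sums in Tg CH4 yr^-1.

Uncertainty in the EF observations is propagated by an ensemble: each of
n members draws one EF per land-cover class from the observation sample
and recomputes the global total; the ensemble mean and standard
deviation summarize the spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd

from .grid import GridSpec, GridField, RegionMask, area_field, area_weighted_total
from .landcover import LandCoverMap, NATURAL_CLASSES, CROPLAND
from .habitat import min_monthly_temperature, potential_habitat_mask, DEFAULT_THRESHOLD_C
from .density import DensityConfig, DensityTable, density_field

HOURS_PER_YEAR = 24 * 365  # leap days ignored
UG_TO_G = 1e-6

#: CH4 Global Warming Potentials (mass basis) by time horizon, years.
DEFAULT_GWP = {20: 79.7, 100: 27.0}

C_PER_CO2 = 12.0 / 44.0

__all__ = [
    "HOURS_PER_YEAR",
    "DEFAULT_GWP",
    "DriverBundle",
    "EmissionField",
    "EnsembleResult",
    "cell_flux",
    "run_member",
    "run_ensemble",
    "offset_fraction",
    "net_flux_field",
    "ch4_to_co2eq_carbon",
]


@dataclass
class DriverBundle:
    """One simulation year's aligned inputs.

    ``temperature_months`` are the twelve climatological monthly-mean
    fields the habitat envelope is evaluated on (deg C).
    """

    year: int
    temperature_months: Sequence[GridField]
    landcover: LandCoverMap
    cropland_fraction: GridField
    gpp: GridField | None = None
    soil_sink: GridField | None = None
    region_mask: RegionMask | None = None

    def __post_init__(self) -> None:
        spec = self.landcover.spec
        layers: list[GridSpec] = [m.spec for m in self.temperature_months]
        layers.append(self.cropland_fraction.spec)
        for opt in (self.gpp, self.soil_sink):
            if opt is not None:
                layers.append(opt.spec)
        if self.region_mask is not None:
            layers.append(self.region_mask.spec)
        if any(s != spec for s in layers):
            raise ValueError("driver grids are not aligned")

    @property
    def spec(self) -> GridSpec:
        return self.landcover.spec


@dataclass
class EmissionField:
    """One member's (or the mean) gridded termite CH4 flux."""

    flux: GridField  # g CH4 m-2 yr-1
    year: int
    variant: str = "control"
    member: int | str = "mean"


@dataclass
class EnsembleResult:
    """Per-member global totals with summary statistics (Tg CH4 yr^-1)."""

    member_totals: np.ndarray
    regional_means: dict[str, float]
    n_members: int
    seed: int

    def __post_init__(self) -> None:
        self.member_totals = np.asarray(self.member_totals, dtype=float)
        if self.n_members < 1 or self.member_totals.size != self.n_members:
            raise ValueError("need at least one member total per member")

    @property
    def mean(self) -> float:
        return float(np.mean(self.member_totals))

    @property
    def sd(self) -> float:
        if self.n_members == 1:
            return 0.0
        return float(np.std(self.member_totals, ddof=1))

    def members_csv(self, path) -> None:
        pd.DataFrame(
            {"member": np.arange(self.n_members), "total_Tg": self.member_totals}
        ).to_csv(path, index=False)

    def summary_json(self, path=None) -> dict:
        d = {
            "mean_Tg": self.mean,
            "sd_Tg": self.sd,
            "regional_means_Tg": self.regional_means,
            "n_members": self.n_members,
            "seed": self.seed,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d


def cell_flux(
    rho_nat: float,
    ef_nat: float,
    rho_crop: float,
    ef_crop: float,
    f_crop: float,
    in_habitat: bool,
) -> float:
    """Annual CH4 flux of one cell (g CH4 m^-2 yr^-1), scalar form.

    The vectorized engine applies the same arithmetic grid-wide; this
    scalar form is the reference the engine is checked against.
    """
    for name, v in (
        ("rho_nat", rho_nat),
        ("ef_nat", ef_nat),
        ("rho_crop", rho_crop),
        ("ef_crop", ef_crop),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if not 0.0 <= f_crop <= 1.0:
        raise ValueError(f"cropland fraction must be in [0, 1], got {f_crop}")
    if not in_habitat:
        return 0.0
    hourly_ug = (1.0 - f_crop) * rho_nat * ef_nat + f_crop * rho_crop * ef_crop
    return hourly_ug * HOURS_PER_YEAR * UG_TO_G


def _habitat_and_density(
    drivers: DriverBundle,
    density_config: DensityConfig,
    table: DensityTable,
    threshold: float,
) -> tuple[np.ndarray, GridField]:
    tmin = min_monthly_temperature(drivers.temperature_months)
    mask = potential_habitat_mask(tmin, threshold)
    rho = density_field(drivers.landcover, drivers.gpp, mask, density_config, table)
    return mask, rho


def _flux_values(
    drivers: DriverBundle,
    mask: np.ndarray,
    rho: GridField,
    ef_assignment: Mapping[str, float],
    table: DensityTable,
) -> np.ndarray:
    spec = drivers.spec
    ef_nat = drivers.landcover.per_class_lookup(
        {c: ef_assignment[c] for c in drivers.landcover.classes}
    )
    f = drivers.cropland_fraction.values
    hourly_ug = np.where(
        mask,
        (1.0 - f) * rho.values * np.nan_to_num(ef_nat)
        + f * table.cropland_density * ef_assignment[CROPLAND],
        0.0,
    )
    values = np.nan_to_num(hourly_ug, nan=0.0) * HOURS_PER_YEAR * UG_TO_G
    values[drivers.landcover.missing] = np.nan
    return values


def run_member(
    drivers: DriverBundle,
    ef_assignment: Mapping[str, float],
    density_config: DensityConfig | None = None,
    table: DensityTable | None = None,
    threshold: float = DEFAULT_THRESHOLD_C,
    variant: str = "control",
    member: int | str = 0,
) -> tuple[EmissionField, float, dict[str, float]]:
    """One full estimate: habitat -> density -> flux -> totals.

    Returns the gridded flux, the global total (Tg CH4 yr^-1), and
    per-region totals (empty when the bundle carries no region mask).
    """
    density_config = density_config or DensityConfig()
    table = table or DensityTable()
    mask, rho = _habitat_and_density(drivers, density_config, table, threshold)
    values = _flux_values(drivers, mask, rho, ef_assignment, table)
    flux = GridField(drivers.spec, values, "g CH4 m-2 yr-1")
    total = area_weighted_total(flux)
    regional: dict[str, float] = {}
    if drivers.region_mask is not None:
        for label in drivers.region_mask.label_set:
            regional[label] = area_weighted_total(flux, drivers.region_mask, label)
    return (
        EmissionField(flux, drivers.year, variant=variant, member=member),
        total,
        regional,
    )


def run_ensemble(
    drivers: DriverBundle,
    ef_dataset,
    n: int = 1000,
    seed: int = 0,
    density_config: DensityConfig | None = None,
    table: DensityTable | None = None,
    threshold: float = DEFAULT_THRESHOLD_C,
) -> EnsembleResult:
    """Monte-Carlo EF ensemble of global (and regional) totals.

    Habitat and density are EF-independent, so they are computed once
    and each member's total reduces to a weighted sum of per-class
    biomass-area integrals times that member's EF draws — numerically
    identical to running :func:`run_member` per member.
    """
    from .emission_factors import draw_ef_assignment

    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    density_config = density_config or DensityConfig()
    table = table or DensityTable()
    mask, rho = _habitat_and_density(drivers, density_config, table, threshold)

    spec = drivers.spec
    a_m2 = area_field(spec) * 1e6
    f = np.nan_to_num(drivers.cropland_fraction.values)
    classes = list(drivers.landcover.classes)
    # per-class integral of (1-f) * rho * area over habitat cells, grams-rate basis
    class_weights = np.zeros(len(classes))
    region_class_weights: dict[str, np.ndarray] = {}
    region_crop: dict[str, float] = {}
    labels = ()
    if drivers.region_mask is not None:
        labels = drivers.region_mask.label_set
        for lab in labels:
            region_class_weights[lab] = np.zeros(len(classes))
    nat_w = np.where(mask, (1.0 - f) * rho.values * a_m2, 0.0)
    crop_w = np.where(mask, f * table.cropland_density * a_m2, 0.0)
    for i, cls in enumerate(classes):
        cells = drivers.landcover.cells_of(cls)
        class_weights[i] = np.sum(nat_w[cells])
        for lab in labels:
            region_class_weights[lab][i] = np.sum(
                nat_w[cells & drivers.region_mask.region(lab)]
            )
    crop_weight = float(np.sum(crop_w))
    for lab in labels:
        region_crop[lab] = float(np.sum(crop_w[drivers.region_mask.region(lab)]))

    to_tg = HOURS_PER_YEAR * UG_TO_G * 1e-12
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    totals = np.empty(n)
    regional_sums = {lab: 0.0 for lab in labels}
    draw_classes = classes + [CROPLAND]
    for m in range(n):
        assignment = draw_ef_assignment(ef_dataset, draw_classes, rng)
        efs = np.array([assignment[c] for c in classes])
        totals[m] = (efs @ class_weights + assignment[CROPLAND] * crop_weight) * to_tg
        for lab in labels:
            regional_sums[lab] += (
                efs @ region_class_weights[lab] + assignment[CROPLAND] * region_crop[lab]
            ) * to_tg
    regional_means = {lab: regional_sums[lab] / n for lab in labels}
    return EnsembleResult(totals, regional_means, n_members=n, seed=seed)


def offset_fraction(emission_total: float, sink_total: float) -> float:
    """Percentage of the soil oxidation sink offset by termite emission."""
    if sink_total <= 0:
        raise ValueError("sink total must be positive")
    return 100.0 * emission_total / sink_total


def net_flux_field(emission: EmissionField, sink: GridField) -> GridField:
    """Signed net CH4 flux, emission minus soil uptake (g CH4 m^-2 yr^-1).

    Positive cells are net sources, negative cells net sinks.
    """
    if sink.spec != emission.flux.spec:
        raise ValueError("sink grid does not match emission grid")
    return GridField(
        emission.flux.spec, emission.flux.values - sink.values, emission.flux.units
    )


def ch4_to_co2eq_carbon(
    tg_ch4: float, horizon: int = 100, gwp: Mapping[int, float] | None = None
) -> float:
    """CH4 mass flux to CO2-equivalent carbon (Tg C yr^-1) via GWP.

    ``tg_ch4 * GWP(horizon) * 12/44``; horizons 20 and 100 years carry
    the standard mass-basis GWP values 79.7 and 27.0 by default.
    """
    gwp = dict(DEFAULT_GWP if gwp is None else gwp)
    if horizon not in gwp:
        raise KeyError(f"no GWP value for horizon {horizon}")
    return tg_ch4 * gwp[horizon] * C_PER_CO2
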