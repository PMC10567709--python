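"""Synthetic driver-data generators.

The emission pipeline needs five gridded inputs per year — monthly mean
surface air temperature, a natural-vegetation land-cover map, cropland
areal fraction, annual gross primary production (GPP), and optionally a
soil CH4 oxidation sink — plus a flat sample of observed emission
factors.  This module generates all of them with the statistical
structure the analysis assumes, so the full pipeline runs and is tested
without any external download:

* temperature has a zonal-mean climatology, a seasonal cycle with
  opposite hemispheric phase, an optional secular warming trend and
  bounded seeded noise, guaranteeing both warm (habitat) and cold
  (non-habitat) latitude bands at baseline;
* land cover is a static zonal biome mosaic covering all fifteen
  natural-vegetation classes;
* cropland fraction is a subtropical/temperate belt with a secular
  expansion trend concentrated toward low latitudes;
* GPP is a land-cover baseline modulated by annual-mean temperature and
  a CO2-fertilization multiplier;
* emission factors are drawn from a zero-inflated truncated lognormal
  whose parameters are numerically moment-matched to the published
  summary statistics of the observational dataset (mean 3.81, s.d.
  4.10, range 0.0-25.26 ug CH4 g^-1 termite h^-1).

Every generator is a pure function of (config, year): a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .grid import GridSpec, GridField, RegionMask, area_weighted_total
from .landcover import NATURAL_CLASSES, MISSING_CODE, LandCoverMap

__all__ = [
    "WorldConfig",
    "EFGeneratorConfig",
    "ocean_mask",
    "gen_monthly_temperature",
    "gen_landcover",
    "gen_cropland_fraction",
    "gen_gpp",
    "gen_ef_sample",
    "gen_soil_sink",
    "gen_region_mask",
]

# Stream tags keep the per-driver RNG streams independent of each other.
_STREAM_TEMPERATURE = 1
_STREAM_GPP = 2
_STREAM_EF = 3


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of one synthetic world.

    Parameters
    ----------
    spec
        Grid geometry; the 5-degree (36 x 72) grid keeps full ensembles
        fast, and the 0.5-degree grid is a configuration change only.
    year_start, year_end
        Inclusive simulation years.
    warming_rate
        Linear surface warming, degrees C per decade, applied uniformly.
    cropland_trend
        Cropland areal-fraction increase per decade (added with a
        low-latitude weighting, then clipped to [0, 1]).
    co2_fertilization_rate
        Fractional GPP increase per decade from rising CO2; the per-year
        multiplier is ``1 + rate * (year - year_start) / 10``.
    seed
        Root RNG seed for every stochastic component.
    """

    spec: GridSpec = field(default_factory=GridSpec.coarse)
    year_start: int = 2001
    year_end: int = 2020
    warming_rate: float = 0.1
    cropland_trend: float = 0.01
    co2_fertilization_rate: float = 0.024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        for name in ("warming_rate", "cropland_trend", "co2_fertilization_rate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    def _check_year(self, year: int) -> None:
        if not (self.year_start <= year <= self.year_end):
            raise ValueError(
                f"year {year} outside configured range "
                f"[{self.year_start}, {self.year_end}]"
            )

    def fertilization_multiplier(self, year: int) -> float:
        return 1.0 + self.co2_fertilization_rate * (year - self.year_start) / 10.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = {
            "n_lat": self.spec.n_lat,
            "n_lon": self.spec.n_lon,
            "resolution": self.spec.resolution,
            "lat_origin": self.spec.lat_origin,
            "lon_origin": self.spec.lon_origin,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        d = dict(d)
        known = {
            "spec",
            "year_start",
            "year_end",
            "warming_rate",
            "cropland_trend",
            "co2_fertilization_rate",
            "seed",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown world-config key(s): {sorted(unknown)}")
        if "spec" in d and isinstance(d["spec"], dict):
            d["spec"] = GridSpec(**d["spec"])
        return cls(**d)


@dataclass(frozen=True)
class EFGeneratorConfig:
    """Targets for the synthetic emission-factor sample.

    Defaults reproduce the published summary of the observational
    dataset: mean 3.81 and s.d. 4.10 ug CH4 g^-1 termite h^-1 over the
    range 0.0-25.26, with a small fraction of exact zeros supplying the
    printed lower end of the range.
    """

    n: int = 10_000
    target_mean: float = 3.81
    target_sd: float = 4.10
    upper_bound: float = 25.26
    lower_bound: float = 0.0
    zero_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower_bound < self.upper_bound:
            raise ValueError("bounds must satisfy 0 <= lower < upper")
        if self.target_mean <= 0 or self.target_sd <= 0:
            raise ValueError("target mean and sd must be positive")
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ValueError("zero_fraction must be in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def ocean_mask(spec: GridSpec) -> np.ndarray:
    """The synthetic world's ocean: everything at |lon| >= 60.

    That leaves a single supercontinent spanning a third of the sphere,
    an earth-like land fraction, so habitat areas and global totals come
    out at geophysically plausible magnitudes.
    """
    lon = spec.lon_centers
    return np.broadcast_to(np.abs(lon) >= 60.0, spec.shape).copy()


# ---------------------------------------------------------------------------
# Temperature

def _annual_mean_temperature(config: WorldConfig, year: int) -> np.ndarray:
    """Zonal annual-mean temperature (deg C) including the warming trend."""
    phi = np.deg2rad(config.spec.lat_centers)
    t_ann = 27.0 * np.cos(phi) - 2.0
    t_ann = t_ann + config.warming_rate * (year - config.year_start) / 10.0
    return np.broadcast_to(t_ann[:, None], config.spec.shape).copy()


def _seasonal_amplitude(spec: GridSpec) -> np.ndarray:
    phi = np.deg2rad(spec.lat_centers)
    return np.broadcast_to((15.0 * np.sin(phi) ** 2)[:, None], spec.shape).copy()


def gen_monthly_temperature(config: WorldConfig, year: int) -> list[GridField]:
    """Twelve monthly mean temperature fields (deg C) for one year.

    Structure: zonal annual mean + seasonal cycle with opposite phase in
    the two hemispheres (amplitude growing poleward) + warming trend +
    bounded uniform noise (+-0.5 deg C).  Equatorial cells stay within
    [20, 30] deg C and polar bands dip below -8 deg C at baseline, so the
    habitat envelope always has both sides to separate.
    """
    config._check_year(year)
    spec = config.spec
    t_ann = _annual_mean_temperature(config, year)
    amp = _seasonal_amplitude(spec)
    hemisphere = np.broadcast_to(
        np.where(spec.lat_centers >= 0.0, 1.0, -1.0)[:, None], spec.shape
    )
    ocean = ocean_mask(spec)
    fields = []
    for month in range(1, 13):
        rng = _rng(config.seed, _STREAM_TEMPERATURE, year, month)
        # peak in July (month 7) in the northern hemisphere
        phase = np.cos(2.0 * np.pi * (month - 7) / 12.0)
        noise = rng.uniform(-0.5, 0.5, size=spec.shape)
        values = t_ann + amp * phase * hemisphere + noise
        values[ocean] = np.nan
        fields.append(GridField(spec, values, "degC"))
    return fields


# ---------------------------------------------------------------------------
# Land cover

# (|lat| upper edge, western-half class, eastern-half class); single-name
# entries fill the whole band.  Zonal belts: tropical forest at the
# equator through savanna/shrubland, temperate and boreal forest, then
# tundra and polar desert at the poles.
_BELTS: list[tuple[float, str, str]] = [
    (7.5, "tropical_evergreen_forest", "tropical_evergreen_forest"),
    (17.5, "tropical_deciduous_forest", "tropical_deciduous_forest"),
    (27.5, "savanna", "dense_shrubland"),
    (37.5, "desert", "open_shrubland"),
    (47.5, "grassland", "temperate_broadleaf_evergreen_forest"),
    (57.5, "temperate_deciduous_forest", "temperate_needleleaf_evergreen_forest"),
    (67.5, "mixed_forest", "boreal_evergreen_forest"),
    (75.0, "boreal_deciduous_forest", "boreal_deciduous_forest"),
    (82.5, "tundra", "tundra"),
    (90.1, "polar_desert", "polar_desert"),
]


def gen_landcover(config: WorldConfig) -> LandCoverMap:
    """Static zonal biome mosaic covering all fifteen natural classes.

    Bands are keyed on the absolute latitude of the cell center; some
    belts are split at longitude 0 so that every class in the density /
    emission-factor table appears on the default grid.
    """
    spec = config.spec
    codes = np.full(spec.shape, MISSING_CODE, dtype=int)
    abslat = np.abs(spec.lat_centers)
    west = spec.lon_centers < 0.0
    prev_edge = 0.0
    for edge, west_cls, east_cls in _BELTS:
        rows = (abslat > prev_edge - 1e-9) & (abslat <= edge)
        wi, ei = NATURAL_CLASSES.index(west_cls), NATURAL_CLASSES.index(east_cls)
        codes[np.ix_(rows, west)] = wi
        codes[np.ix_(rows, ~west)] = ei
        prev_edge = edge
    codes[ocean_mask(spec)] = MISSING_CODE
    return LandCoverMap(spec, codes)


# ---------------------------------------------------------------------------
# Cropland

def gen_cropland_fraction(config: WorldConfig, year: int) -> GridField:
    """Cropland areal fraction in [0, 1] for one year.

    Baseline is a subtropical/temperate belt (peak near |lat| = 32.5);
    the secular trend adds ``cropland_trend`` per decade weighted toward
    low latitudes, emulating historical conversion of tropical natural
    vegetation.  Deterministic: land-use reconstructions carry no
    weather-like noise.
    """
    config._check_year(year)
    spec = config.spec
    abslat = np.abs(spec.lat_centers)
    base = 0.25 * np.exp(-(((abslat - 32.5) / 15.0) ** 2))
    expansion_weight = np.exp(-((abslat / 35.0) ** 2))
    decades = (year - config.year_start) / 10.0
    frac = base + config.cropland_trend * decades * expansion_weight
    values = np.broadcast_to(np.clip(frac, 0.0, 1.0)[:, None], spec.shape).copy()
    values[ocean_mask(spec)] = np.nan
    return GridField(spec, values, "1")


# ---------------------------------------------------------------------------
# GPP

# Baseline annual GPP (g C m^-2 yr^-1) per land-cover class under a fully
# favourable temperature; tropical forest sits at 2500 so that the
# GPP-driven density relationship lands near the tabulated 8-11 g m^-2.
_GPP_BASE: dict[str, float] = {
    "tropical_evergreen_forest": 2500.0,
    "tropical_deciduous_forest": 2000.0,
    "temperate_broadleaf_evergreen_forest": 1300.0,
    "temperate_needleleaf_evergreen_forest": 1200.0,
    "temperate_deciduous_forest": 1300.0,
    "boreal_evergreen_forest": 800.0,
    "boreal_deciduous_forest": 700.0,
    "mixed_forest": 1100.0,
    "savanna": 1400.0,
    "grassland": 800.0,
    "dense_shrubland": 900.0,
    "open_shrubland": 500.0,
    "tundra": 120.0,
    "desert": 150.0,
    "polar_desert": 0.0,
}


def gen_gpp(
    config: WorldConfig, year: int, fertilization: float | None = None
) -> GridField:
    """Annual GPP (g C m^-2 yr^-1) for one year.

    ``base(landcover) * temperature modifier * fertilization * (1 + noise)``,
    truncated at zero.  The temperature modifier ramps linearly from 0 at
    -5 deg C annual mean to 1 at 25 deg C; ``fertilization`` defaults to
    the config's CO2 multiplier for the year.  Noise is multiplicative
    (+-5 %), so the fertilization ratio between two runs with the same
    seed is exact.
    """
    config._check_year(year)
    spec = config.spec
    if fertilization is None:
        fertilization = config.fertilization_multiplier(year)
    lc = gen_landcover(config)
    base = lc.per_class_lookup(_GPP_BASE)
    t_ann = _annual_mean_temperature(config, year)
    modifier = np.clip((t_ann + 5.0) / 30.0, 0.0, 1.0)
    rng = _rng(config.seed, _STREAM_GPP, year)
    noise = 1.0 + rng.uniform(-0.05, 0.05, size=spec.shape)
    values = np.clip(base * modifier * fertilization * noise, 0.0, None)
    values[ocean_mask(spec)] = np.nan
    return GridField(spec, values, "g C m-2 yr-1")


# ---------------------------------------------------------------------------
# Emission factors

def _truncated_lognormal_moments(
    mu: float, sigma: float, upper: float
) -> tuple[float, float]:
    """Mean and second moment of a lognormal truncated to (0, upper]."""
    with np.errstate(over="ignore", invalid="ignore"):
        z = (np.log(upper) - mu) / sigma
        denom = stats.norm.cdf(z)
        m1 = np.exp(mu + 0.5 * sigma**2) * stats.norm.cdf(z - sigma) / denom
        m2 = np.exp(2.0 * mu + 2.0 * sigma**2) * stats.norm.cdf(z - 2.0 * sigma) / denom
    return m1, m2


def _match_ef_moments(config: EFGeneratorConfig) -> tuple[float, float]:
    """Solve for (mu, sigma) of the underlying normal so that the
    zero-inflated truncated lognormal hits the target mean and s.d.
    """
    p0 = config.zero_fraction
    target_m1 = config.target_mean
    target_m2 = config.target_sd**2 + config.target_mean**2

    def residuals(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        m1, m2 = _truncated_lognormal_moments(mu, sigma, config.upper_bound)
        return [(1.0 - p0) * m1 - target_m1, (1.0 - p0) * m2 - target_m2]

    # start from the untruncated lognormal matching the continuous part
    cont_mean = target_m1 / (1.0 - p0)
    cont_m2 = target_m2 / (1.0 - p0)
    cv2 = max(cont_m2 / cont_mean**2 - 1.0, 1e-6)
    sigma0 = np.sqrt(np.log1p(cv2))
    mu0 = np.log(cont_mean) - 0.5 * sigma0**2
    sol = optimize.root(residuals, x0=[mu0, np.log(sigma0)], tol=1e-12)
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    resid = residuals(sol.x)
    bad = not np.all(np.isfinite(resid))
    if bad or not sol.success or max(abs(resid[0]), abs(resid[1] / target_m2)) > 1e-6:
        raise ValueError(
            "emission-factor moment targets are not attainable under the "
            f"truncation bound {config.upper_bound}"
        )
    return mu, sigma


def gen_ef_sample(config: EFGeneratorConfig):
    """Draw a synthetic emission-factor sample (ug CH4 g^-1 termite h^-1).

    A fraction ``zero_fraction`` of draws are exact zeros (the printed
    lower end of the observed range); the rest come from a lognormal
    truncated to (0, upper_bound] whose (mu, sigma) are root-found so the
    overall mixture has the target mean and standard deviation.
    """
    from .emission_factors import EFDataset

    rng = _rng(config.seed, _STREAM_EF)
    if config.zero_fraction >= 1.0:
        return EFDataset(np.zeros(config.n), source="synthetic")
    mu, sigma = _match_ef_moments(config)
    zeros = rng.random(config.n) < config.zero_fraction
    n_pos = int(np.sum(~zeros))
    # inverse-CDF sampling of the truncated lognormal
    z_up = stats.norm.cdf((np.log(config.upper_bound) - mu) / sigma)
    u = rng.random(n_pos) * z_up
    draws = np.exp(mu + sigma * stats.norm.ppf(u))
    values = np.zeros(config.n)
    values[~zeros] = np.minimum(draws, config.upper_bound)
    if config.lower_bound > 0.0:
        values = np.maximum(values, config.lower_bound)
    return EFDataset(values, source="synthetic")


# ---------------------------------------------------------------------------
# Soil CH4 oxidation sink

def gen_soil_sink(config: WorldConfig, year: int, total_tg: float = 31.6) -> GridField:
    """Soil methanotrophic CH4 uptake (g CH4 m^-2 yr^-1), prescribed total.

    A smooth positive field over land, scaled so its area-weighted global
    total equals ``total_tg`` (Tg CH4 yr^-1).  The spatial shape (warm
    regions take up more) is schematic; the sink is a consumed input
    here, not a process simulation.
    """
    config._check_year(year)
    if total_tg < 0:
        raise ValueError("soil sink total must be non-negative")
    spec = config.spec
    phi = np.deg2rad(spec.lat_centers)
    shape = np.broadcast_to((0.2 + np.cos(phi))[:, None], spec.shape).copy()
    shape[ocean_mask(spec)] = np.nan
    raw = GridField(spec, shape, "g CH4 m-2 yr-1")
    if total_tg == 0.0:
        values = np.where(np.isnan(shape), np.nan, 0.0)
        return GridField(spec, values, "g CH4 m-2 yr-1")
    scale = total_tg / area_weighted_total(raw)
    return GridField(spec, shape * scale, "g CH4 m-2 yr-1")


# ---------------------------------------------------------------------------
# Regions

def gen_region_mask(spec: GridSpec) -> RegionMask:
    """Bounding-box regions of the synthetic world (Africa-like and
    South-America-like tropical blocks, everything else 'Other')."""
    lat = spec.lat_centers[:, None]
    lon = spec.lon_centers[None, :]
    labels = np.full(spec.shape, "Other", dtype=object)
    labels[np.broadcast_to((lon >= 5) & (lon < 60) & (np.abs(lat) < 40), spec.shape)] = "Africa"
    labels[
        np.broadcast_to((lon >= -60) & (lon < -5) & (lat > -60) & (lat < 15), spec.shape)
    ] = "South America"
    labels[ocean_mask(spec)] = ""
    return RegionMask(spec, labels, ("Africa", "South America", "Other"))


def ef_sample_to_csv(dataset, path) -> None:
    """One-column CSV with header ``ef_ug_per_g_per_h``."""
    pd.DataFrame({"ef_ug_per_g_per_h": dataset.values}).to_csv(path, index=False)


def ef_sample_from_csv(path):
    from .emission_factors import EFDataset

    df = pd.read_csv(path)
    if "ef_ug_per_g_per_h" not in df.columns:
        raise ValueError(f"{path}: expected column 'ef_ug_per_g_per_h'")
    return EFDataset(df["ef_ug_per_g_per_h"].to_numpy(float), source=str(path))
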