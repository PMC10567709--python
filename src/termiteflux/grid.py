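"""Raster lattice, cell geometry, masks, aggregation and NetCDF/CSV I/O.

Everything downstream (habitat masking, density mapping, emission
upscaling) operates on a regular latitude-longitude grid.  Cells are
center-registered: a 0.5-degree global grid has centers at
-89.75 ... 89.75 and -179.75 ... 179.75.  Ocean / no-data cells carry an
explicit missing marker (NaN), never zero, so a zero remains a meaningful
flux value.

The Earth is modelled as a sphere of radius 6371.0 km; the sub-0.3 %
ellipsoidal correction is irrelevant at the precision of a global
biogenic-flux inventory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "GridField",
    "RegionMask",
    "UnitsError",
    "cell_area",
    "band_areas",
    "area_field",
    "area_weighted_total",
    "read_field",
    "write_field",
    "read_field_csv",
    "write_field_csv",
]


class UnitsError(ValueError):
    """Raised when a field's units are incompatible with an operation."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular global latitude-longitude lattice.

    Parameters
    ----------
    n_lat, n_lon
        Number of rows (latitude bands) and columns (longitude bands).
    resolution
        Cell size in degrees; ``n_lat * resolution`` must equal 180 and
        ``n_lon * resolution`` must equal 360.
    lat_origin, lon_origin
        Southern / western edge of the grid (degrees).  Coordinates refer
        to cell *centers*.
    """

    n_lat: int = 360
    n_lon: int = 720
    resolution: float = 0.5
    lat_origin: float = -90.0
    lon_origin: float = -180.0

    def __post_init__(self) -> None:
        if not np.isclose(self.n_lat * self.resolution, 180.0):
            raise ValueError(
                f"n_lat * resolution must be 180, got {self.n_lat * self.resolution}"
            )
        if not np.isclose(self.n_lon * self.resolution, 360.0):
            raise ValueError(
                f"n_lon * resolution must be 360, got {self.n_lon * self.resolution}"
            )

    @classmethod
    def coarse(cls) -> "GridSpec":
        """A 5-degree (36 x 72) grid used for fast test-scale worlds."""
        return cls(n_lat=36, n_lon=72, resolution=5.0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lat_centers(self) -> np.ndarray:
        r = self.resolution
        return self.lat_origin + r / 2.0 + r * np.arange(self.n_lat)

    @property
    def lon_centers(self) -> np.ndarray:
        r = self.resolution
        return self.lon_origin + r / 2.0 + r * np.arange(self.n_lon)


@dataclass
class GridField:
    """A single-variable layer on a :class:`GridSpec`.

    ``values`` is a float array of shape ``(n_lat, n_lon)``; missing
    (ocean / no-data) cells are NaN and are excluded from every
    aggregation.
    """

    spec: GridSpec
    values: np.ndarray
    units: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.spec.shape}"
            )
        if not self.units:
            raise ValueError("units must be a non-empty string")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "GridField":
        return GridField(self.spec, self.values.copy(), self.units)


@dataclass
class RegionMask:
    """Per-cell region labels (e.g. Africa / South America / Other).

    ``labels`` is an object array of strings aligned with the grid; the
    empty string marks missing (ocean) cells.  Every non-missing cell
    belongs to exactly one region, so regional totals partition the
    global total.
    """

    spec: GridSpec
    labels: np.ndarray
    label_set: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != self.spec.shape:
            raise ValueError("labels shape does not match grid")
        found = sorted({str(x) for x in self.labels.ravel() if x})
        if not self.label_set:
            self.label_set = tuple(found)
        else:
            extra = set(found) - set(self.label_set)
            if extra:
                raise ValueError(f"labels outside declared label_set: {sorted(extra)}")

    def region(self, label: str) -> np.ndarray:
        if label not in self.label_set:
            raise KeyError(f"unknown region label {label!r}")
        return self.labels == label


def cell_area(lat_band_index: int, spec: GridSpec) -> float:
    """Area (km^2) of one cell in latitude band ``lat_band_index``.

    On a sphere of radius R the area of a cell spanning longitude width
    d_lambda between latitudes phi_bottom and phi_top is
    ``R^2 * d_lambda * (sin phi_top - sin phi_bottom)``; it is identical
    for all cells in a band.
    """
    if not 0 <= lat_band_index < spec.n_lat:
        raise IndexError(
            f"latitude band index {lat_band_index} out of range [0, {spec.n_lat})"
        )
    r = spec.resolution
    phi_bottom = np.deg2rad(spec.lat_origin + lat_band_index * r)
    phi_top = np.deg2rad(spec.lat_origin + (lat_band_index + 1) * r)
    dlam = np.deg2rad(r)
    return float(EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_top) - np.sin(phi_bottom)))


def band_areas(spec: GridSpec) -> np.ndarray:
    """Cell areas (km^2) for every latitude band, shape ``(n_lat,)``."""
    r = spec.resolution
    edges = np.deg2rad(spec.lat_origin + r * np.arange(spec.n_lat + 1))
    dlam = np.deg2rad(r)
    return EARTH_RADIUS_KM**2 * dlam * np.diff(np.sin(edges))


def area_field(spec: GridSpec) -> np.ndarray:
    """Per-cell areas (km^2) broadcast to the full grid shape."""
    return np.broadcast_to(band_areas(spec)[:, None], spec.shape).copy()


_PER_M2_TOKENS = ("m-2", "m^-2", "m^{-2}", "m⁻²", "/m2", "m2 ")


def _require_per_m2(units: str) -> None:
    u = units.replace(" ", "").lower()
    if not any(tok.replace(" ", "") in u for tok in ("m-2", "m^-2", "m⁻²", "/m2")):
        raise UnitsError(
            f"area_weighted_total needs a per-m2 rate field, got units {units!r}"
        )


def area_weighted_total(
    field: GridField,
    region_mask: RegionMask | None = None,
    label: str | None = None,
) -> float:
    """Global (or regional) total of a per-m^2 rate field, in Tg yr^-1.

    Each non-missing cell contributes ``value * area_km2 * 1e6`` grams,
    and the sum is scaled to teragrams by 1e-12.  Missing cells are
    skipped.  When ``region_mask`` and ``label`` are given only cells of
    that region are summed.
    """
    _require_per_m2(field.units)
    areas = area_field(field.spec)
    sel = ~field.missing
    if region_mask is not None:
        if label is None:
            raise ValueError("a region label is required with a region mask")
        sel &= region_mask.region(label)
    grams = np.sum(field.values[sel] * areas[sel]) * 1e6
    return float(grams * 1e-12)


def masked_area_km2(mask: np.ndarray, spec: GridSpec) -> float:
    """Total area (km^2) of cells where ``mask`` is True."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spec.shape:
        raise ValueError("mask shape does not match grid")
    return float(np.sum(area_field(spec)[mask]))


# ---------------------------------------------------------------------------
# I/O — CF-style NetCDF via xarray, plus a tiny CSV fallback for fixtures.
# The scipy backend (NetCDF3) is used so files stay dependency-light.

def write_field(path, field: GridField, name: str) -> None:
    """Write one field as a CF-style NetCDF variable with a units attribute."""
    da = xr.DataArray(
        field.values,
        dims=("lat", "lon"),
        coords={"lat": field.spec.lat_centers, "lon": field.spec.lon_centers},
        name=name,
        attrs={"units": field.units},
    )
    da.to_netcdf(path, engine="scipy")


def read_field(path, name: str, spec: GridSpec | None = None) -> GridField:
    """Read ``name`` from a NetCDF file into a :class:`GridField`.

    If ``spec`` is given the file's lat/lon coordinates must match it; a
    file with no units attribute yields units ``"unknown"`` with a
    logged warning.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if "lat" not in ds.coords or "lon" not in ds.coords:
            raise ValueError(f"{path}: missing lat/lon coordinate variables")
        if name not in ds:
            raise KeyError(f"{path}: no variable named {name!r}")
        da = ds[name].load()
    if spec is None:
        spec = _spec_from_coords(da["lat"].values, da["lon"].values)
    else:
        if da.shape != spec.shape:
            raise ValueError(
                f"{path}: variable shape {da.shape} does not match grid {spec.shape}"
            )
        if not (
            np.allclose(da["lat"].values, spec.lat_centers)
            and np.allclose(da["lon"].values, spec.lon_centers)
        ):
            raise ValueError(f"{path}: coordinates do not match the requested grid")
    units = da.attrs.get("units", "")
    if not units:
        logger.warning("%s:%s has no units attribute; using 'unknown'", path, name)
        warnings.warn(f"{path}:{name} has no units attribute", stacklevel=2)
        units = "unknown"
    return GridField(spec, np.asarray(da.values, dtype=float), units)


def _spec_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridSpec:
    res = float(lat[1] - lat[0]) if len(lat) > 1 else 180.0 / len(lat)
    return GridSpec(
        n_lat=len(lat),
        n_lon=len(lon),
        resolution=res,
        lat_origin=float(lat[0]) - res / 2.0,
        lon_origin=float(lon[0]) - res / 2.0,
    )


def write_field_csv(path, field: GridField) -> None:
    """Tiny-fixture fallback: tidy CSV of (lat, lon, value), missing omitted."""
    lat = np.repeat(field.spec.lat_centers, field.spec.n_lon)
    lon = np.tile(field.spec.lon_centers, field.spec.n_lat)
    vals = field.values.ravel()
    keep = ~np.isnan(vals)
    pd.DataFrame({"lat": lat[keep], "lon": lon[keep], "value": vals[keep]}).to_csv(
        path, index=False
    )


def read_field_csv(path, spec: GridSpec, units: str = "unknown") -> GridField:
    df = pd.read_csv(path)
    values = np.full(spec.shape, np.nan)
    li = np.searchsorted(spec.lat_centers, df["lat"].values)
    lj = np.searchsorted(spec.lon_centers, df["lon"].values)
    if (
        li.max(initial=0) >= spec.n_lat
        or lj.max(initial=0) >= spec.n_lon
        or not np.allclose(spec.lat_centers[li], df["lat"].values)
        or not np.allclose(spec.lon_centers[lj], df["lon"].values)
    ):
        raise ValueError(f"{path}: coordinates do not fall on grid cell centers")
    values[li, lj] = df["value"].values
    return GridField(spec, values, units)
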