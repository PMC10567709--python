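"""Emission-factor dataset, summary statistics, and per-member sampling.

An emission factor (EF) is the CH4 release per unit termite biomass and
time, in ug CH4 g^-1 termite h^-1.  Observed EFs span 0.0-25.26 with a
strongly right-skewed distribution (mean 3.81, s.d. 4.10), so the
ensemble machinery samples them stochastically: each ensemble member
draws one EF per land-cover class, uniformly with replacement from the
observation list, and reuses that draw for every cell of the class.

Drawing per class (not per cell) is deliberate: i.i.d. per-cell draws
would average away the EF variance over ~1e5 grid cells and collapse the
ensemble spread of the global total, which empirically is of the same
order as the mean.  A prescribed per-class alternative (the Sanderson
table) is provided for variant runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .landcover import load_landcover_table, CROPLAND

__all__ = [
    "EFDataset",
    "EFScheme",
    "EFSummary",
    "ef_summary",
    "draw_ef_assignment",
    "prescribed_ef",
    "prescribed_ef_table",
]


@dataclass
class EFDataset:
    """A flat sample of observed emission factors (ug CH4 g^-1 termite h^-1)."""

    values: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("EF dataset must be non-empty")
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("EF values must be finite and non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EFScheme:
    """Which EF source an estimator variant uses.

    ``empirical_sample`` draws per class per ensemble member from a
    dataset; ``prescribed_per_class`` uses the fixed per-class table.
    """

    mode: str = "empirical_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("empirical_sample", "prescribed_per_class"):
            raise ValueError(f"unknown EF scheme mode {self.mode!r}")


class EFSummary(NamedTuple):
    mean: float
    sd: float
    min: float
    max: float


def ef_summary(dataset: EFDataset) -> EFSummary:
    """Sample mean, s.d. (n-1 denominator), min and max of a dataset.

    A single-observation dataset has no defined sample s.d.; it is
    reported as 0 with a warning.
    """
    v = dataset.values
    if v.size == 1:
        warnings.warn("sample s.d. undefined for n = 1; reporting 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(v, ddof=1))
    return EFSummary(float(np.mean(v)), sd, float(np.min(v)), float(np.max(v)))


def draw_ef_assignment(
    dataset: EFDataset, classes: Iterable[str], rng: np.random.Generator
) -> dict[str, float]:
    """One ensemble member's per-class EF map.

    One independent uniform draw with replacement from the dataset per
    land-cover class (cropland included); the member reuses its draw for
    every cell of that class.
    """
    classes = list(classes)
    idx = rng.integers(0, len(dataset), size=len(classes))
    return {cls: float(dataset.values[i]) for cls, i in zip(classes, idx)}


def prescribed_ef_table() -> dict[str, float]:
    """The fixed per-class EF table (ug CH4 g^-1 termite h^-1)."""
    return {
        k: float(v) for k, v in load_landcover_table()["ef_ug_per_g_per_h"].items()
    }


def prescribed_ef(cls: str) -> float:
    """Fixed tabulated EF for one land-cover/use class."""
    table = prescribed_ef_table()
    if cls not in table:
        raise KeyError(f"unknown land-cover class {cls!r}")
    return table[cls]
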