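"""Global light-temperature mismatch impact index from climate rasters.

Warming shifts temperatures while the photoperiod cycle stays fixed, so
regions with strong seasonality that are projected to warm most face the
greatest risk of warm temperatures coinciding with short days. The impact
metric is

    raw = seasonality * projected warming          [degC²]
    index = (raw - min) / (max - min)              in [0, 1]

min-max scaled over valid cells, so 0 is the globally smallest effect and
1 the greatest. Two seasonality definitions are supported: the mean
monthly maximum minus mean monthly minimum over the year (``annual_range``,
the default) and the absolute July-January mean-temperature difference
(``july_january``). NaN cells are nodata and propagate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyDomainError, InvalidOptionError, InvalidSpecificationError

SEASONALITY_DEFINITIONS = ("annual_range", "july_january")


@dataclass
class ClimateStack:
    """12 monthly min + 12 monthly max grids and one projected-warming grid.

    All grids share shape; NaN marks nodata and the masks are unioned, so a
    cell missing in any band is invalid everywhere.
    """

    tmin_monthly: np.ndarray  # (12, nrow, ncol), degC
    tmax_monthly: np.ndarray  # (12, nrow, ncol), degC
    warming: np.ndarray  # (nrow, ncol), degC increase under the scenario

    def __post_init__(self):
        self.tmin_monthly = np.asarray(self.tmin_monthly, dtype=float)
        self.tmax_monthly = np.asarray(self.tmax_monthly, dtype=float)
        self.warming = np.asarray(self.warming, dtype=float)
        if self.tmin_monthly.shape != self.tmax_monthly.shape:
            raise InvalidSpecificationError("tmin and tmax stacks differ in shape")
        if self.tmin_monthly.ndim != 3 or self.tmin_monthly.shape[0] != 12:
            raise InvalidSpecificationError(
                f"monthly stacks must be (12, nrow, ncol), got {self.tmin_monthly.shape}"
            )
        if self.warming.shape != self.tmin_monthly.shape[1:]:
            raise InvalidSpecificationError("warming grid shape mismatch")
        # union the nodata masks across all 25 bands
        invalid = (
            np.isnan(self.tmin_monthly).any(axis=0)
            | np.isnan(self.tmax_monthly).any(axis=0)
            | np.isnan(self.warming)
        )
        self.tmin_monthly[:, invalid] = np.nan
        self.tmax_monthly[:, invalid] = np.nan
        self.warming[invalid] = np.nan
        valid = ~invalid
        if np.any(self.tmax_monthly[:, valid] < self.tmin_monthly[:, valid]):
            raise InvalidSpecificationError("tmax < tmin at some valid cell")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.warming)


@dataclass
class MismatchIndexGrid:
    index: np.ndarray  # in [0, 1] at valid cells, NaN elsewhere
    provenance: dict = field(default_factory=dict)


def seasonality(stack: ClimateStack, definition: str = "annual_range") -> np.ndarray:
    """Per-cell seasonality (degC) under the chosen definition.

    ``annual_range``: mean over months of tmax minus mean of tmin.
    ``july_january``: |mean temperature in July − in January| with monthly
    mean = (tmin + tmax) / 2; months are indexed January-first.
    """
    if definition == "annual_range":
        return stack.tmax_monthly.mean(axis=0) - stack.tmin_monthly.mean(axis=0)
    if definition == "july_january":
        tmean = (stack.tmin_monthly + stack.tmax_monthly) / 2.0
        return np.abs(tmean[6] - tmean[0])
    raise InvalidOptionError(
        f"unknown seasonality definition {definition!r}; "
        f"choose from {SEASONALITY_DEFINITIONS}"
    )


def mismatch_index(
    stack: ClimateStack, definition: str = "annual_range"
) -> MismatchIndexGrid:
    """Min-max scaled seasonality x warming product.

    Invariant under any positive affine transform of the raw metric (in
    particular, uniformly rescaling the warming grid leaves the index
    unchanged), and preserves the raw metric's cell ranking. A degenerate
    all-equal raw metric (e.g. zero warming everywhere) yields an all-zero
    index with a warning.
    """
    season = seasonality(stack, definition)
    raw = season * stack.warming
    valid = np.isfinite(raw)
    if not np.any(valid):
        raise EmptyDomainError("no valid cells in the climate stack")
    lo = float(raw[valid].min())
    hi = float(raw[valid].max())
    index = np.full(raw.shape, np.nan)
    if hi == lo:
        warnings.warn(
            "raw mismatch metric constant over valid cells; index set to 0",
            stacklevel=2,
        )
        index[valid] = 0.0
    else:
        index[valid] = (raw[valid] - lo) / (hi - lo)
    return MismatchIndexGrid(
        index=index,
        provenance={
            "seasonality_definition": definition,
            "raw_min": lo,
            "raw_max": hi,
            "n_valid_cells": int(valid.sum()),
        },
    )
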