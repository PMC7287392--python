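"""Synthetic monthly climate rasters with a latitudinal seasonality gradient.

Stands in for gridded monthly-climatology products (e.g. WorldClim) in
tests and demos. Monthly mean temperature at a cell follows a sinusoidal
annual cycle whose amplitude grows with |latitude| and whose phase flips
between hemispheres (northern peak in July, southern in January); the
projected-warming surface grows toward the poles, emulating polar
amplification under a high-emission scenario. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import numpy as np

from ..climate import ClimateStack
from ..errors import InvalidSpecificationError


def simulate_climate_rasters(
    shape: tuple[int, int] = (36, 72),
    amplitude_max_c: float = 15.0,
    equator_mean_c: float = 28.0,
    pole_cooling_c: float = 38.0,
    diurnal_range_c: float = 8.0,
    warming_base_c: float = 1.5,
    warming_polar_extra_c: float = 3.5,
    noise_sd: float = 0.0,
    nodata_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ClimateStack:
    """Monthly min/max temperature stacks plus a warming grid.

    Rows span latitude +90 (row 0) to −90; columns are longitude.
    Seasonal amplitude is ``amplitude_max_c * |lat|/90``, so seasonality is
    monotone in |latitude| when ``noise_sd`` is zero. ``nodata_fraction``
    masks a random subset of cells with NaN in all 25 grids (emulating
    ocean masks). Gaussian noise perturbs the monthly mean only, keeping
    tmax − tmin = ``diurnal_range_c`` > 0 everywhere.
    """
    nrow, ncol = shape
    if nrow < 1 or ncol < 1:
        raise InvalidSpecificationError(f"grid shape must be positive, got {shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lat = np.linspace(90.0, -90.0, nrow)[:, None] * np.ones((1, ncol))
    rel = np.abs(lat) / 90.0
    annual_mean = equator_mean_c - pole_cooling_c * rel
    amplitude = amplitude_max_c * rel
    # phase: cos peaks at month index 6 (July) in the north, 0 (January)
    # in the south
    months = np.arange(12)
    north = lat >= 0
    tmean = np.empty((12, nrow, ncol))
    for m in months:
        phase_n = np.cos(2 * np.pi * (m - 6) / 12)
        phase_s = np.cos(2 * np.pi * m / 12)
        cyc = np.where(north, phase_n, phase_s)
        tmean[m] = annual_mean + amplitude * cyc
    if noise_sd > 0:
        tmean = tmean + rng.normal(0.0, noise_sd, size=tmean.shape)

    tmin = tmean - diurnal_range_c / 2.0
    tmax = tmean + diurnal_range_c / 2.0
    warming = warming_base_c + warming_polar_extra_c * rel
    if noise_sd > 0:
        warming = np.maximum(
            warming + rng.normal(0.0, noise_sd, size=warming.shape), 0.0
        )

    if nodata_fraction > 0:
        mask = rng.random((nrow, ncol)) < nodata_fraction
        tmin[:, mask] = np.nan
        tmax[:, mask] = np.nan
        warming[mask] = np.nan

    return ClimateStack(tmin_monthly=tmin, tmax_monthly=tmax, warming=warming)
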