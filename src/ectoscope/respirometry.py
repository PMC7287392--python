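"""Closed-chamber respirometry: oxygen-depletion slopes and mass-specific MO2.

A fish sits in a sealed chamber of known volume; dissolved O2 concentration
(μmol O2 L⁻¹) is logged while it declines. The whole-animal oxygen
consumption rate is

    MO2 = (-slope) * V / m        [μmol O2 g⁻¹ min⁻¹]

with slope the OLS fit of concentration on time (μmol L⁻¹ min⁻¹), V the
chamber volume (L) and m the wet mass (g). Resting rates come from a 27 ml
chamber monitored for 30 min; maximal rates from a 130 ml swim-chamber
recorded for about 10 min while the fish swims near its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError, RisingOxygenError

MIN_SAMPLES = 10

#: Default r² below which a slope fit is flagged (warning only, value kept).
DEFAULT_R2_THRESHOLD = 0.9

# Garcia & Gordon (1992) refit of Benson & Krause, μmol O2 kg⁻¹ at 100% air
# saturation; used by the unit-conversion helper only.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


@dataclass
class RespirometryTrace:
    """A sealed-chamber O2 depletion recording for one fish at one phase."""

    time_min: np.ndarray
    o2_umol_per_l: np.ndarray
    chamber_volume_l: float
    fish_mass_g: float
    test_temp_c: float
    phase: str  # 'rest' or 'max'
    fish_id: str

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.o2_umol_per_l = np.asarray(self.o2_umol_per_l, dtype=float)
        if self.time_min.shape != self.o2_umol_per_l.shape:
            raise InvalidInputError("time and O2 arrays differ in length")
        if self.time_min.size < MIN_SAMPLES:
            raise InvalidInputError(
                f"trace needs >= {MIN_SAMPLES} samples, got {self.time_min.size}"
            )
        if np.any(np.diff(self.time_min) <= 0):
            raise InvalidInputError("time stamps must be strictly increasing")
        if np.any(self.o2_umol_per_l < 0):
            raise InvalidInputError("O2 concentrations must be non-negative")
        if self.phase not in ("rest", "max"):
            raise InvalidInputError(f"phase must be 'rest' or 'max', got {self.phase!r}")
        if self.chamber_volume_l <= 0 or self.fish_mass_g <= 0:
            raise InvalidInputError("chamber volume and fish mass must be positive")


@dataclass
class SlopeFit:
    slope_umol_l_min: float
    intercept_umol_l: float
    r2: float
    window_min: tuple[float, float]
    n_points: int


@dataclass
class Mo2Measurement:
    """Mass-specific oxygen consumption rate derived from one trace."""

    fish_id: str
    phase: str
    test_temp_c: float
    mo2_umol_g_min: float
    fit_r2: float
    window_used: tuple[float, float]
    qc_flags: list[str] = field(default_factory=list)


def fit_o2_slope(
    trace: RespirometryTrace, window: tuple[float, float] | None = None
) -> SlopeFit:
    """OLS slope of O2 concentration against time over ``window``.

    ``window`` is an inclusive ``(t_start, t_end)`` interval in minutes;
    ``None`` uses the full recording. Returns the slope in μmol L⁻¹ min⁻¹
    together with r² for quality control. A perfectly flat trace has zero
    slope and, by convention, r² = 0 (no variance explained).
    """
    t, y = trace.time_min, trace.o2_umol_per_l
    if window is not None:
        lo, hi = window
        if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            raise InvalidInputError(
                f"window {window} outside trace extent ({t[0]}, {t[-1]})"
            )
        keep = (t >= lo) & (t <= hi)
        t, y = t[keep], y[keep]
    if t.size < MIN_SAMPLES:
        raise InsufficientDataError(
            f"{t.size} points in window; need >= {MIN_SAMPLES}"
        )
    if np.ptp(y) == 0.0:
        # linregress returns nan r for constant y; a flat trace is a valid
        # (if degenerate) zero-slope fit.
        return SlopeFit(0.0, float(y[0]), 0.0, (float(t[0]), float(t[-1])), t.size)
    res = stats.linregress(t, y)
    return SlopeFit(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        (float(t[0]), float(t[-1])),
        t.size,
    )


def compute_mo2(
    trace: RespirometryTrace,
    window: tuple[float, float] | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    trim_initial_min: float = 0.0,
    blank_slope_umol_l_min: float = 0.0,
) -> Mo2Measurement:
    """Mass-specific MO2 from a depletion trace.

    ``trim_initial_min`` drops the first k minutes (settling artefacts)
    before fitting. ``blank_slope_umol_l_min`` subtracts a background
    (microbial) depletion slope measured on an empty chamber; default 0,
    i.e. no correction. Non-declining O2 raises :class:`RisingOxygenError`
    rather than returning a zero or negative rate; a poor fit
    (r² < ``r2_threshold``) only flags the measurement.
    """
    if trim_initial_min > 0:
        t0 = trace.time_min[0] + trim_initial_min
        hi = trace.time_min[-1] if window is None else window[1]
        lo = t0 if window is None else max(window[0], t0)
        window = (lo, hi)
    fit = fit_o2_slope(trace, window)
    slope = fit.slope_umol_l_min - blank_slope_umol_l_min
    if slope >= 0:
        raise RisingOxygenError(
            f"fish {trace.fish_id} ({trace.phase}, {trace.test_temp_c}degC): "
            f"O2 slope {slope:.4g} μmol/L/min is not negative; no consumption measurable"
        )
    flags = []
    if fit.r2 < r2_threshold:
        flags.append(f"low_r2:{fit.r2:.3f}")
    mo2 = -slope * trace.chamber_volume_l / trace.fish_mass_g
    return Mo2Measurement(
        fish_id=trace.fish_id,
        phase=trace.phase,
        test_temp_c=trace.test_temp_c,
        mo2_umol_g_min=float(mo2),
        fit_r2=fit.r2,
        window_used=fit.window_min,
        qc_flags=flags,
    )


def o2_saturation_umol_per_l(temp_c: float, salinity_psu: float = 0.0) -> float:
    """Dissolved O2 at 100% air saturation (μmol L⁻¹), Garcia & Gordon (1992).

    Freshwater default. Density correction kg→L is ignored (<0.3% at the
    temperatures used here), consistent with common respirometry practice.
    """
    ts = np.log((298.15 - temp_c) / (273.15 + temp_c))
    lnc = sum(a * ts**i for i, a in enumerate(_GG_A))
    lnc += salinity_psu * sum(b * ts**i for i, b in enumerate(_GG_B))
    lnc += _GG_C0 * salinity_psu**2
    return float(np.exp(lnc))


def o2_from_percent_saturation(
    percent_sat: np.ndarray, temp_c: float, salinity_psu: float = 0.0
) -> np.ndarray:
    """Convert % air saturation readings to μmol O2 L⁻¹."""
    return np.asarray(percent_sat, dtype=float) / 100.0 * o2_saturation_umol_per_l(
        temp_c, salinity_psu
    )


def o2_from_mg_per_l(mg_per_l: np.ndarray) -> np.ndarray:
    """Convert mg O2 L⁻¹ to μmol O2 L⁻¹ (molar mass 31.998 g mol⁻¹)."""
    return np.asarray(mg_per_l, dtype=float) * 1000.0 / 31.998
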