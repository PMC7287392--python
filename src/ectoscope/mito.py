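"""Mitochondrial oxygraph analysis: respiration states, RCR and P:O ratio.

Isolated-mitochondria assay in a sealed, stirred chamber. Respiratory
substrates (malate + pyruvate) start State 2; a bolus of ADP (0.5 mM final)
starts State 3 (phosphorylating) respiration; when the ADP is exhausted the
rate relaxes to State 4 (proton leak); FCCP finally uncouples the membrane
and yields the maximal electron-transport rate. Each state's O2 consumption
rate is the negative OLS slope of the concentration trace over that segment,
normalised to mitochondrial protein:

    rate = (-slope [nmol O2 ml⁻¹ min⁻¹]) / protein [mg ml⁻¹]
         (nmol O2 min⁻¹ mg⁻¹)

The State 3 → State 4 transition ("stabilisation" of the rate) is located
by exhaustive continuous two-segment least squares over every candidate
breakpoint at sample resolution, constrained to a slope-magnitude decrease.
The P:O ratio (ATP per oxygen *atom*) is the ADP added divided by twice the
O2 consumed between ADP addition and State 4 onset, both in nmol:

    P:O = ADP_nmol / (2 * O2_consumed_nmol)

using fitted segment values (not raw samples) at the boundary times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidTraceError,
    NoState4Error,
)

EVENT_ORDER = ("substrates_added", "adp_added", "fccp_added")

#: Minimum points on each side of a candidate State 4 breakpoint.
MIN_SEGMENT_POINTS = 10


@dataclass
class MitoTrace:
    """Event-annotated O2 trace from one oxygraph run."""

    time_min: np.ndarray
    o2_nmol_per_ml: np.ndarray
    events: dict[str, float]  # event name -> time_min
    chamber_volume_ml: float
    protein_mg_per_ml: float
    adp_mM: float = 0.5
    sample_id: str = ""
    test_temp_c: float = float("nan")
    ground_truth: dict[str, Any] | None = None  # populated by the simulator

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.o2_nmol_per_ml = np.asarray(self.o2_nmol_per_ml, dtype=float)
        if self.time_min.shape != self.o2_nmol_per_ml.shape:
            raise InvalidInputError("time and O2 arrays differ in length")
        if np.any(np.diff(self.time_min) <= 0):
            raise InvalidInputError("time stamps must be strictly increasing")
        missing = [e for e in EVENT_ORDER if e not in self.events]
        if missing:
            raise InvalidInputError(f"missing events: {missing}")
        ts = [self.events[e] for e in EVENT_ORDER]
        if not (ts[0] < ts[1] < ts[2]):
            raise InvalidInputError(
                f"events must be strictly ordered {EVENT_ORDER}, got times {ts}"
            )
        if self.chamber_volume_ml <= 0:
            raise InvalidInputError("chamber volume must be positive")
        if self.protein_mg_per_ml <= 0:
            raise InvalidInputError("protein concentration must be positive")
        if self.adp_mM <= 0:
            raise InvalidInputError("ADP concentration must be positive")


@dataclass
class State4Fit:
    """Continuous two-segment fit of the post-ADP, pre-FCCP window."""

    onset_min: float
    slope_state3: float  # nmol ml⁻¹ min⁻¹, segment before the breakpoint
    slope_state4: float  # nmol ml⁻¹ min⁻¹, segment after
    intercept: float  # fitted O2 at the ADP-addition time
    rss: float

    def o2_at(self, t: float) -> float:
        """Fitted O2 concentration at time ``t`` (within the fit window)."""
        dt = t - self._t0
        y = self.intercept + self.slope_state3 * min(dt, self._knot_dt)
        if dt > self._knot_dt:
            y += self.slope_state4 * (dt - self._knot_dt)
        return y

    _t0: float = 0.0
    _knot_dt: float = 0.0


@dataclass
class MitoRates:
    """Protein-normalised state rates plus derived coupling quantities."""

    sample_id: str
    test_temp_c: float
    state2: float
    state3: float
    state4: float
    fccp: float  # maximal uncoupled rate
    state4_onset_min: float
    po_ratio: float
    rcr: float
    qc_flags: list[str] = field(default_factory=list)


def _segment_slice(trace: MitoTrace, t_lo: float, t_hi: float) -> slice:
    i = int(np.searchsorted(trace.time_min, t_lo - 1e-12, side="left"))
    j = int(np.searchsorted(trace.time_min, t_hi + 1e-12, side="right"))
    return slice(i, j)


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    if t.size < 3:
        raise InsufficientDataError(f"segment has only {t.size} samples")
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def detect_state4_onset(
    trace: MitoTrace, min_segment_points: int = MIN_SEGMENT_POINTS
) -> State4Fit:
    """Locate the State 3 → State 4 transition by breakpoint regression.

    Fits a continuous two-segment line to the window between ADP and FCCP
    additions for every candidate knot at sample resolution (an exhaustive
    search) and keeps the residual-sum-of-squares minimiser among candidates
    where the rate slows (|slope after| < |slope before|). Raises
    :class:`NoState4Error` when no candidate shows a slope decrease, i.e.
    the ADP was never exhausted.
    """
    sl = _segment_slice(trace, trace.events["adp_added"], trace.events["fccp_added"])
    t = trace.time_min[sl]
    y = trace.o2_nmol_per_ml[sl]
    n = t.size
    if n < 2 * min_segment_points:
        raise InsufficientDataError(
            f"post-ADP window has {n} samples; need >= {2 * min_segment_points}"
        )
    t0 = t[0]
    tc = t - t0

    # Candidate knots at samples [m, n-m); all 3x3 normal equations are
    # assembled from suffix cumulative sums, so the sweep is O(n).
    lo, hi = min_segment_points, n - min_segment_points
    ks = np.arange(lo, hi)
    tk = tc[ks]

    def suffix(v):
        c = np.cumsum(v[::-1])[::-1]
        return c[ks]

    ones = np.ones_like(tc)
    S1 = suffix(ones)
    St = suffix(tc)
    St2 = suffix(tc * tc)
    Sy = suffix(y)
    Sty = suffix(tc * y)

    n_tot = float(n)
    T = tc.sum()
    T2 = (tc * tc).sum()
    Y = y.sum()
    TY = (tc * y).sum()
    YY = float(y @ y)

    # hinge h = (t - tk)+ evaluated only at samples strictly after the knot;
    # the sample at the knot contributes 0 so using i > k suffices.
    Sh = St - tk * S1
    Sth = St2 - tk * St
    Shh = St2 - 2 * tk * St + tk * tk * S1
    Shy = Sty - tk * Sy

    m = ks.size
    G = np.empty((m, 3, 3))
    G[:, 0, 0] = n_tot
    G[:, 0, 1] = G[:, 1, 0] = T
    G[:, 1, 1] = T2
    G[:, 0, 2] = G[:, 2, 0] = Sh
    G[:, 1, 2] = G[:, 2, 1] = Sth
    G[:, 2, 2] = Shh
    b = np.empty((m, 3))
    b[:, 0] = Y
    b[:, 1] = TY
    b[:, 2] = Shy

    beta = np.linalg.solve(G, b[..., None])[..., 0]
    rss = YY - np.einsum("ij,ij->i", beta, b)

    s1 = beta[:, 1]
    s2 = beta[:, 1] + beta[:, 2]
    valid = np.abs(s2) < np.abs(s1) - 1e-12 * np.abs(s1)
    if not np.any(valid):
        raise NoState4Error(
            f"sample {trace.sample_id!r}: no breakpoint with a slope-magnitude "
            "decrease in the post-ADP window (ADP never exhausted?)"
        )
    rss_masked = np.where(valid, rss, np.inf)
    best = int(np.argmin(rss_masked))
    fit = State4Fit(
        onset_min=float(t0 + tk[best]),
        slope_state3=float(s1[best]),
        slope_state4=float(s2[best]),
        intercept=float(beta[best, 0]),
        rss=float(rss[best]),
    )
    fit._t0 = float(t0)
    fit._knot_dt = float(tk[best])
    return fit


def compute_po_ratio(trace: MitoTrace, fit: State4Fit) -> float:
    """ADP phosphorylated per oxygen atom consumed during State 3.

    ADP (nmol) = adp_mM * volume_ml * 1000; O2 consumed (nmol of O2
    molecules) is the fitted concentration drop between ADP addition and
    State 4 onset times the chamber volume. Oxygen atoms = 2 * O2.
    """
    adp_nmol = trace.adp_mM * trace.chamber_volume_ml * 1000.0
    drop = fit.o2_at(trace.events["adp_added"]) - fit.o2_at(fit.onset_min)
    o2_nmol = drop * trace.chamber_volume_ml
    if o2_nmol <= 0:
        raise InvalidTraceError(
            f"sample {trace.sample_id!r}: non-positive O2 consumption "
            f"({o2_nmol:.4g} nmol) during State 3"
        )
    return adp_nmol / (2.0 * o2_nmol)


def compute_state_rates(
    trace: MitoTrace,
    fit: State4Fit | None = None,
    min_segment_points: int = MIN_SEGMENT_POINTS,
) -> MitoRates:
    """Protein-normalised rates for States 2/3/4 and the FCCP-uncoupled state.

    Segments: substrates→ADP (State 2), ADP→onset (State 3), onset→FCCP
    (State 4), FCCP→end (uncoupled). Also returns RCR = State3/State4 and
    the P:O ratio. QC flags record rising segments and an FCCP rate below
    State 3, which indicates compromised membrane integrity.
    """
    if fit is None:
        fit = detect_state4_onset(trace, min_segment_points)
    ev = trace.events
    bounds = {
        "state2": (ev["substrates_added"], ev["adp_added"]),
        "state3": (ev["adp_added"], fit.onset_min),
        "state4": (fit.onset_min, ev["fccp_added"]),
        "fccp": (ev["fccp_added"], trace.time_min[-1]),
    }
    flags: list[str] = []
    rates: dict[str, float] = {}
    for name, (lo, hi) in bounds.items():
        if name == "state3":
            slope = fit.slope_state3
        elif name == "state4":
            slope = fit.slope_state4
        else:
            sl = _segment_slice(trace, lo, hi)
            slope = _ols_slope(trace.time_min[sl], trace.o2_nmol_per_ml[sl])
        if slope > 0:
            flags.append(f"rising_segment:{name}")
        rates[name] = -slope / trace.protein_mg_per_ml

    if rates["fccp"] < rates["state3"]:
        flags.append("membrane_integrity")
    rcr = rates["state3"] / rates["state4"] if rates["state4"] > 0 else float("nan")
    if not np.isfinite(rcr):
        flags.append("undefined_rcr")
    po = compute_po_ratio(trace, fit)
    return MitoRates(
        sample_id=trace.sample_id,
        test_temp_c=trace.test_temp_c,
        state2=rates["state2"],
        state3=rates["state3"],
        state4=rates["state4"],
        fccp=rates["fccp"],
        state4_onset_min=fit.onset_min,
        po_ratio=po,
        rcr=rcr,
        qc_flags=flags,
    )


def analyze_mito_trace(
    trace: MitoTrace, min_segment_points: int = MIN_SEGMENT_POINTS
) -> MitoRates:
    """Full per-trace analysis: breakpoint, state rates, RCR and P:O."""
    fit = detect_state4_onset(trace, min_segment_points)
    return compute_state_rates(trace, fit, min_segment_points)
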