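"""Trace-level simulators: respirometry, oxygraph and swim trials.

Each simulator is the forward model of its analysis counterpart, so
simulate -> analyse round-trips recover the ground truth exactly in
noiseless mode and within sampling error under noise. Geometry defaults
mirror the study's instruments: a 27 ml resting respirometry chamber, a
130 ml maximal-rate chamber, a 0.5 mM ADP bolus in the oxygraph, and a
0.06 m/s + 0.02 m/s-per-5-min swim protocol.
"""

from __future__ import annotations

import numpy as np

from ..errors import (
    DegenerateTraceError,
    DegenerateTrialError,
    InvalidSpecificationError,
)
from ..mito import MitoTrace
from ..respirometry import MIN_SAMPLES, RespirometryTrace
from ..swim import SwimProtocol, SwimTrialRecord

#: Air-saturated freshwater at ~20 degC, μmol O2 / L.
DEFAULT_START_O2_UMOL_L = 280.0

#: Oxygen-enriched oxygraph medium, nmol O2 / ml.
DEFAULT_START_O2_NMOL_ML = 400.0


def simulate_respirometry_trace(
    true_mo2: float,
    mass_g: float,
    volume_l: float = 0.027,
    duration_min: float = 30.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    dt_min: float = 1.0 / 12.0,
    start_o2_umol_l: float = DEFAULT_START_O2_UMOL_L,
    fish_id: str = "F0000",
    phase: str = "rest",
    test_temp_c: float = 18.0,
) -> RespirometryTrace:
    """Sealed-chamber O2 depletion with linear true slope.

    True slope = −true_mo2 * mass / volume (μmol L⁻¹ min⁻¹); Gaussian
    sensor noise is added on top. If the true concentration would reach
    zero before ``duration_min`` the recording is truncated there; a
    truncation leaving fewer than the minimum sample count raises
    :class:`DegenerateTraceError` (near-immediate anoxia).
    """
    if true_mo2 < 0 or mass_g <= 0 or volume_l <= 0 or duration_min <= 0:
        raise InvalidSpecificationError("magnitudes must be positive (MO2 >= 0)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slope = -true_mo2 * mass_g / volume_l
    if slope < 0:
        t_anoxia = start_o2_umol_l / (-slope)
        duration_min = min(duration_min, t_anoxia)
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    t = t[start_o2_umol_l + slope * t >= 0.0]
    if t.size < MIN_SAMPLES:
        raise DegenerateTraceError(
            f"MO2 {true_mo2} with start O2 {start_o2_umol_l} μmol/L exhausts the "
            f"chamber within {t.size} samples (immediate anoxia)"
        )
    y = start_o2_umol_l + slope * t
    if noise_sd > 0:
        y = np.maximum(y + rng.normal(0.0, noise_sd, size=t.size), 0.0)
    return RespirometryTrace(
        time_min=t,
        o2_umol_per_l=y,
        chamber_volume_l=volume_l,
        fish_mass_g=mass_g,
        test_temp_c=test_temp_c,
        phase=phase,
        fish_id=fish_id,
    )


def simulate_swim_trial(
    true_ucrit_ms: float,
    protocol: SwimProtocol | None = None,
    body_length_m: float = 0.025,
    jitter_sd_min: float = 0.0,
    seed: int | np.random.Generator = 0,
    fish_id: str = "F0000",
    test_temp_c: float = 18.0,
    allow_initial_failure: bool = False,
) -> SwimTrialRecord:
    """Swim-trial record whose Brett interpolation returns ``true_ucrit_ms``.

    Inverts the Brett formula: the last fully completed speed is the
    largest protocol step not exceeding the true Ucrit, and the time at the
    failure speed is the proportional remainder of the step interval.
    ``jitter_sd_min`` adds truncated Gaussian noise to that time (clipped
    to [0, interval)), emulating timing error. A true Ucrit below the
    initial protocol speed raises :class:`DegenerateTrialError` unless
    ``allow_initial_failure`` is set, in which case the record encodes a
    failure during the habituation step (no step completed, pro-rated
    time), which the Ucrit computation flags for exclusion review.
    """
    p = protocol or SwimProtocol()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if true_ucrit_ms < p.initial_speed_ms:
        if not allow_initial_failure or true_ucrit_ms < 0:
            raise DegenerateTrialError(
                f"true Ucrit {true_ucrit_ms} m/s below initial protocol speed "
                f"{p.initial_speed_ms} m/s"
            )
        t_init = true_ucrit_ms / p.initial_speed_ms * p.initial_duration_min
        return SwimTrialRecord(
            fish_id=fish_id,
            test_temp_c=test_temp_c,
            last_completed_speed_ms=0.0,
            time_at_final_speed_min=min(
                t_init, np.nextafter(p.initial_duration_min, 0.0)
            ),
            standard_length_m=body_length_m,
            protocol=p,
        )
    # tolerant floor so a Ucrit exactly on a step speed yields 0 min at the
    # next speed rather than a full-interval artefact
    k = int(np.floor((true_ucrit_ms - p.initial_speed_ms) / p.increment_ms + 1e-9))
    last_completed = p.initial_speed_ms + k * p.increment_ms
    t_final = (true_ucrit_ms - last_completed) / p.increment_ms * p.interval_min
    t_final = min(max(t_final, 0.0), np.nextafter(p.interval_min, 0.0))
    if jitter_sd_min > 0:
        t_final = float(
            np.clip(
                t_final + rng.normal(0.0, jitter_sd_min),
                0.0,
                np.nextafter(p.interval_min, 0.0),
            )
        )
    return SwimTrialRecord(
        fish_id=fish_id,
        test_temp_c=test_temp_c,
        last_completed_speed_ms=last_completed,
        time_at_final_speed_min=t_final,
        standard_length_m=body_length_m,
        protocol=p,
    )


def simulate_mito_trace(
    state_rates: dict[str, float] | None = None,
    protein_mg_ml: float = 0.1,
    volume_ml: float = 0.25,
    adp_mM: float = 0.5,
    target_po: float | None = None,
    state3_duration_min: float | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    dt_min: float = 0.05,
    start_o2_nmol_ml: float = DEFAULT_START_O2_NMOL_ML,
    baseline_min: float = 2.0,
    state2_min: float = 5.0,
    state4_min: float = 10.0,
    fccp_min: float = 5.0,
    sample_id: str = "S0000",
    test_temp_c: float = 18.0,
) -> MitoTrace:
    """Piecewise-linear oxygraph trace with event markers and known truth.

    ``state_rates`` gives the protein-normalised rates (nmol O2 min⁻¹ mg⁻¹)
    for keys state2/state3/state4/fccp; the concentration slope of each
    segment is −rate * protein. The State 3 segment length is set either
    directly (``state3_duration_min``) or from a target P:O ratio, using
    the assay stoichiometry: O2 consumed during State 3 must equal
    ADP_nmol / (2 * P:O). The State 4 onset is snapped to the sampling
    grid; ``trace.ground_truth`` records both the target and the realised
    (post-snapping) P:O along with every segment slope and boundary time.
    """
    rates = dict(state_rates or {"state2": 10.0, "state3": 50.0, "state4": 10.0, "fccp": 60.0})
    for key in ("state2", "state3", "state4", "fccp"):
        if key not in rates:
            raise InvalidSpecificationError(f"state_rates missing {key!r}")
        if rates[key] <= 0:
            raise InvalidSpecificationError(f"rate {key} must be positive")
    if rates["state4"] >= rates["state3"]:
        raise InvalidSpecificationError(
            "state4 rate must be below state3 rate (coupled mitochondria)"
        )
    if adp_mM <= 0 or protein_mg_ml <= 0 or volume_ml <= 0:
        raise InvalidSpecificationError("concentrations and volume must be positive")
    if (target_po is None) == (state3_duration_min is None):
        if target_po is None:
            target_po = 1.5  # sensible default efficiency
        else:
            raise InvalidSpecificationError(
                "give either target_po or state3_duration_min, not both"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    adp_nmol = adp_mM * volume_ml * 1000.0
    o2_consumption_nmol_min = rates["state3"] * protein_mg_ml * volume_ml
    if state3_duration_min is None:
        o2_target_nmol = adp_nmol / (2.0 * target_po)
        state3_duration_min = o2_target_nmol / o2_consumption_nmol_min

    def snap(t: float) -> float:
        return round(t / dt_min) * dt_min

    t_sub = snap(baseline_min)
    t_adp = snap(t_sub + state2_min)
    t_onset = snap(t_adp + state3_duration_min)
    if t_onset <= t_adp:
        raise InvalidSpecificationError("state3 duration shorter than one sample")
    t_fccp = snap(t_onset + state4_min)
    t_end = snap(t_fccp + fccp_min)

    knots = np.array([0.0, t_sub, t_adp, t_onset, t_fccp, t_end])
    seg_slopes = np.array(
        [
            0.0,  # pre-substrate baseline
            -rates["state2"] * protein_mg_ml,
            -rates["state3"] * protein_mg_ml,
            -rates["state4"] * protein_mg_ml,
            -rates["fccp"] * protein_mg_ml,
        ]
    )
    t = np.arange(0.0, t_end + dt_min / 2, dt_min)
    knot_vals = np.concatenate(
        ([start_o2_nmol_ml], start_o2_nmol_ml + np.cumsum(seg_slopes * np.diff(knots)))
    )
    y = np.interp(t, knots, knot_vals)
    if knot_vals.min() <= 0:
        raise DegenerateTraceError(
            f"chamber O2 exhausted (min {knot_vals.min():.1f} nmol/ml); raise "
            "start_o2_nmol_ml or shorten the protocol"
        )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)

    realized_o2_nmol = (
        rates["state3"] * protein_mg_ml * (t_onset - t_adp) * volume_ml
    )
    realized_po = adp_nmol / (2.0 * realized_o2_nmol)
    trace = MitoTrace(
        time_min=t,
        o2_nmol_per_ml=y,
        events={"substrates_added": t_sub, "adp_added": t_adp, "fccp_added": t_fccp},
        chamber_volume_ml=volume_ml,
        protein_mg_per_ml=protein_mg_ml,
        adp_mM=adp_mM,
        sample_id=sample_id,
        test_temp_c=test_temp_c,
    )
    trace.ground_truth = {
        "rates": rates,
        "target_po": target_po,
        "realized_po": realized_po,
        "state4_onset_min": t_onset,
        "segment_slopes": dict(
            zip(("baseline", "state2", "state3", "state4", "fccp"), seg_slopes)
        ),
        "rcr": rates["state3"] / rates["state4"],
    }
    return trace
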