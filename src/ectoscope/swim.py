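"""Critical sustained swimming speed (Ucrit) from stepped-velocity trials.

A fish swims against flow that starts at ``initial_speed`` for an initial
habituation step and then rises by ``increment`` every ``interval`` minutes
until exhaustion. Brett's interpolation credits the partially completed
final step:

    Ucrit = U_last + dU * (t_f / dt)

where U_last is the highest fully sustained speed, dU the increment, t_f the
time survived at the failure speed and dt the step interval. Dividing by
standard length gives the length-specific speed in BL s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError, InvalidRecordError


@dataclass(frozen=True)
class SwimProtocol:
    """Stepped-velocity protocol; defaults follow the flume assay used here
    (0.06 m s⁻¹ for 20 min, then +0.02 m s⁻¹ every 5 min)."""

    initial_speed_ms: float = 0.06
    initial_duration_min: float = 20.0
    increment_ms: float = 0.02
    interval_min: float = 5.0

    def __post_init__(self):
        for name in (
            "initial_speed_ms",
            "initial_duration_min",
            "increment_ms",
            "interval_min",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"protocol field {name} must be positive")


@dataclass
class SwimTrialRecord:
    """Outcome of one stepped-velocity trial for one fish.

    ``last_completed_speed_ms`` is the highest speed fully sustained; 0.0
    encodes failure during the initial habituation step (no step completed),
    in which case ``time_at_final_speed_min`` is time survived at the
    initial speed and must be below ``initial_duration_min``.
    """

    fish_id: str
    test_temp_c: float
    last_completed_speed_ms: float
    time_at_final_speed_min: float
    standard_length_m: float
    protocol: SwimProtocol = field(default_factory=SwimProtocol)

    def __post_init__(self):
        p = self.protocol
        if self.standard_length_m <= 0:
            raise InvalidRecordError("standard length must be positive")
        if self.time_at_final_speed_min < 0:
            raise InvalidRecordError("time at final speed cannot be negative")
        if self.last_completed_speed_ms == 0.0:
            if self.time_at_final_speed_min >= p.initial_duration_min:
                raise InvalidRecordError(
                    "initial step survived in full: record the first increment "
                    "as a completed step instead"
                )
            return
        if self.last_completed_speed_ms < p.initial_speed_ms - 1e-12:
            raise InvalidRecordError(
                f"last completed speed {self.last_completed_speed_ms} below "
                f"initial protocol speed {p.initial_speed_ms}"
            )
        if self.time_at_final_speed_min >= p.interval_min:
            raise InvalidRecordError(
                f"time at final speed ({self.time_at_final_speed_min} min) "
                f">= step interval ({p.interval_min} min): the step was "
                "completed, not failed"
            )


@dataclass
class UcritResult:
    fish_id: str
    test_temp_c: float
    ucrit_ms: float
    ucrit_bl_s: float
    qc_flags: list[str]


def compute_ucrit(record: SwimTrialRecord) -> UcritResult:
    """Brett-interpolated Ucrit in m s⁻¹ and BL s⁻¹.

    Fish that fail during the initial habituation step get the pro-rated
    speed ``initial_speed * t/initial_duration`` and an
    ``initial_step_failure`` flag so they can be reviewed for exclusion.
    """
    p = record.protocol
    flags: list[str] = []
    if record.last_completed_speed_ms == 0.0:
        ucrit = p.initial_speed_ms * (
            record.time_at_final_speed_min / p.initial_duration_min
        )
        flags.append("initial_step_failure")
    else:
        ucrit = record.last_completed_speed_ms + p.increment_ms * (
            record.time_at_final_speed_min / p.interval_min
        )
    return UcritResult(
        fish_id=record.fish_id,
        test_temp_c=record.test_temp_c,
        ucrit_ms=float(ucrit),
        ucrit_bl_s=float(ucrit / record.standard_length_m),
        qc_flags=flags,
    )
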