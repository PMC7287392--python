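"""Exception hierarchy for the ectoscope pipeline.

Every error raised by the analysis modules derives from :class:`EctoscopeError`
so that the CLI and pipeline driver can catch pipeline-level failures while
letting programming errors propagate.
"""


class EctoscopeError(Exception):
    """Base class for all ectoscope errors."""


class InvalidSpecificationError(EctoscopeError):
    """A simulation or model specification violates its preconditions."""


class DegenerateTraceError(EctoscopeError):
    """Simulation parameters produce a physically impossible trace."""


class DegenerateTrialError(EctoscopeError):
    """Swim-trial parameters are inconsistent with the protocol."""


class InsufficientDataError(EctoscopeError):
    """Too few samples to fit the requested quantity."""


class RisingOxygenError(EctoscopeError):
    """Oxygen concentration does not decline: no measurable consumption."""


class InvalidRecordError(EctoscopeError):
    """A trial or measurement record violates its invariants."""


class NoState4Error(EctoscopeError):
    """No slope-decrease breakpoint found after ADP addition."""


class InvalidTraceError(EctoscopeError):
    """An oxygraph trace is inconsistent with the assay stoichiometry."""


class InvalidInputError(EctoscopeError):
    """A required input value is missing or out of range."""


class AliasingError(EctoscopeError):
    """The design cannot estimate the requested term or contrast."""


class MissingPairError(EctoscopeError):
    """A fish x test-temperature pairing required for a join is absent."""


class UndefinedEffectError(EctoscopeError):
    """Effect size is undefined (zero pooled variance or n < 2)."""


class EmptyDomainError(EctoscopeError):
    """No valid (non-nodata) cells in a raster operation."""


class InvalidOptionError(EctoscopeError):
    """An unrecognised option value was supplied."""


class PipelineError(EctoscopeError):
    """A pipeline stage failed; carries the stage name and offending key."""

    def __init__(self, stage: str, key: str, message: str):
        self.stage = stage
        self.key = key
        super().__init__(f"stage '{stage}' failed on '{key}': {message}")
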