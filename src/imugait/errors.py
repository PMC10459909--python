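"""Exception hierarchy for the imugait pipeline.

Every anticipated failure mode raises a subclass of :class:`ImuGaitError`
so callers can distinguish pipeline faults from programming errors.
"""


class ImuGaitError(Exception):
    """Base class for all imugait errors."""


class ValidationError(ImuGaitError):
    """A domain object violates one of its invariants."""


class ParseError(ImuGaitError):
    """A log file could not be parsed; the message names the offending line."""


class SyncError(ImuGaitError):
    """Base class for synchronization failures."""


class NoPulseError(SyncError):
    """No magnetometer sample exceeds the pulse threshold."""


class AmbiguousPulseError(SyncError):
    """Several well-separated super-threshold magnetometer peaks were found."""

    def __init__(self, candidate_times):
        self.candidate_times = list(candidate_times)
        super().__init__(
            f"ambiguous sync pulse: {len(self.candidate_times)} candidate "
            f"peaks at t = {self.candidate_times}"
        )


class InsufficientTapsError(SyncError):
    """Fewer tap peaks than requested were detected."""


class AlignmentError(SyncError):
    """An implied clock offset exceeds the configured sanity bound."""


class GapTooLongError(ImuGaitError):
    """A timestamp gap exceeds the maximum repairable length."""


class DegenerateInputError(ImuGaitError):
    """Input carries no usable information (all-zero, constant, flat...)."""


class ThresholdError(ImuGaitError):
    """An automatic threshold could not be derived from the signal."""


class EventDetectionError(ImuGaitError):
    """Gait-event detection produced no usable result."""


class EmptySelectionError(ImuGaitError):
    """No stride survived straight-walking selection."""


class IntegrationError(ImuGaitError):
    """Displacement integration preconditions are not met."""


class StatisticsError(ImuGaitError):
    """Invalid input to a statistical routine."""
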