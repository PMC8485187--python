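"""Exception types raised by the engine."""


class StepscreenError(Exception):
    """Base class for all engine errors."""


class InstrumentValidationError(StepscreenError, ValueError):
    """An item-level response vector violates the instrument's constraints.

    Carries the offending item index (0-based) when a single item is at
    fault, so callers can point at the bad column in tabular input.
    """

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class ScheduleError(StepscreenError, ValueError):
    """A monitoring operation was asked about a week outside the schedule,
    or a screen-negative patient was put on the follow-up schedule."""


class NonCompleterError(StepscreenError, ValueError):
    """A completer-only classification was requested for a patient with no
    completed follow-up assessment."""


class AnalyticsError(StepscreenError, ValueError):
    """A cohort-level statistic is undefined for the given inputs
    (empty cohort, zero identified cases, zero baseline SD)."""
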