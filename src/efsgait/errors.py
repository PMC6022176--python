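"""Exception hierarchy for efsgait."""


class EfsGaitError(Exception):
    """Base class for all efsgait errors."""


class FormatError(EfsGaitError, ValueError):
    """A file did not conform to the expected CSV dialect."""


class ConfigurationError(EfsGaitError, ValueError):
    """A configuration object is internally inconsistent."""


class MalformedSignalError(EfsGaitError, ValueError):
    """A signal violates the structural assumptions of a detector.

    Carries the sample index at which the violation was observed.
    """

    def __init__(self, message: str, index: int | None = None):
        if index is not None:
            message = f"{message} (sample index {index})"
        super().__init__(message)
        self.index = index


class InsufficientSignalError(EfsGaitError, ValueError):
    """A trace does not contain enough structure to detect events."""


class InconsistentEventsError(EfsGaitError, ValueError):
    """An event sequence implies a non-positive phase duration."""
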