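"""Exception hierarchy shared by every stage of the pipeline."""


class BorealCarbonError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(BorealCarbonError, ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(BorealCarbonError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class MissingDataError(BorealCarbonError):
    """A required measurement is absent; the plot is flagged, never zeroed."""

    def __init__(self, message: str, plot_id=None):
        super().__init__(message)
        self.plot_id = plot_id


class SchemaError(BorealCarbonError, ValueError):
    """A delimited table does not match its declared column schema."""
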