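"""Exception hierarchy."""


class ScrltiError(Exception):
    """Base class for package errors."""


class InvalidParameterError(ScrltiError, ValueError):
    """A parameter is outside its admissible range (e.g. cutoff >= Nyquist)."""


class InvalidInputError(ScrltiError, ValueError):
    """Input data violate an operation's preconditions (e.g. empty series)."""


class DegenerateInputError(ScrltiError, ValueError):
    """Input is formally valid but degenerate (e.g. zero variance)."""


class DataError(ScrltiError, ValueError):
    """A data file or channel is missing or malformed."""


class FitError(ScrltiError, RuntimeError):
    """All optimization starts failed."""
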