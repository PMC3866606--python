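"""Exception hierarchy for the package."""


class SprotannError(Exception):
    """Base class for package errors."""


class ContractError(SprotannError):
    """An operation was called with arguments violating its contract."""


class ParseError(SprotannError):
    """Malformed input file content."""


class ValidationError(SprotannError):
    """An object violates a domain-type invariant."""


class GenerationError(SprotannError):
    """A synthetic-data generator exhausted its retry budget."""


class CalibrationError(SprotannError):
    """Insufficient or degenerate data for a statistical calibration."""
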