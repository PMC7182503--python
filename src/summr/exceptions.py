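"""Exception taxonomy shared across the package."""


class SummrError(Exception):
    """Base class for all package errors."""


class ConfigError(SummrError, ValueError):
    """A configuration (column map, analysis settings) is invalid."""


class InputError(SummrError, ValueError):
    """An input table, matrix, or argument violates a precondition."""


class InsufficientInstrumentsError(InputError):
    """Too few usable instruments for the requested operation."""
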