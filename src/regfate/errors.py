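"""Exception hierarchy shared across the pipeline."""


class RegfateError(Exception):
    """Base class for all package errors."""


class ParameterError(RegfateError, ValueError):
    """An invalid parameter or design field; the message names the field."""


class ValidationError(RegfateError, ValueError):
    """Inconsistent or degenerate input data."""


class InputError(RegfateError, ValueError):
    """Missing or malformed input (files, tables, gene sets)."""
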