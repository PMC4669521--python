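"""Exception hierarchy used across the package."""


class EpiclockError(Exception):
    """Base class for all package errors."""


class ValidationError(EpiclockError, ValueError):
    """An input object violates a documented invariant."""


class ParseError(EpiclockError, ValueError):
    """A file could not be parsed; message carries the 1-based line number."""


class SchemaError(EpiclockError, ValueError):
    """A tabular file is missing required columns."""


class ConvergenceError(EpiclockError, RuntimeError):
    """An iterative solver failed to reach its tolerance within its budget."""
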