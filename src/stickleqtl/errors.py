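"""Exception types shared across the package."""


class StickleQtlError(Exception):
    """Base class for package errors."""


class ConfigurationError(StickleQtlError):
    """Invalid simulation or run parameters."""


class GenerationError(StickleQtlError):
    """A synthetic-data generator could not honour its constraints."""


class SchemaError(StickleQtlError):
    """A malformed input file; message names file, line and rule."""


class DegenerateInputError(StickleQtlError):
    """Input too degenerate for the requested statistic (e.g. one class)."""
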