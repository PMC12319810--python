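"""Exception types shared across the package."""


class NeuroageError(Exception):
    """Base class for all package-specific errors."""


class DomainError(NeuroageError, ValueError):
    """An input lies outside the supported domain (e.g. age out of range)."""


class ShapeError(NeuroageError, ValueError):
    """Array shapes are inconsistent with each other or with a contract."""


class DegenerateInputError(NeuroageError, ValueError):
    """Input is formally valid but statistically degenerate (constant data,
    zero variance, all-background volume)."""


class MissingDataError(NeuroageError, ValueError):
    """A required clinical component is missing; the caller must decide how
    to handle it rather than having it silently skipped."""


class ConfigError(NeuroageError, ValueError):
    """A configuration object violates its invariants."""
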