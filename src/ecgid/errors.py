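"""Typed errors shared across the package."""


class EcgidError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EcgidError, ValueError):
    """Input data violates a precondition (empty, non-finite, out of range)."""


class InvalidParameterError(EcgidError, ValueError):
    """A configuration parameter is out of its valid range."""


class DegenerateDistributionError(InvalidInputError):
    """Quantile breakpoints coincide (near-constant difference series)."""


class StateError(EcgidError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class ManifestError(EcgidError, ValueError):
    """A cohort manifest is missing required recordings or is inconsistent."""


class ParseError(EcgidError, ValueError):
    """A file on disk does not conform to the expected format."""
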