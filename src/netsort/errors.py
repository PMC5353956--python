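"""Exception hierarchy shared across the package."""


class NetsortError(Exception):
    """Base class for all package errors."""


class FormatError(NetsortError, ValueError):
    """A file or table does not conform to the expected layout."""


class ValidationError(NetsortError, ValueError):
    """Input violates a semantic constraint (roles, bounds, duplicates)."""


class RandomizationError(NetsortError, RuntimeError):
    """A randomization scheme could not satisfy its constraints."""


class FitError(NetsortError, RuntimeError):
    """A statistical fit failed or is undefined for the given input."""
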