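"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 2, data/validation and
format errors -> 3, numerical failures -> 4.
"""


class CCSSPError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CCSSPError, ValueError):
    """A domain object violates one of its invariants.

    The message always names the offending field.
    """


class FormatError(CCSSPError, ValueError):
    """A file does not match the documented container schema."""


class ParameterError(CCSSPError, ValueError):
    """A user-supplied parameter is outside its documented range."""


class NumericalError(CCSSPError, RuntimeError):
    """A numerical computation failed (e.g. singular eigenproblem)."""
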