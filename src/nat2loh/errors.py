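"""Exception hierarchy shared across the package."""


class Nat2Error(Exception):
    """Base class for all package errors."""


class ParseError(Nat2Error):
    """A malformed input file (the message names the offending line/column)."""


class DefinitionError(Nat2Error):
    """An invalid or inconsistent site/allele definition table."""


class AmbiguousBaseError(Nat2Error):
    """An observed base that is neither the reference nor the catalogued alternate."""


class UnknownAlleleError(Nat2Error, KeyError):
    """A star-allele name not present in the allele table."""


class ValidationError(Nat2Error, ValueError):
    """An out-of-range parameter or inconsistent configuration."""
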