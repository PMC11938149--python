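"""Exception hierarchy shared across the package."""


class NmrscoreError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NmrscoreError):
    """A file could not be parsed under the named standard."""


class SelectionError(NmrscoreError):
    """A selection expression is malformed."""


class SuperpositionError(NmrscoreError):
    """Atom sets cannot be superposed (count mismatch, degenerate geometry)."""


class DataError(NmrscoreError):
    """Input data violates a precondition (bad values, missing columns...)."""
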