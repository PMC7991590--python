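"""Exception hierarchy."""


class MutsenseError(Exception):
    """Base class for all package errors."""


class FormatError(MutsenseError):
    """A file does not follow the expected layout."""


class ValidationError(MutsenseError):
    """Parsed content violates a table invariant."""


class DegenerateDataError(MutsenseError):
    """Input distribution has no spread (constant scores, zero SD, ...)."""


class InsufficientDataError(MutsenseError):
    """Too few residues/records to run an operation."""
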