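"""Exception hierarchy for contract violations.

Every error raised on bad user input derives from :class:`HdnnError`, so
callers (including the CLI) can catch one type and exit with a message.
"""


class HdnnError(Exception):
    """Base class for all package-level contract errors."""


class FormatError(HdnnError):
    """A file is malformed: missing columns, bad model version, truncation."""


class ParseError(FormatError):
    """A cell could not be parsed as a number; names the row and column."""


class LabelError(HdnnError):
    """A label value outside {0, 1} (after any configured mapping)."""


class DomainError(HdnnError):
    """An argument outside its mathematical domain (ratio <= 0, empty class...)."""


class ShapeError(HdnnError):
    """Array dimensions inconsistent with the model or with each other."""


class StratificationError(HdnnError):
    """A class is too small (or absent) for the requested stratified operation."""


class SplitError(HdnnError):
    """An invalid tree split: one side empty or indices not a partition."""


class NumericError(HdnnError):
    """Non-finite values arose during training (divergence, NaN gradients)."""
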