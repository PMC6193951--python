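"""Exception types shared across chexfit."""


class ChexfitError(Exception):
    """Base class for all chexfit errors."""


class InvalidParameterError(ChexfitError, ValueError):
    """A model parameter violates its physical constraints."""


class InvalidInputError(ChexfitError, ValueError):
    """Input data are malformed or insufficient for the requested operation."""


class ParseError(ChexfitError, ValueError):
    """A data file could not be parsed; the message names file, line and column."""


class DegenerateFitError(ChexfitError, RuntimeError):
    """The fit Jacobian is singular; the message names the offending parameter."""


class InsufficientOverlapError(ChexfitError, ValueError):
    """Too few common residues between two chemical-shift sets."""


class InconsistentTitrationError(ChexfitError, ValueError):
    """Titration populations are non-monotone beyond their stated uncertainties."""
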