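"""Exception hierarchy for the consenz pipeline."""


class ConsenzError(Exception):
    """Base class for all consenz errors."""


class InputError(ConsenzError, ValueError):
    """Invalid input value (empty sequence, unknown compound, bad config)."""


class AlignmentFormatError(ConsenzError, ValueError):
    """Alignment file malformed: unequal row lengths, empty alignment, ..."""


class AlphabetError(ConsenzError, ValueError):
    """Illegal character in a sequence; message names the offending position."""


class SymbolError(ConsenzError, KeyError):
    """Consensus-class symbol not present in the symbol map."""


class BoundsError(ConsenzError, IndexError):
    """Index outside the alignment or sequence."""


class DesignInfeasibleError(ConsenzError, ValueError):
    """No synonymous codon choice removes a forbidden motif."""


class PrematureStopError(ConsenzError, ValueError):
    """Internal stop codon encountered during translation."""


class InsufficientDataError(ConsenzError, ValueError):
    """Too few samples in the regression window."""
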