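"""Exception hierarchy.

All input-contract violations derive from ``ValueError`` so callers can catch
either the specific class or the built-in.
"""


class AmpstdError(ValueError):
    """Base class for all ampstd contract violations."""


class AlphabetError(AmpstdError):
    """A character outside the IUPAC nucleotide alphabet was encountered."""


class FastaFormatError(AmpstdError):
    """A FASTA file is empty or structurally malformed."""


class DesignError(AmpstdError):
    """No acceptable primer hit / primer pair exists on the consensus."""


class FitError(AmpstdError):
    """A standard curve cannot be fitted from the supplied dilution data."""


class PlanningError(AmpstdError):
    """A dilution series cannot be realised from the available stock."""


class QuantError(AmpstdError):
    """A sample cannot be quantified (e.g. no finite Cq replicate)."""
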