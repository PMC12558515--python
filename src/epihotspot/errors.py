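"""Exception hierarchy shared across the package."""


class EpihotspotError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(EpihotspotError):
    """Input is not parseable FASTA, or a record violates the residue alphabet."""


class EmptyInputError(EpihotspotError):
    """A reader received a file with no usable content."""


class HgvsParseError(EpihotspotError):
    """A protein-level HGVS label could not be parsed."""


class ReferenceMismatchError(EpihotspotError):
    """A variant's stated reference residue disagrees with the sequence."""


class ValidationError(EpihotspotError):
    """A domain object or argument violates its invariants."""


class DialectError(EpihotspotError):
    """A prediction-engine output file does not match the requested dialect."""


class RowParseError(EpihotspotError):
    """A data row of an engine output file is truncated or malformed."""


class UnsupportedAlleleError(EpihotspotError):
    """A predictor was asked for an allele it has no model for."""


class GenerationError(EpihotspotError):
    """Synthetic-data generation could not satisfy its constraints."""
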