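"""Exception hierarchy for annotation parsing and feature derivation."""


class GeneTablesError(Exception):
    """Base class for all package-specific errors."""


class InvalidIntervalError(GeneTablesError):
    """A genomic interval with start > end or non-positive coordinates."""


class TransSplicingUnsupportedError(GeneTablesError):
    """Transcripts of one gene span multiple chromosomes or strands."""


class ZeroLengthIntronError(GeneTablesError):
    """Two consecutive exons are directly adjacent on the genome."""


class NoCdsError(GeneTablesError):
    """A coding-sequence operation was requested on a non-coding transcript."""


class CdsInconsistencyError(GeneTablesError):
    """The CDS span is not covered by the transcript's exons."""


class FormatError(GeneTablesError):
    """Malformed GFF3/GTF/table input."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TableIntegrityError(GeneTablesError):
    """A feature-table row contradicts itself (stated length != span)."""


class MissingDerivationError(GeneTablesError):
    """Gene_Table export requested before feature derivation was run."""


class UndefinedStatisticError(GeneTablesError):
    """A ratio or percent change with an undefined (zero/negative) base."""


class ParameterConflictError(GeneTablesError):
    """Mutually inconsistent synthetic-generator parameters."""
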