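"""Core domain types for gene models and coordinate arithmetic.

Coordinates are 1-based and inclusive at both ends, the NCBI Gene /
GFF3 convention (GTF shares it).  Intervals are always stored
genomically (``start <= end``) regardless of strand; transcription
order is carried by list position and serial numbers, never by
coordinate order, so minus-strand models stay unambiguous.

Chromosome names are plain text everywhere ("1".."22", "X", "Y",
"MT") — never numeric, so "X"/"Y" cannot be misread as numbers by
downstream spreadsheet tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import (
    InvalidIntervalError,
    TransSplicingUnsupportedError,
)

#: RefSeq curation statuses.  REVIEWED and VALIDATED are human-curated;
#: MODEL/PREDICTED/INFERRED are computational; NA means the record
#: carried no status annotation at all.
REFSEQ_STATUSES = (
    "REVIEWED",
    "VALIDATED",
    "MODEL",
    "PROVISIONAL",
    "INFERRED",
    "PREDICTED",
    "NA",
)

PROTEIN_CODING = "protein-coding"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on a chromosome sequence.

    Parameters
    ----------
    chrom_accession
        Sequence accession the coordinates refer to (text).
    start, end
        1-based, both inclusive; ``start <= end`` always, on either strand.
    strand
        ``"+"`` or ``"-"``.
    """

    chrom_accession: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InvalidIntervalError(
                f"invalid interval {self.chrom_accession}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise InvalidIntervalError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        """Overlap with ``other`` on the same sequence, or None."""
        if self.chrom_accession != other.chrom_accession:
            return None
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        if lo > hi:
            return None
        return GenomicInterval(self.chrom_accession, lo, hi, self.strand)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom_accession == other.chrom_accession
            and self.start <= other.start
            and other.end <= self.end
        )

    def mirror(self, chrom_length: int) -> "GenomicInterval":
        """Reflect the interval through the chromosome midpoint.

        Mirroring maps position p to ``chrom_length - p + 1`` and flips
        the strand; lengths are preserved.  Used by strand-invariance
        checks.
        """
        return GenomicInterval(
            self.chrom_accession,
            chrom_length - self.end + 1,
            chrom_length - self.start + 1,
            "-" if self.strand == "+" else "+",
        )


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (``end - start + 1``)."""
    return iv.length


@dataclass
class TranscriptRecord:
    """One mRNA: exons in transcription (5'->3') order plus an optional CDS.

    ``cds_span`` is the genomic interval from the first to the last
    coding base, stop codon included.  UTR/CDS length splits are derived
    by :func:`genetables.features.split_utrs`, not stored.
    """

    accession: str
    exons: list[GenomicInterval]
    cds_span: Optional[GenomicInterval] = None
    refseq_status: str = "NA"
    protein_accession: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise InvalidIntervalError(f"{self.accession}: transcript with no exons")
        strand = self.exons[0].strand
        chrom = self.exons[0].chrom_accession
        for ex in self.exons:
            if ex.strand != strand or ex.chrom_accession != chrom:
                raise TransSplicingUnsupportedError(
                    f"{self.accession}: exons on multiple chromosomes/strands"
                )
        # transcription order: genomic starts strictly increase on "+",
        # strictly decrease on "-"; exons never overlap
        for a, b in zip(self.exons, self.exons[1:]):
            upstream, downstream = (a, b) if strand == "+" else (b, a)
            if downstream.start <= upstream.end:
                raise InvalidIntervalError(
                    f"{self.accession}: exons overlap or are out of "
                    f"transcription order"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom_accession(self) -> str:
        return self.exons[0].chrom_accession

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_len(self) -> int:
        return sum(ex.length for ex in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom_accession,
            min(ex.start for ex in self.exons),
            max(ex.end for ex in self.exons),
            self.strand,
        )

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None


@dataclass
class GeneRecord:
    """One gene: identity, curation metadata and its transcripts."""

    gene_id: str
    symbol: str
    chromosome: str
    gene_type: str = PROTEIN_CODING
    refseq_status: str = "NA"
    in_current_annotation: bool = True
    live: bool = True
    span: Optional[GenomicInterval] = None
    transcripts: list[TranscriptRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.transcripts:
            union = gene_span_from_transcripts(self.transcripts)
            if self.span is None:
                self.span = union
            elif not self.span.contains(union):
                raise InvalidIntervalError(
                    f"gene {self.gene_id}: declared span does not cover "
                    f"its transcripts"
                )

    @property
    def gene_length(self) -> int:
        if self.span is None:
            raise InvalidIntervalError(f"gene {self.gene_id} has no span")
        return self.span.length

    @property
    def strand(self) -> str:
        if self.transcripts:
            return self.transcripts[0].strand
        assert self.span is not None
        return self.span.strand

    @property
    def chrom_accession(self) -> str:
        if self.transcripts:
            return self.transcripts[0].chrom_accession
        assert self.span is not None
        return self.span.chrom_accession


def gene_span_from_transcripts(
    transcripts: Sequence[TranscriptRecord],
) -> GenomicInterval:
    """Union span (min start to max end) over all exons of all transcripts.

    All transcripts must sit on one chromosome accession and strand;
    a mixed set raises :class:`TransSplicingUnsupportedError` rather
    than being silently split.
    """
    if not transcripts:
        raise InvalidIntervalError("gene span of an empty transcript list")
    chrom = transcripts[0].chrom_accession
    strand = transcripts[0].strand
    for t in transcripts:
        if t.chrom_accession != chrom or t.strand != strand:
            raise TransSplicingUnsupportedError(
                "transcripts span multiple chromosomes or strands"
            )
    return GenomicInterval(
        chrom,
        min(ex.start for t in transcripts for ex in t.exons),
        max(ex.end for t in transcripts for ex in t.exons),
        strand,
    )


@dataclass
class SummaryStats:
    """n, median, mean, SD, min, max and total of one length/count batch.

    ``sd`` is the sample standard deviation (n-1 denominator) and is
    None when n == 1; an empty batch is represented by ``n == 0`` with
    every other field None (an "empty-stats" marker, never zeros).
    ``min_labels``/``max_labels`` identify the extreme features (all
    ties, sorted), e.g. ``["GSTP1 E1"]``.
    """

    n: int
    median: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    total: Optional[float] = None
    min_labels: list[str] = field(default_factory=list)
    max_labels: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return self.n == 0


@dataclass
class FeatureRow:
    """One exon of one transcript — one row of the per-feature table.

    The companion intron (the intron immediately downstream of this
    exon in transcription order) lives on the same row; last-exon rows
    therefore carry no intron fields.  Coding fields hold the exon's
    intersection with the CDS span when non-empty.  Absent optional
    fields are None and are exported as empty cells, never as 0.
    """

    gene_id: str
    symbol: str
    gene_type: str
    chromosome: str
    chrom_accession: str
    strand: str
    gene_start: int
    gene_end: int
    gene_length: int
    transcript_accession: str
    transcript_refseq_status: str
    transcript_len: int
    cds_start: Optional[int]
    cds_end: Optional[int]
    utr5_len: Optional[int]
    cds_len: Optional[int]
    utr3_len: Optional[int]
    exon_start: int
    exon_end: int
    exon_len: int
    exon_serial: int
    coding_start: Optional[int] = None
    coding_end: Optional[int] = None
    coding_len: Optional[int] = None
    coding_serial: Optional[int] = None
    intron_start: Optional[int] = None
    intron_end: Optional[int] = None
    intron_len: Optional[int] = None
    intron_serial: Optional[int] = None
    last_exon: bool = False
    last_coding_exon: bool = False
    nr_exon: str = ""
    nr_coding: str = ""
    nr_intron: str = ""
    protein_accession: str = ""
    live: bool = True
    in_current_annotation: bool = True
    gene_refseq_status: str = "NA"


def iter_transcripts(genes: Iterable[GeneRecord]):
    """Yield (gene, transcript) pairs in stable gene/transcript order."""
    for g in genes:
        for t in g.transcripts:
            yield g, t
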