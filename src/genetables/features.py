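"""Derivation of introns, coding-exon portions, UTR/CDS splits,
serial numbers, last-exon flags and non-redundancy labels.

Every operation takes transcription order from the exon list, so the
same code handles both strands: "upstream"/"downstream" always mean
5'->3' along the mRNA, while stored coordinates stay genomic.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import (
    CdsInconsistencyError,
    NoCdsError,
    ZeroLengthIntronError,
)
from .model import FeatureRow, GeneRecord, GenomicInterval, TranscriptRecord

#: Label given to the representative of a duplicated feature group.
YES_MERGED = "Yes—Merged"
#: Label given to a feature that occurs in exactly one isoform.
YES_UNIQUE = "Yes—Unique"

#: Introns of 1-3 bp arise from upstream annotation artifacts in the
#: source gene tables; they are flagged, never silently dropped.
ARTIFACT_INTRON_MAX_BP = 3


def derive_introns(t: TranscriptRecord) -> list[GenomicInterval]:
    """Introns of a transcript, in transcription order (serial = index + 1).

    A transcript with n exons has exactly n - 1 introns; intron i fills
    the genomic gap between exon i and exon i + 1.  Mono-exonic
    transcripts yield an empty list.  Adjacent exons with no gap are an
    annotation defect and raise :class:`ZeroLengthIntronError`.
    """
    introns: list[GenomicInterval] = []
    for a, b in zip(t.exons, t.exons[1:]):
        left, right = (a, b) if t.strand == "+" else (b, a)
        if right.start - left.end < 2:
            raise ZeroLengthIntronError(
                f"{t.accession}: adjacent exons "
                f"{left.start}-{left.end} / {right.start}-{right.end}"
            )
        introns.append(
            GenomicInterval(t.chrom_accession, left.end + 1, right.start - 1, t.strand)
        )
    return introns


def derive_coding_exons(
    t: TranscriptRecord,
) -> list[tuple[int, GenomicInterval, int]]:
    """Coding portion of each exon: (exon index, interval, coding serial).

    The coding portion is the exon's intersection with the CDS span
    (stop codon included); exons wholly inside a UTR contribute nothing
    but keep their exon serial.  Coding serials count coding exons in
    transcription order starting at 1.
    """
    if t.cds_span is None:
        raise NoCdsError(f"{t.accession} has no CDS span")
    out = []
    serial = 0
    for i, ex in enumerate(t.exons):
        part = ex.intersection(t.cds_span)
        if part is not None:
            serial += 1
            out.append((i, part, serial))
    if sum(p.length for _, p, _ in out) != _covered_cds_length(t):
        raise CdsInconsistencyError(f"{t.accession}: CDS not covered by exons")
    return out


def _covered_cds_length(t: TranscriptRecord) -> int:
    assert t.cds_span is not None
    if not (
        any(ex.start <= t.cds_span.start <= ex.end for ex in t.exons)
        and any(ex.start <= t.cds_span.end <= ex.end for ex in t.exons)
    ):
        raise CdsInconsistencyError(
            f"{t.accession}: CDS span extends past the exon union"
        )
    return t.cds_span.length - sum(
        iv.length
        for iv in (
            GenomicInterval(t.chrom_accession, a, b)
            for a, b in _gaps(t)
            if t.cds_span.start <= a and b <= t.cds_span.end
        )
    )


def _gaps(t: TranscriptRecord):
    exs = sorted(t.exons, key=lambda e: e.start)
    for a, b in zip(exs, exs[1:]):
        if b.start - a.end >= 2:
            yield a.end + 1, b.start - 1


def split_utrs(t: TranscriptRecord) -> tuple[int, int, int]:
    """Partition the mRNA into (utr5_len, cds_len, utr3_len) in bp.

    The split is strand-aware: on the minus strand the 5' UTR lies at
    genomically higher coordinates.  The three parts always sum to the
    transcript length.
    """
    if t.cds_span is None:
        raise NoCdsError(f"{t.accession} has no CDS span")
    cds = t.cds_span
    utr5 = cds_len = utr3 = 0
    for ex in t.exons:
        inside = ex.intersection(cds)
        cds_len += inside.length if inside else 0
        before = max(0, min(ex.end, cds.start - 1) - ex.start + 1)
        after = max(0, ex.end - max(ex.start, cds.end + 1) + 1)
        if t.strand == "+":
            utr5 += before
            utr3 += after
        else:
            utr5 += after
            utr3 += before
    if cds_len != _covered_cds_length(t):
        raise CdsInconsistencyError(f"{t.accession}: CDS not covered by exons")
    return utr5, cds_len, utr3


def flag_last_exons(t: TranscriptRecord) -> list[bool]:
    """Per-exon flags marking the 3'-most exon in transcription order."""
    return [i == t.n_exons - 1 for i in range(t.n_exons)]


def build_feature_rows(gene: GeneRecord) -> list[FeatureRow]:
    """Expand a gene into one row per (transcript, exon).

    Rows carry the exon, its coding portion if any, and its companion
    intron (the gap to the next exon in transcription order); the last
    exon of each transcript has no companion intron.  Non-redundancy
    labels are left blank here — they are a whole-set property assigned
    by :func:`mark_non_redundant`.
    """
    rows: list[FeatureRow] = []
    assert gene.span is not None
    for t in gene.transcripts:
        introns = derive_introns(t)
        if t.cds_span is not None:
            coding = {i: (iv, ser) for i, iv, ser in derive_coding_exons(t)}
            utr5, cds_len, utr3 = split_utrs(t)
            cds_start, cds_end = t.cds_span.start, t.cds_span.end
            last_coding_idx = max(coding) if coding else None
        else:
            coding = {}
            utr5 = cds_len = utr3 = None
            cds_start = cds_end = None
            last_coding_idx = None
        for i, ex in enumerate(t.exons):
            row = FeatureRow(
                gene_id=gene.gene_id,
                symbol=gene.symbol,
                gene_type=gene.gene_type,
                chromosome=gene.chromosome,
                chrom_accession=gene.chrom_accession,
                strand=t.strand,
                gene_start=gene.span.start,
                gene_end=gene.span.end,
                gene_length=gene.gene_length,
                transcript_accession=t.accession,
                transcript_refseq_status=t.refseq_status,
                transcript_len=t.transcript_len,
                cds_start=cds_start,
                cds_end=cds_end,
                utr5_len=utr5,
                cds_len=cds_len,
                utr3_len=utr3,
                exon_start=ex.start,
                exon_end=ex.end,
                exon_len=ex.length,
                exon_serial=i + 1,
                last_exon=(i == t.n_exons - 1),
                last_coding_exon=(i == last_coding_idx),
                protein_accession=t.protein_accession,
                live=gene.live,
                in_current_annotation=gene.in_current_annotation,
                gene_refseq_status=gene.refseq_status,
            )
            if i in coding:
                iv, ser = coding[i]
                row.coding_start, row.coding_end = iv.start, iv.end
                row.coding_len, row.coding_serial = iv.length, ser
            if i < len(introns):
                intr = introns[i]
                row.intron_start, row.intron_end = intr.start, intr.end
                row.intron_len, row.intron_serial = intr.length, i + 1
            rows.append(row)
    return rows


FEATURE_CLASSES = ("exon", "coding", "intron")

_CLASS_FIELDS = {
    "exon": ("exon_start", "exon_end", "exon_serial", "nr_exon"),
    "coding": ("coding_start", "coding_end", "coding_serial", "nr_coding"),
    "intron": ("intron_start", "intron_end", "intron_serial", "nr_intron"),
}


def mark_non_redundant(rows: Sequence[FeatureRow], feature_class: str) -> None:
    """Assign non-redundancy labels for one feature class, in place.

    Features are identical iff they share (chromosome accession,
    strand, start, end) exactly; partially overlapping features are
    distinct elements.  Each identity group gets exactly one labelled
    representative — "Yes—Unique" for singleton groups, "Yes—Merged"
    for duplicated ones — chosen as the first row under the
    deterministic sort (gene_id, transcript accession, serial); the
    other group members stay blank.  Filtering on a non-blank label
    therefore yields the non-redundant feature set.
    """
    if feature_class not in _CLASS_FIELDS:
        raise ValueError(f"unknown feature class {feature_class!r}")
    f_start, f_end, f_serial, f_label = _CLASS_FIELDS[feature_class]
    groups: dict[tuple, list[FeatureRow]] = defaultdict(list)
    for row in rows:
        start = getattr(row, f_start)
        if start is None:
            continue
        key = (row.chrom_accession, row.strand, start, getattr(row, f_end))
        groups[key].append(row)
    for members in groups.values():
        members.sort(
            key=lambda r: (r.gene_id, r.transcript_accession, getattr(r, f_serial))
        )
        for m in members:
            setattr(m, f_label, "")
        setattr(members[0], f_label, YES_UNIQUE if len(members) == 1 else YES_MERGED)


def mark_all_non_redundant(rows: Sequence[FeatureRow]) -> None:
    for cls in FEATURE_CLASSES:
        mark_non_redundant(rows, cls)


@dataclass
class ShortIntronHit:
    """One non-redundant intron below the short-intron threshold."""

    symbol: str
    transcript_accession: str
    intron_serial: int
    chrom_accession: str
    start: int
    end: int
    length: int
    #: 1-3 bp introns are almost certainly annotation artifacts of the
    #: upstream gene tables; longer sub-threshold introns are candidate
    #: non-canonical excisions (e.g. the 26-bp IRE1-mediated segment).
    classification: str = "non-canonical-excision-candidate"


@dataclass
class ShortIntronReport:
    threshold: int
    hits: list[ShortIntronHit] = field(default_factory=list)


def flag_short_introns(
    rows: Iterable[FeatureRow], threshold: int = 30
) -> ShortIntronReport:
    """List non-redundant introns shorter than ``threshold`` bp.

    Splice sites cannot accommodate introns below ~30 bp, so anything
    shorter is either an annotation artifact or a segment removed by a
    non-spliceosomal mechanism.  The report is for manual review; no
    row is removed.  Introns of exactly ``threshold`` bp are not
    flagged.
    """
    report = ShortIntronReport(threshold=threshold)
    for row in rows:
        if row.intron_len is None or not row.nr_intron:
            continue
        if row.intron_len < threshold:
            report.hits.append(
                ShortIntronHit(
                    symbol=row.symbol,
                    transcript_accession=row.transcript_accession,
                    intron_serial=row.intron_serial,
                    chrom_accession=row.chrom_accession,
                    start=row.intron_start,
                    end=row.intron_end,
                    length=row.intron_len,
                    classification=(
                        "annotation-artifact"
                        if row.intron_len <= ARTIFACT_INTRON_MAX_BP
                        else "non-canonical-excision-candidate"
                    ),
                )
            )
    report.hits.sort(key=lambda h: (h.symbol, h.intron_serial))
    return report


def derive_all(genes: Iterable[GeneRecord]) -> list[FeatureRow]:
    """Feature rows for a whole gene set, with non-redundancy labels."""
    rows: list[FeatureRow] = []
    for g in genes:
        rows.extend(build_feature_rows(g))
    mark_all_non_redundant(rows)
    return rows
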