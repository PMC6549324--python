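"""Annotation input/output.

Readers accept GFF3 (gene -> mRNA -> exon/CDS hierarchy linked by
ID/Parent) and GTF2.2 (gene_id/transcript_id attributes, optional
separate ``stop_codon`` features), both through :mod:`gffutils`.
Writers produce the three-table export — a Genes table, a Transcripts
table and a per-exon Gene_Table — as TSV (UTF-8, Unix newlines), with
an optional ``.xlsx`` convenience wrapper.  Column inventories are
documented in ``docs/data_dictionary.md`` and exposed as the
``*_COLUMNS`` constants here.

Conventions:

* the internal CDS span always includes the stop codon; GTF
  ``stop_codon`` features are merged into the CDS on read, and GFF3
  CDS features are assumed stop-inclusive unless
  ``gff3_cds_includes_stop=False`` is passed (the reader then extends
  the span by the adjacent ``stop_codon`` features if present);
* chromosome columns are written as text so "X"/"Y" survive
  spreadsheet round-trips;
* absent optional fields (intron columns on last-exon rows, coding
  columns on fully untranslated exons) are empty cells, never 0.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import gffutils

from .errors import FormatError, MissingDerivationError, TableIntegrityError
from .features import derive_all
from .model import (
    FeatureRow,
    GeneRecord,
    GenomicInterval,
    PROTEIN_CODING,
    TranscriptRecord,
)

logger = logging.getLogger(__name__)

#: Attribute keys the readers look for; override via ``attribute_keys=``.
DEFAULT_ATTRIBUTE_KEYS = {
    "gene_biotype": "gene_biotype",
    "gene_refseq_status": "gene_refseq_status",
    "transcript_refseq_status": "transcript_refseq_status",
    "genome_annotation_status": "genome_annotation_status",
    "chromosome": "chromosome",
    "protein_id": "protein_id",
}

NOT_CURRENT = "not in current annotation release"

GENES_COLUMNS = [
    "GeneID",
    "Gene_Symbol",
    "Chromosome",
    "Gene_Type",
    "Gene_RefSeq_Status",
    "Transcript_RefSeq_Statuses",
    "Gene_Length_bp",
]

TRANSCRIPTS_COLUMNS = [
    "GeneID",
    "Gene_Symbol",
    "Chromosome",
    "Gene_Type",
    "Gene_RefSeq_Status",
    "Transcript_Accession",
    "Transcript_RefSeq_Status",
    "Transcript_Length_bp",
    "UTR5_Length_bp",
    "CDS_Length_bp",
    "UTR3_Length_bp",
    "Exons_per_RNA",
    "Coding_Exons_per_RNA",
]

GENE_TABLE_COLUMNS = [
    "GeneID",
    "Gene_Symbol",
    "Gene_Type",
    "Chromosome",
    "Chromosome_Accession",
    "Strand",
    "Gene_Start",
    "Gene_End",
    "Gene_Length_bp",
    "Transcript_Accession",
    "Transcript_RefSeq_Status",
    "Transcript_Length_bp",
    "CDS_Start",
    "CDS_End",
    "UTR5_Length_bp",
    "CDS_Length_bp",
    "UTR3_Length_bp",
    "Exon_Start",
    "Exon_End",
    "Exon_Length_bp",
    "Exon_Serial",
    "Coding_Start",
    "Coding_End",
    "Coding_Length_bp",
    "Coding_Serial",
    "Intron_Start",
    "Intron_End",
    "Intron_Length_bp",
    "Intron_Serial",
    "Last_Exon",
    "Last_Coding_Exon",
    "Non_Redundant_Exon",
    "Non_Redundant_Coding_Exon",
    "Non_Redundant_Intron",
    "Protein_Accession",
    "Live_Status",
    "Genome_Annotation_Status",
    "Gene_RefSeq_Status",
]


@dataclass
class AnnotationSet:
    """One imported annotation release: genes plus provenance."""

    genes: list[GeneRecord] = dc_field(default_factory=list)
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate gene ids: {', '.join(dupes)}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes)


def _provenance(fmt: str, path) -> dict:
    return {
        "source_format": fmt,
        "source_path": str(path),
        "import_timestamp": datetime.now(timezone.utc).isoformat(),
    }


def _attr1(feature, key: str, default: str = "") -> str:
    vals = feature.attributes.get(key)
    return vals[0] if vals else default


def _strip_prefix(fid: str) -> str:
    # tolerate "gene:..."/"rna:..." style namespaced IDs
    return fid.split(":", 1)[1] if ":" in fid else fid


def _build_set(
    db: gffutils.FeatureDB,
    fmt: str,
    path,
    strict: bool,
    keys: dict[str, str],
    gff3_cds_includes_stop: bool,
) -> AnnotationSet:
    genes: dict[str, GeneRecord] = {}
    order: list[str] = []
    for gf in db.features_of_type("gene"):
        gid = _attr1(gf, "gene_id") or _strip_prefix(gf.id)
        chrom = _attr1(gf, keys["chromosome"]) or gf.seqid.removeprefix("chr")
        biotype = _attr1(gf, keys["gene_biotype"], "")
        # normalize the protein-coding biotype spelling; any other
        # biotype is kept verbatim (curation only tests membership)
        gene_type = (
            PROTEIN_CODING
            if biotype.replace("_", "-") == PROTEIN_CODING
            else (biotype or "other")
        )
        annot_status = _attr1(gf, keys["genome_annotation_status"], "current")
        genes[gid] = GeneRecord(
            gene_id=gid,
            symbol=_attr1(gf, "Name") or _attr1(gf, "gene_name") or gid,
            chromosome=chrom,
            gene_type=gene_type,
            refseq_status=_attr1(gf, keys["gene_refseq_status"], "NA"),
            in_current_annotation=annot_status != NOT_CURRENT,
            span=GenomicInterval(gf.seqid, gf.start, gf.end, gf.strand),
        )
        order.append(gid)

    for tf in list(db.features_of_type("mRNA")) + list(db.features_of_type("transcript")):
        if fmt == "gff3":
            parents = tf.attributes.get("Parent")
            parent_id = _strip_prefix(parents[0]) if parents else None
        else:
            parent_id = _attr1(tf, "gene_id") or None
        if parent_id is None or parent_id not in genes:
            msg = f"transcript {tf.id}: parent gene {parent_id!r} not found"
            if strict:
                raise FormatError(msg)
            logger.warning("skipping: %s", msg)
            continue
        gene = genes[parent_id]

        exon_ivs = []
        for ex in db.children(tf, featuretype="exon"):
            exon_ivs.append(GenomicInterval(ex.seqid, ex.start, ex.end, ex.strand))
        if not exon_ivs:
            msg = f"transcript {tf.id}: no exons"
            if strict:
                raise FormatError(msg)
            logger.warning("skipping: %s", msg)
            continue
        exon_ivs.sort(key=lambda iv: iv.start, reverse=(tf.strand == "-"))
        bad = [iv for iv in exon_ivs if iv.start < tf.start or iv.end > tf.end]
        if bad:
            msg = f"transcript {tf.id}: exon outside the mRNA span"
            if strict:
                raise FormatError(msg)
            logger.warning("skipping: %s", msg)
            continue

        cds_parts = list(db.children(tf, featuretype="CDS"))
        stops = list(db.children(tf, featuretype="stop_codon"))
        cds_span = None
        protein_acc = ""
        spans = list(cds_parts)
        if fmt == "gtf" or not gff3_cds_includes_stop:
            spans += stops
        if spans:
            cds_span = GenomicInterval(
                tf.seqid,
                min(c.start for c in spans),
                max(c.end for c in spans),
                tf.strand,
            )
            protein_acc = next(
                (_attr1(c, keys["protein_id"]) for c in cds_parts if _attr1(c, keys["protein_id"])),
                "",
            )
            covered = all(
                any(iv.start <= p <= iv.end for iv in exon_ivs)
                for p in (cds_span.start, cds_span.end)
            )
            if not covered:
                msg = f"transcript {tf.id}: CDS not covered by exons"
                if strict:
                    raise FormatError(msg)
                logger.warning("skipping: %s", msg)
                continue

        accession = _attr1(tf, "transcript_id") or _strip_prefix(tf.id)
        gene.transcripts.append(
            TranscriptRecord(
                accession=accession,
                exons=exon_ivs,
                cds_span=cds_span,
                refseq_status=_attr1(tf, keys["transcript_refseq_status"], "NA"),
                protein_accession=protein_acc,
            )
        )

    out = []
    for gid in order:
        g = genes[gid]
        if g.transcripts:
            # transcripts were appended after construction; re-run the
            # span consistency check now that they are attached
            g.transcripts.sort(key=lambda t: t.accession)
            out.append(g)
        else:
            logger.warning("gene %s has no usable transcripts; dropped", gid)
    return AnnotationSet(genes=out, provenance=_provenance(fmt, path))


def _make_db(path, force_gtf: bool) -> Optional[gffutils.FeatureDB]:
    text = Path(path).read_text()
    feature_types = {
        line.split("\t")[2]
        for line in text.splitlines()
        if line and not line.startswith("#") and len(line.split("\t")) >= 8
    }
    if not feature_types:  # header-only / empty file -> empty set
        return None
    kwargs: dict = {}
    if force_gtf:
        kwargs.update(
            disable_infer_genes="gene" in feature_types,
            disable_infer_transcripts="transcript" in feature_types,
        )
    try:
        return gffutils.create_db(
            text,
            ":memory:",
            from_string=True,
            keep_order=True,
            merge_strategy="create_unique",
            **kwargs,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_gff3(
    path,
    strict: bool = True,
    attribute_keys: Optional[dict[str, str]] = None,
    gff3_cds_includes_stop: bool = True,
) -> AnnotationSet:
    """Read a GFF3 file into an :class:`AnnotationSet`.

    Exons are sorted into transcription order on read, so the file's
    own feature order is irrelevant.  In strict mode (default) orphan
    Parent links, exons outside their mRNA span and CDS spans not
    covered by exons raise :class:`FormatError`; in lenient mode the
    offending transcript is skipped with a logged warning.
    """
    keys = {**DEFAULT_ATTRIBUTE_KEYS, **(attribute_keys or {})}
    db = _make_db(path, force_gtf=False)
    if db is None:
        return AnnotationSet(genes=[], provenance=_provenance("gff3", path))
    return _build_set(db, "gff3", path, strict, keys, gff3_cds_includes_stop)


def read_gtf(
    path,
    strict: bool = True,
    attribute_keys: Optional[dict[str, str]] = None,
) -> AnnotationSet:
    """Read a GTF2.2 file; ``stop_codon`` features are merged into the CDS."""
    keys = {**DEFAULT_ATTRIBUTE_KEYS, **(attribute_keys or {})}
    db = _make_db(path, force_gtf=True)
    if db is None:
        return AnnotationSet(genes=[], provenance=_provenance("gtf", path))
    return _build_set(db, "gtf", path, strict, keys, gff3_cds_includes_stop=True)


# ---------------------------------------------------------------------------
# GFF3 / GTF writers (used by the synthetic generator and format tests)


def write_gff3(aset: AnnotationSet, path) -> None:
    """Write an AnnotationSet as GFF3 with the attribute keys we read."""
    lines = ["##gff-version 3"]
    for g in aset.genes:
        assert g.span is not None
        status = "current" if g.in_current_annotation else NOT_CURRENT
        biotype = "protein_coding" if g.gene_type == PROTEIN_CODING else g.gene_type
        lines.append(
            "\t".join(
                [
                    g.chrom_accession,
                    "genetables",
                    "gene",
                    str(g.span.start),
                    str(g.span.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID=gene:{g.gene_id};Name={g.symbol};gene_id={g.gene_id};"
                    f"gene_biotype={biotype};gene_refseq_status={g.refseq_status};"
                    f"genome_annotation_status={status};chromosome={g.chromosome}",
                ]
            )
        )
        for t in g.transcripts:
            sp = t.span
            lines.append(
                "\t".join(
                    [
                        g.chrom_accession,
                        "genetables",
                        "mRNA",
                        str(sp.start),
                        str(sp.end),
                        ".",
                        t.strand,
                        ".",
                        f"ID=rna:{t.accession};Parent=gene:{g.gene_id};"
                        f"transcript_id={t.accession};"
                        f"transcript_refseq_status={t.refseq_status}",
                    ]
                )
            )
            for ex in sorted(t.exons, key=lambda e: e.start):
                lines.append(
                    "\t".join(
                        [
                            g.chrom_accession,
                            "genetables",
                            "exon",
                            str(ex.start),
                            str(ex.end),
                            ".",
                            t.strand,
                            ".",
                            f"Parent=rna:{t.accession}",
                        ]
                    )
                )
            if t.cds_span is not None:
                from .features import derive_coding_exons

                attrs = f"Parent=rna:{t.accession}"
                if t.protein_accession:
                    attrs += f";protein_id={t.protein_accession}"
                for _, iv, _ in sorted(
                    derive_coding_exons(t), key=lambda x: x[1].start
                ):
                    lines.append(
                        "\t".join(
                            [
                                g.chrom_accession,
                                "genetables",
                                "CDS",
                                str(iv.start),
                                str(iv.end),
                                ".",
                                t.strand,
                                "0",
                                attrs,
                            ]
                        )
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def _gtf_attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items() if v != "")


def write_gtf(aset: AnnotationSet, path) -> None:
    """Write GTF2.2 with explicit gene/transcript lines.

    The stop codon (last three coding bases in transcription order) is
    emitted as separate ``stop_codon`` feature(s) and excluded from the
    CDS features, per GTF convention; a reader merging the two recovers
    the stop-inclusive CDS span.
    """
    from .features import derive_coding_exons

    lines: list[str] = []
    for g in aset.genes:
        assert g.span is not None
        status = "current" if g.in_current_annotation else NOT_CURRENT
        biotype = "protein_coding" if g.gene_type == PROTEIN_CODING else g.gene_type
        base = dict(
            gene_id=g.gene_id,
            gene_name=g.symbol,
            gene_biotype=biotype,
            gene_refseq_status=g.refseq_status,
            genome_annotation_status=status,
            chromosome=g.chromosome,
        )

        def line(ftype: str, start: int, end: int, attrs: dict) -> str:
            return "\t".join(
                [
                    g.chrom_accession,
                    "genetables",
                    ftype,
                    str(start),
                    str(end),
                    ".",
                    g.strand,
                    "0" if ftype in ("CDS", "stop_codon") else ".",
                    _gtf_attrs(**attrs),
                ]
            )

        lines.append(line("gene", g.span.start, g.span.end, base))
        for t in g.transcripts:
            tattrs = {
                **base,
                "transcript_id": t.accession,
                "transcript_refseq_status": t.refseq_status,
            }
            sp = t.span
            lines.append(line("transcript", sp.start, sp.end, tattrs))
            for ex in sorted(t.exons, key=lambda e: e.start):
                lines.append(line("exon", ex.start, ex.end, tattrs))
            if t.cds_span is None:
                continue
            cattrs = dict(tattrs)
            if t.protein_accession:
                cattrs["protein_id"] = t.protein_accession
            coding = [iv for _, iv, _ in derive_coding_exons(t)]  # transcription order
            positions: list[int] = []
            for iv in coding:
                rng = range(iv.start, iv.end + 1)
                positions.extend(reversed(rng) if t.strand == "-" else rng)
            n_stop = min(3, len(positions))
            stop_pos = set(positions[-n_stop:])
            for iv in coding:
                kept = [p for p in range(iv.start, iv.end + 1) if p not in stop_pos]
                for s, e in _runs(kept):
                    lines.append(line("CDS", s, e, cattrs))
            for s, e in _runs(sorted(stop_pos)):
                lines.append(line("stop_codon", s, e, cattrs))
    Path(path).write_text("\n".join(lines) + "\n")


def _runs(sorted_positions: Sequence[int]):
    """Contiguous (start, end) runs of sorted genomic positions."""
    run_start = prev = None
    for p in sorted_positions:
        if run_start is None:
            run_start = prev = p
        elif p == prev + 1:
            prev = p
        else:
            yield run_start, prev
            run_start = prev = p
    if run_start is not None:
        yield run_start, prev


# ---------------------------------------------------------------------------
# Three-table export


def _cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "Yes" if v else ""
    return str(v)


def _write_tsv(path, columns: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for r in rows:
            w.writerow([_cell(v) for v in r])


def write_genes_table(aset: AnnotationSet, path) -> None:
    """Genes table: one row per gene, chromosome as text."""
    rows = []
    for g in aset.genes:
        statuses = sorted({t.refseq_status for t in g.transcripts})
        rows.append(
            [
                g.gene_id,
                g.symbol,
                g.chromosome,
                g.gene_type,
                g.refseq_status,
                ";".join(statuses),
                g.gene_length if g.span else None,
            ]
        )
    _write_tsv(path, GENES_COLUMNS, rows)


def write_transcripts_table(aset: AnnotationSet, path) -> None:
    """Transcripts table: one row per mRNA with its UTR/CDS length split."""
    from .features import split_utrs

    rows = []
    for g in aset.genes:
        for t in g.transcripts:
            if t.cds_span is not None:
                u5, c, u3 = split_utrs(t)
                n_coding = sum(
                    1 for ex in t.exons if ex.intersection(t.cds_span) is not None
                )
            else:
                u5 = c = u3 = None
                n_coding = 0
            rows.append(
                [
                    g.gene_id,
                    g.symbol,
                    g.chromosome,
                    g.gene_type,
                    g.refseq_status,
                    t.accession,
                    t.refseq_status,
                    t.transcript_len,
                    u5,
                    c,
                    u3,
                    t.n_exons,
                    n_coding,
                ]
            )
    _write_tsv(path, TRANSCRIPTS_COLUMNS, rows)


def write_gene_table(rows: Sequence[FeatureRow], path) -> None:
    """Gene_Table: one row per (transcript, exon) with companion intron.

    Requires derived rows with non-redundancy labels assigned (every
    non-empty derivation labels at least one row per feature class);
    underived input raises :class:`MissingDerivationError`.
    """
    if rows and not any(r.nr_exon for r in rows):
        raise MissingDerivationError(
            "non-redundancy labels absent — run feature derivation first"
        )
    out = []
    for r in rows:
        out.append(
            [
                r.gene_id,
                r.symbol,
                r.gene_type,
                r.chromosome,
                r.chrom_accession,
                r.strand,
                r.gene_start,
                r.gene_end,
                r.gene_length,
                r.transcript_accession,
                r.transcript_refseq_status,
                r.transcript_len,
                r.cds_start,
                r.cds_end,
                r.utr5_len,
                r.cds_len,
                r.utr3_len,
                r.exon_start,
                r.exon_end,
                r.exon_len,
                r.exon_serial,
                r.coding_start,
                r.coding_end,
                r.coding_len,
                r.coding_serial,
                r.intron_start,
                r.intron_end,
                r.intron_len,
                r.intron_serial,
                r.last_exon,
                r.last_coding_exon,
                r.nr_exon,
                r.nr_coding,
                r.nr_intron,
                r.protein_accession,
                "live" if r.live else "dead",
                "current" if r.in_current_annotation else NOT_CURRENT,
                r.gene_refseq_status,
            ]
        )
    _write_tsv(path, GENE_TABLE_COLUMNS, out)


def _int_or_none(s: str) -> Optional[int]:
    return int(s) if s != "" else None


def read_gene_table(path) -> tuple[AnnotationSet, list[FeatureRow]]:
    """Read a Gene_Table TSV back into records and rows.

    Reconstructs genes/transcripts from the exon rows and checks row
    integrity: every stated length must equal end - start + 1, and
    re-deriving introns and coding portions from the reconstructed
    exons must reproduce the file's own values.  Violations raise
    :class:`TableIntegrityError` naming the row.
    """
    rows: list[FeatureRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != GENE_TABLE_COLUMNS:
            raise FormatError(f"{path}: unexpected Gene_Table header")
        for i, rec in enumerate(reader, start=2):
            try:
                row = FeatureRow(
                    gene_id=rec["GeneID"],
                    symbol=rec["Gene_Symbol"],
                    gene_type=rec["Gene_Type"],
                    chromosome=rec["Chromosome"],
                    chrom_accession=rec["Chromosome_Accession"],
                    strand=rec["Strand"],
                    gene_start=int(rec["Gene_Start"]),
                    gene_end=int(rec["Gene_End"]),
                    gene_length=int(rec["Gene_Length_bp"]),
                    transcript_accession=rec["Transcript_Accession"],
                    transcript_refseq_status=rec["Transcript_RefSeq_Status"],
                    transcript_len=int(rec["Transcript_Length_bp"]),
                    cds_start=_int_or_none(rec["CDS_Start"]),
                    cds_end=_int_or_none(rec["CDS_End"]),
                    utr5_len=_int_or_none(rec["UTR5_Length_bp"]),
                    cds_len=_int_or_none(rec["CDS_Length_bp"]),
                    utr3_len=_int_or_none(rec["UTR3_Length_bp"]),
                    exon_start=int(rec["Exon_Start"]),
                    exon_end=int(rec["Exon_End"]),
                    exon_len=int(rec["Exon_Length_bp"]),
                    exon_serial=int(rec["Exon_Serial"]),
                    coding_start=_int_or_none(rec["Coding_Start"]),
                    coding_end=_int_or_none(rec["Coding_End"]),
                    coding_len=_int_or_none(rec["Coding_Length_bp"]),
                    coding_serial=_int_or_none(rec["Coding_Serial"]),
                    intron_start=_int_or_none(rec["Intron_Start"]),
                    intron_end=_int_or_none(rec["Intron_End"]),
                    intron_len=_int_or_none(rec["Intron_Length_bp"]),
                    intron_serial=_int_or_none(rec["Intron_Serial"]),
                    last_exon=rec["Last_Exon"] == "Yes",
                    last_coding_exon=rec["Last_Coding_Exon"] == "Yes",
                    nr_exon=rec["Non_Redundant_Exon"],
                    nr_coding=rec["Non_Redundant_Coding_Exon"],
                    nr_intron=rec["Non_Redundant_Intron"],
                    protein_accession=rec["Protein_Accession"],
                    live=rec["Live_Status"] == "live",
                    in_current_annotation=rec["Genome_Annotation_Status"] == "current",
                    gene_refseq_status=rec["Gene_RefSeq_Status"],
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}: bad row", line=i) from exc
            for what, s, e, ln in (
                ("exon", row.exon_start, row.exon_end, row.exon_len),
                ("coding", row.coding_start, row.coding_end, row.coding_len),
                ("intron", row.intron_start, row.intron_end, row.intron_len),
                ("gene", row.gene_start, row.gene_end, row.gene_length),
            ):
                if s is not None and ln != e - s + 1:
                    raise TableIntegrityError(
                        f"{path} row {i}: {what} length {ln} != "
                        f"{e}-{s}+1 = {e - s + 1}"
                    )
            rows.append(row)

    aset = _reconstruct(rows, path)
    _check_rederivation(aset, rows, path)
    return aset, rows


def _reconstruct(rows: Sequence[FeatureRow], path) -> AnnotationSet:
    genes: dict[str, dict] = {}
    for r in rows:
        g = genes.setdefault(
            r.gene_id,
            {"row": r, "tx": {}},
        )
        tx = g["tx"].setdefault(r.transcript_accession, {"row": r, "exons": {}})
        tx["exons"][r.exon_serial] = GenomicInterval(
            r.chrom_accession, r.exon_start, r.exon_end, r.strand
        )
    out = []
    for gid, g in genes.items():
        r0 = g["row"]
        transcripts = []
        for acc, tx in sorted(g["tx"].items()):
            tr = tx["row"]
            exons = [tx["exons"][s] for s in sorted(tx["exons"])]
            cds = (
                GenomicInterval(tr.chrom_accession, tr.cds_start, tr.cds_end, tr.strand)
                if tr.cds_start is not None
                else None
            )
            transcripts.append(
                TranscriptRecord(
                    accession=acc,
                    exons=exons,
                    cds_span=cds,
                    refseq_status=tr.transcript_refseq_status,
                    protein_accession=tr.protein_accession,
                )
            )
        out.append(
            GeneRecord(
                gene_id=gid,
                symbol=r0.symbol,
                chromosome=r0.chromosome,
                gene_type=r0.gene_type,
                refseq_status=r0.gene_refseq_status,
                in_current_annotation=r0.in_current_annotation,
                live=r0.live,
                span=GenomicInterval(
                    r0.chrom_accession, r0.gene_start, r0.gene_end, r0.strand
                ),
                transcripts=transcripts,
            )
        )
    return AnnotationSet(genes=out, provenance=_provenance("gene_table", path))


def _check_rederivation(aset: AnnotationSet, rows: Sequence[FeatureRow], path) -> None:
    derived = derive_all(aset.genes)
    key = lambda r: (r.gene_id, r.transcript_accession, r.exon_serial)
    want = {key(r): r for r in rows}
    for d in derived:
        r = want.get(key(d))
        if r is None:
            raise TableIntegrityError(
                f"{path}: transcript {d.transcript_accession} exon "
                f"{d.exon_serial} absent from the table"
            )
        for f in (
            "intron_start",
            "intron_end",
            "intron_len",
            "intron_serial",
            "coding_start",
            "coding_end",
            "coding_len",
            "coding_serial",
            "utr5_len",
            "cds_len",
            "utr3_len",
            "last_exon",
        ):
            if getattr(d, f) != getattr(r, f):
                raise TableIntegrityError(
                    f"{path}: {d.transcript_accession} exon {d.exon_serial}: "
                    f"{f} is {getattr(r, f)!r} but re-derivation gives "
                    f"{getattr(d, f)!r}"
                )


def write_tables_xlsx(aset: AnnotationSet, rows: Sequence[FeatureRow], path) -> None:
    """Convenience export of the three tables as one .xlsx workbook."""
    import tempfile

    from openpyxl import Workbook

    wb = Workbook()
    names = ("Genes", "Transcripts", "Gene_Table")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        write_genes_table(aset, tmp / "g.tsv")
        write_transcripts_table(aset, tmp / "t.tsv")
        write_gene_table(rows, tmp / "gt.tsv")
        for name, f in zip(names, ("g.tsv", "t.tsv", "gt.tsv")):
            ws = wb.create_sheet(name) if wb.sheetnames != ["Sheet"] else wb.active
            ws.title = name
            with open(tmp / f, newline="", encoding="utf-8") as fh:
                for rec in csv.reader(fh, delimiter="\t"):
                    ws.append(rec)
    wb.save(path)
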