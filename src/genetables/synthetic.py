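"""Seeded synthetic annotation sets with exact, known ground truth.

The generator emulates the structure the pipeline assumes: curated
multi-isoform protein-coding gene models with exons shared across
isoforms, mono-exonic genes, both strands, 5'UTR/CDS/3'UTR structure
(stop codon inside the CDS), a mix of RefSeq statuses, and
contaminant records (non-protein-coding genes, computational-status
genes, mitochondrial genes, records dropped from the current
annotation, model-predicted XM_ transcripts) that exercise every
curation rule.

Ground truth is tallied *as the models are emitted*, from the
generator's own mRNA-coordinate bookkeeping — never by running the
pipeline's genomic re-derivation — so a full-pipeline run that
reproduces every ground-truth cell is a real recovery test, not a
tautology.

Length distributions are log-normal and feature counts are truncated
geometric; both are pragmatic families parameterized to hit curated
human medians (exon ~131 bp, intron ~1747 bp, ~9 exons per mRNA),
not claims about biology.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .curation import FilterReport
from .errors import ParameterConflictError
from .io import AnnotationSet
from .model import (
    GeneRecord,
    GenomicInterval,
    PROTEIN_CODING,
    TranscriptRecord,
)
from .stats import N_CHROMOSOMES

NUCLEAR_CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y"]

_CONTAMINANTS = ("pseudogene", "mt", "non_current", "model_status", "xm_only")
#: curation rule each contaminant category is charged to (its only defect)
CONTAMINANT_RULE = {
    "pseudogene": "gene_type",
    "model_status": "gene_status",
    "non_current": "not_current",
    "mt": "chromosome",
    "xm_only": "no_passing_transcript",
}


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic annotation generator.

    Medians are in bp (lengths) or features per transcript (counts);
    fractions are probabilities in [0, 1].  The contaminant fractions
    partition genes into defect categories, each violating exactly one
    curation rule, so filter accounting is predictable.
    """

    n_genes: int = 200
    seed: int = 0
    isoforms_mean: float = 2.6
    exons_median: float = 9.0
    exons_min: int = 1
    max_exons: int = 400
    exon_len_median: float = 131.0
    exon_len_sigma: float = 1.0
    intron_len_median: float = 1747.0
    intron_len_sigma: float = 1.4
    intron_len_min: int = 30
    utr5_median: float = 170.0
    utr5_sigma: float = 0.8
    utr3_median: float = 700.0
    utr3_sigma: float = 1.0
    shared_exon_fraction: float = 0.7
    mono_exonic_fraction: float = 0.05
    minus_strand_fraction: float = 0.5
    status_mix: tuple[tuple[str, float], ...] = (
        ("REVIEWED", 0.35),
        ("VALIDATED", 0.65),
    )
    pseudogene_fraction: float = 0.06
    mt_fraction: float = 0.03
    non_current_fraction: float = 0.04
    model_status_fraction: float = 0.05
    xm_only_fraction: float = 0.04
    #: probability a clean gene carries one extra model-predicted (XM_)
    #: transcript, removed at transcript level while the gene is kept
    extra_xm_transcript_fraction: float = 0.15

    def validate(self) -> None:
        fracs = {
            "shared_exon_fraction": self.shared_exon_fraction,
            "mono_exonic_fraction": self.mono_exonic_fraction,
            "minus_strand_fraction": self.minus_strand_fraction,
            "pseudogene_fraction": self.pseudogene_fraction,
            "mt_fraction": self.mt_fraction,
            "non_current_fraction": self.non_current_fraction,
            "model_status_fraction": self.model_status_fraction,
            "xm_only_fraction": self.xm_only_fraction,
            "extra_xm_transcript_fraction": self.extra_xm_transcript_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterConflictError(f"{name}={v} outside [0, 1]")
        total_contaminant = (
            self.pseudogene_fraction
            + self.mt_fraction
            + self.non_current_fraction
            + self.model_status_fraction
            + self.xm_only_fraction
        )
        if total_contaminant > 1.0:
            raise ParameterConflictError("contaminant fractions sum past 1")
        if self.n_genes < 1:
            raise ParameterConflictError("n_genes must be >= 1")
        if self.exons_min < 1:
            raise ParameterConflictError("exons_min must be >= 1")
        if self.mono_exonic_fraction > 0 and self.exons_min > 1:
            raise ParameterConflictError(
                "mono_exonic_fraction > 0 conflicts with exons_min > 1"
            )
        if self.exons_median < self.exons_min:
            raise ParameterConflictError("exons_median below exons_min")
        if self.intron_len_min < 1 or self.exon_len_median < 1:
            raise ParameterConflictError("length parameters must be positive")
        if abs(sum(w for _, w in self.status_mix) - 1.0) > 1e-9:
            raise ParameterConflictError("status_mix weights must sum to 1")


@dataclass
class GroundTruth:
    """Exact expected values for the pipeline run on a generated set.

    ``cells`` maps flattened report keys ("mrnas.length.mean", ...) to
    the values the full pipeline must recover; ``filter`` holds the
    expected curation accounting.  Derived jointly with the annotation
    at emission time, never re-estimated.
    """

    cells: dict[str, Optional[float]] = field(default_factory=dict)
    filter: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, ensure_ascii=False)


# --- internal emission-time bookkeeping -------------------------------------


@dataclass
class _TxTruth:
    gene_id: str
    symbol: str
    accession: str
    chrom_acc: str
    strand: str
    exon_coords: list[tuple[int, int]]  # transcription order
    intron_coords: list[tuple[int, int]]
    coding_coords: list[tuple[int, int]]
    coding_exon_index: list[int]  # exon index of each coding portion
    utr5: int
    cds_len: int
    utr3: int

    @property
    def exon_lens(self):
        return [e - s + 1 for s, e in self.exon_coords]

    @property
    def intron_lens(self):
        return [e - s + 1 for s, e in self.intron_coords]

    @property
    def coding_lens(self):
        return [e - s + 1 for s, e in self.coding_coords]


@dataclass
class _GeneTruth:
    gene_id: str
    symbol: str
    chromosome: str
    span: tuple[int, int]  # over ALL transcripts, kept or not
    kept_transcripts: list[_TxTruth]


def _geom_p_for_median(median_extra: float) -> float:
    # geometric on {0,1,...}; median ~= -1/log2(1-p)
    if median_extra <= 0:
        return 1.0
    return 1.0 - 2.0 ** (-1.0 / median_extra)


def _lognormal_int(rng: np.random.Generator, median: float, sigma: float, lo: int) -> int:
    return max(lo, int(round(float(rng.lognormal(math.log(median), sigma)))))


def generate(params: GeneratorParams) -> tuple[AnnotationSet, GroundTruth]:
    """Emit a seeded annotation set and its exact ground truth.

    Deterministic for a fixed seed: a single explicit RNG stream
    drives every draw, and no global RNG state is touched.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes: list[GeneRecord] = []
    truths: list[_GeneTruth] = []
    removed_by_rule = {r: 0 for r in CONTAMINANT_RULE.values()}
    n_bad_tx_in_kept = 0
    n_tx_total = 0

    cursors: dict[str, int] = {}
    statuses, weights = zip(*params.status_mix)
    p_extra_exon = _geom_p_for_median(params.exons_median - 1.0)

    cat_names = list(_CONTAMINANTS) + ["clean"]
    cat_probs = [
        params.pseudogene_fraction,
        params.mt_fraction,
        params.non_current_fraction,
        params.model_status_fraction,
        params.xm_only_fraction,
    ]
    cat_probs.append(1.0 - sum(cat_probs))

    for i in range(params.n_genes):
        category = cat_names[int(rng.choice(len(cat_names), p=cat_probs))]
        chrom = (
            "MT"
            if category == "mt"
            else NUCLEAR_CHROMOSOMES[int(rng.integers(len(NUCLEAR_CHROMOSOMES)))]
        )
        chrom_acc = f"NC_{chrom}"
        strand = "-" if rng.random() < params.minus_strand_fraction else "+"
        gene_id = f"G{i + 1:05d}"
        symbol = f"SYN{i + 1:04d}"

        # master exon/intron chain, genomically left -> right
        if rng.random() < params.mono_exonic_fraction:
            n_master = 1
        else:
            n_master = min(
                params.max_exons,
                max(params.exons_min, 1 + int(rng.geometric(p_extra_exon)) - 1),
            )
        exon_lens = [
            _lognormal_int(rng, params.exon_len_median, params.exon_len_sigma, 2)
            for _ in range(n_master)
        ]
        intron_lens = [
            _lognormal_int(
                rng, params.intron_len_median, params.intron_len_sigma,
                params.intron_len_min,
            )
            for _ in range(n_master - 1)
        ]
        origin = cursors.get(chrom_acc, 1000) + int(rng.integers(1000, 100000))
        master: list[tuple[int, int]] = []
        pos = origin
        for k, el in enumerate(exon_lens):
            master.append((pos, pos + el - 1))
            pos += el + (intron_lens[k] if k < n_master - 1 else 0)
        cursors[chrom_acc] = pos

        # isoforms: sub-ranges of the master chain, occasionally with
        # trimmed terminal exons so some coordinates are isoform-unique
        n_iso = int(rng.geometric(1.0 / max(1.0, params.isoforms_mean)))
        n_iso = min(n_iso, 6) if n_master > 1 else 1
        iso_exons: list[list[tuple[int, int]]] = []
        for j in range(n_iso):
            if j == 0 or n_master == 1:
                a, b = 0, n_master - 1
            else:
                a = int(rng.integers(0, max(1, n_master // 6)))
                b = n_master - 1 - int(rng.integers(0, max(1, n_master // 6)))
                if b < a:
                    a, b = 0, n_master - 1
            exons = [list(master[k]) for k in range(a, b + 1)]
            if j > 0 and rng.random() > params.shared_exon_fraction:
                # trim the outward edge of a terminal exon (shrink only,
                # so ordering/overlap invariants cannot break)
                for idx, edge in ((0, "left"), (-1, "right")):
                    s, e = exons[idx]
                    room = e - s + 1 - 2
                    if room > 0 and rng.random() < 0.8:
                        delta = int(rng.integers(1, min(room, 50) + 1))
                        if edge == "left":
                            exons[idx][0] = s + delta
                        else:
                            exons[idx][1] = e - delta
            iso_exons.append([tuple(x) for x in exons])

        tx_records: list[TranscriptRecord] = []
        tx_truths: list[_TxTruth] = []
        overall_lo = min(s for iso in iso_exons for s, _ in iso)
        overall_hi = max(e for iso in iso_exons for _, e in iso)

        for j, exons_lr in enumerate(iso_exons):
            order = exons_lr if strand == "+" else list(reversed(exons_lr))
            L = sum(e - s + 1 for s, e in order)
            # mRNA-coordinate CDS placement; stop codon inside the CDS
            u5 = _lognormal_int(rng, params.utr5_median, params.utr5_sigma, 1)
            u3 = _lognormal_int(rng, params.utr3_median, params.utr3_sigma, 1)
            if u5 + u3 > L - 3:
                scale = (L - 3) / (u5 + u3)
                u5 = max(0, int(u5 * scale * 0.9))
                u3 = max(0, min(u3, L - 3 - u5))
            cds_len = L - u5 - u3
            coding_coords: list[tuple[int, int]] = []
            coding_exon_index: list[int] = []
            intron_coords: list[tuple[int, int]] = []
            cum = 0
            for k, (s, e) in enumerate(order):
                el = e - s + 1
                lo = max(cum + 1, u5 + 1)
                hi = min(cum + el, u5 + cds_len)
                if lo <= hi:
                    a_off, b_off = lo - cum, hi - cum  # 1-based within exon
                    if strand == "+":
                        coding_coords.append((s + a_off - 1, s + b_off - 1))
                    else:
                        coding_coords.append((e - b_off + 1, e - a_off + 1))
                    coding_exon_index.append(k)
                if k < len(order) - 1:
                    ns, ne = order[k + 1]
                    if strand == "+":
                        intron_coords.append((e + 1, ns - 1))
                    else:
                        intron_coords.append((ne + 1, s - 1))
                cum += el

            is_xm = category == "xm_only"
            accession = f"{'XM' if is_xm else 'NM'}_{i + 1:05d}{j + 1:02d}.1"
            t_status = str(rng.choice(statuses, p=weights))
            if category == "model_status":
                pass  # transcripts stay curated; the gene status is the defect
            cds_g_lo = min(s for s, _ in coding_coords)
            cds_g_hi = max(e for _, e in coding_coords)
            tx_records.append(
                TranscriptRecord(
                    accession=accession,
                    exons=[
                        GenomicInterval(chrom_acc, s, e, strand) for s, e in order
                    ],
                    cds_span=GenomicInterval(chrom_acc, cds_g_lo, cds_g_hi, strand),
                    refseq_status=t_status,
                    protein_accession=f"NP_{i + 1:05d}{j + 1:02d}.1",
                )
            )
            tx_truths.append(
                _TxTruth(
                    gene_id=gene_id,
                    symbol=symbol,
                    accession=accession,
                    chrom_acc=chrom_acc,
                    strand=strand,
                    exon_coords=order,
                    intron_coords=intron_coords,
                    coding_coords=coding_coords,
                    coding_exon_index=coding_exon_index,
                    utr5=u5,
                    cds_len=cds_len,
                    utr3=u3,
                )
            )

        # one optional model-predicted transcript inside a clean gene:
        # identical structure to isoform 1 but an XM_ accession
        if (
            category == "clean"
            and rng.random() < params.extra_xm_transcript_fraction
        ):
            first = tx_records[0]
            tx_records.append(
                TranscriptRecord(
                    accession=f"XM_{i + 1:05d}99.1",
                    exons=list(first.exons),
                    cds_span=first.cds_span,
                    refseq_status="MODEL",
                    protein_accession=f"XP_{i + 1:05d}99.1",
                )
            )
            n_bad_tx_in_kept += 1

        gene_status = (
            "MODEL" if category == "model_status" else str(rng.choice(statuses, p=weights))
        )
        gene = GeneRecord(
            gene_id=gene_id,
            symbol=symbol,
            chromosome=chrom,
            gene_type="pseudo" if category == "pseudogene" else PROTEIN_CODING,
            refseq_status=gene_status,
            in_current_annotation=category != "non_current",
            transcripts=tx_records,
        )
        genes.append(gene)
        n_tx_total += len(tx_records)
        if category == "clean":
            truths.append(
                _GeneTruth(
                    gene_id=gene_id,
                    symbol=symbol,
                    chromosome=chrom,
                    span=(overall_lo, overall_hi),
                    kept_transcripts=tx_truths,
                )
            )
        else:
            removed_by_rule[CONTAMINANT_RULE[category]] += 1

    gt = GroundTruth(cells=_expected_cells(truths))
    gt.filter = {
        "input_genes": params.n_genes,
        "retained_genes": len(truths),
        "removed_by_rule": removed_by_rule,
        "input_transcripts": n_tx_total,
        "retained_transcripts": sum(len(t.kept_transcripts) for t in truths),
        "transcripts_removed_within_kept_genes": n_bad_tx_in_kept,
    }
    aset = AnnotationSet(
        genes=genes,
        provenance={"source_format": "synthetic", "seed": params.seed},
    )
    return aset, gt


# --- independent ground-truth arithmetic ------------------------------------


def _stats_cells(prefix: str, values: list[float]) -> dict:
    out: dict[str, Optional[float]] = {f"{prefix}.n": len(values)}
    keys = ("median", "mean", "sd", "min", "max", "total")
    if not values:
        out.update({f"{prefix}.{k}": None for k in keys})
        return out
    out[f"{prefix}.median"] = float(statistics.median(values))
    out[f"{prefix}.mean"] = statistics.fmean(values)
    out[f"{prefix}.sd"] = (
        statistics.stdev([float(v) for v in values]) if len(values) > 1 else None
    )
    out[f"{prefix}.min"] = float(min(values))
    out[f"{prefix}.max"] = float(max(values))
    out[f"{prefix}.total"] = float(sum(values))
    return out


def _expected_cells(truths: list[_GeneTruth]) -> dict[str, Optional[float]]:
    cells: dict[str, Optional[float]] = {}
    cells["genes.n"] = len(truths)
    cells["genes.mean_per_chromosome"] = len(truths) / N_CHROMOSOMES
    per_chr: dict[str, int] = {}
    for g in truths:
        per_chr[g.chromosome] = per_chr.get(g.chromosome, 0) + 1
    for c, n in per_chr.items():
        cells[f"genes.per_chromosome.{c}"] = n
    cells.update(
        _stats_cells("genes.length", [g.span[1] - g.span[0] + 1 for g in truths])
    )

    txs = [t for g in truths for t in g.kept_transcripts]
    cells["mrnas.n"] = len(txs)
    cells.update(_stats_cells("mrnas.length", [sum(t.exon_lens) for t in txs]))
    cells.update(_stats_cells("mrnas.utr5", [t.utr5 for t in txs]))
    cells.update(_stats_cells("mrnas.cds", [t.cds_len for t in txs]))
    cells.update(_stats_cells("mrnas.utr3", [t.utr3 for t in txs]))

    # rows of each feature class: (identity key, sort key, length, is_last_exon)
    for cls in ("exon", "coding", "intron"):
        entries = []
        for t in txs:
            if cls == "exon":
                coords = t.exon_coords
                idx = list(range(len(coords)))
                serials = [k + 1 for k in idx]
            elif cls == "coding":
                coords = t.coding_coords
                idx = t.coding_exon_index
                serials = [k + 1 for k in range(len(coords))]
            else:
                coords = t.intron_coords
                idx = list(range(len(coords)))
                serials = [k + 1 for k in idx]
            n_ex = len(t.exon_coords)
            for (s, e), exon_idx, serial in zip(coords, idx, serials):
                entries.append(
                    {
                        "key": (t.chrom_acc, t.strand, s, e),
                        "sort": (t.gene_id, t.accession, serial),
                        "len": e - s + 1,
                        "last": (
                            exon_idx == n_ex - 1 if cls != "intron" else False
                        ),
                    }
                )
        cells[f"features.{cls}.raw.n"] = len(entries)
        cells.update(
            _stats_cells(f"features.{cls}.raw.length", [x["len"] for x in entries])
        )
        groups: dict[tuple, list[dict]] = {}
        for x in entries:
            groups.setdefault(x["key"], []).append(x)
        reps = [min(g, key=lambda x: x["sort"]) for g in groups.values()]
        cells[f"features.{cls}.non_redundant.n"] = len(reps)
        cells.update(
            _stats_cells(
                f"features.{cls}.non_redundant.length", [x["len"] for x in reps]
            )
        )
        if cls in ("exon", "coding"):
            cells.update(
                _stats_cells(
                    f"features.{cls}.raw.not_last",
                    [x["len"] for x in entries if not x["last"]],
                )
            )
            cells.update(
                _stats_cells(
                    f"features.{cls}.non_redundant.not_last",
                    [x["len"] for x in reps if not x["last"]],
                )
            )

        # per-transcript feature counts
        counts = []
        gene_ids = []
        for t in txs:
            if cls == "exon":
                c = len(t.exon_coords)
            elif cls == "coding":
                c = len(t.coding_coords)
            else:
                c = len(t.exon_coords) - 1
            counts.append(c)
            gene_ids.append(t.gene_id)
        pref = f"features.{cls}.per_transcript"
        cells.update(_stats_cells(f"{pref}.stats", counts))
        if cls == "intron":
            positive = [c for c in counts if c >= 1]
            if positive:
                mn = min(positive)
                cells[f"{pref}.stats.min"] = float(mn)
                cells[f"{pref}.min_n_transcripts"] = sum(
                    1 for c in counts if c == mn
                )
                cells[f"{pref}.min_n_genes"] = len(
                    {g for c, g in zip(counts, gene_ids) if c == mn}
                )
            else:
                cells[f"{pref}.stats.min"] = None
        elif counts:
            mn = min(counts)
            cells[f"{pref}.min_n_transcripts"] = sum(1 for c in counts if c == mn)
            cells[f"{pref}.min_n_genes"] = len(
                {g for c, g in zip(counts, gene_ids) if c == mn}
            )
    return cells


def compare_to_ground_truth(
    report_flat: dict, gt: GroundTruth, rel_tol: float = 1e-9
) -> list[str]:
    """Mismatches between a flattened StatsReport and the ground truth.

    Integer-valued cells must match exactly; real cells to ``rel_tol``
    relative.  Returns a list of human-readable mismatch descriptions
    (empty = full recovery).
    """
    problems = []
    for key, want in gt.cells.items():
        if key not in report_flat:
            problems.append(f"{key}: missing from report")
            continue
        got = report_flat[key]
        if want is None or got is None:
            if want != got:
                problems.append(f"{key}: expected {want!r}, got {got!r}")
            continue
        if float(want).is_integer() and float(got).is_integer():
            if int(want) != int(got):
                problems.append(f"{key}: expected {want}, got {got}")
        elif not math.isclose(float(want), float(got), rel_tol=rel_tol):
            problems.append(f"{key}: expected {want}, got {got}")
    return problems


def compare_filter_report(report: FilterReport, gt: GroundTruth) -> list[str]:
    """Mismatches between curation accounting and generator knowledge."""
    problems = []
    f = gt.filter
    pairs = [
        ("input_genes", report.input_genes),
        ("retained_genes", report.retained_genes),
        ("input_transcripts", report.input_transcripts),
        ("retained_transcripts", report.retained_transcripts),
        (
            "transcripts_removed_within_kept_genes",
            report.transcripts_removed_within_kept_genes,
        ),
    ]
    for key, got in pairs:
        if f[key] != got:
            problems.append(f"{key}: expected {f[key]}, got {got}")
    for rule, want in f["removed_by_rule"].items():
        got = report.removed_by_rule.get(rule, 0)
        if want != got:
            problems.append(f"removed_by_rule[{rule}]: expected {want}, got {got}")
    return problems


def make_edge_fixtures() -> AnnotationSet:
    """A fixed annotation set exercising every boundary shape.

    Contains: an internal 2-bp exon; a coding exon of exactly 1 bp
    (the CDS starts on the last base of the first exon); a 26-bp
    intron (flagged at the default 30-bp threshold) next to a gene
    whose shortest intron is exactly 30 bp (not flagged); a
    mono-exonic gene; and a 363-exon transcript.  All records pass
    the default curation policy; every derived value is hand-checkable.
    """

    def iv(acc, s, e, strand):
        return GenomicInterval(acc, s, e, strand)

    genes = []
    # internal 2-bp exon (E2)
    acc = "NC_EDGE1"
    genes.append(
        GeneRecord(
            gene_id="E00001",
            symbol="SHORTEXON2BP",
            chromosome="5",
            refseq_status="REVIEWED",
            transcripts=[
                TranscriptRecord(
                    accession="NM_E0000101.1",
                    exons=[
                        iv(acc, 1000, 1999, "+"),
                        iv(acc, 3000, 3001, "+"),
                        iv(acc, 5000, 5999, "+"),
                    ],
                    cds_span=iv(acc, 1500, 5499, "+"),
                    refseq_status="REVIEWED",
                    protein_accession="NP_E0000101.1",
                )
            ],
        )
    )
    # 1-bp coding exon: CDS starts on the last base of E1
    acc = "NC_EDGE2"
    genes.append(
        GeneRecord(
            gene_id="E00002",
            symbol="CODING1BP",
            chromosome="11",
            refseq_status="VALIDATED",
            transcripts=[
                TranscriptRecord(
                    accession="NM_E0000201.1",
                    exons=[
                        iv(acc, 1000, 1300, "+"),
                        iv(acc, 2000, 2399, "+"),
                        iv(acc, 3000, 3499, "+"),
                    ],
                    cds_span=iv(acc, 1300, 3100, "+"),
                    refseq_status="VALIDATED",
                    protein_accession="NP_E0000201.1",
                )
            ],
        )
    )
    # 26-bp intron on the minus strand (non-canonical excision shape)
    acc = "NC_EDGE3"
    genes.append(
        GeneRecord(
            gene_id="E00003",
            symbol="INTRON26BP",
            chromosome="22",
            refseq_status="REVIEWED",
            transcripts=[
                TranscriptRecord(
                    accession="NM_E0000301.1",
                    exons=[iv(acc, 1126, 1225, "-"), iv(acc, 1000, 1099, "-")],
                    cds_span=iv(acc, 1050, 1175, "-"),
                    refseq_status="REVIEWED",
                    protein_accession="NP_E0000301.1",
                )
            ],
        )
    )
    # shortest intron exactly at the 30-bp threshold: not flagged
    acc = "NC_EDGE4"
    genes.append(
        GeneRecord(
            gene_id="E00004",
            symbol="INTRON30BP",
            chromosome="12",
            refseq_status="VALIDATED",
            transcripts=[
                TranscriptRecord(
                    accession="NM_E0000401.1",
                    exons=[iv(acc, 2000, 2099, "+"), iv(acc, 2130, 2229, "+")],
                    cds_span=iv(acc, 2050, 2179, "+"),
                    refseq_status="VALIDATED",
                    protein_accession="NP_E0000401.1",
                )
            ],
        )
    )
    # mono-exonic gene: a single row, Last_Exon = Yes, no intron fields
    acc = "NC_EDGE5"
    genes.append(
        GeneRecord(
            gene_id="E00005",
            symbol="MONOEXON",
            chromosome="X",
            refseq_status="REVIEWED",
            transcripts=[
                TranscriptRecord(
                    accession="NM_E0000501.1",
                    exons=[iv(acc, 1000, 1999, "+")],
                    cds_span=iv(acc, 1200, 1799, "+"),
                    refseq_status="REVIEWED",
                    protein_accession="NP_E0000501.1",
                )
            ],
        )
    )
    # 363 exons in one transcript
    acc = "NC_EDGE6"
    exons = [iv(acc, 10000 + k * 200, 10000 + k * 200 + 99, "+") for k in range(363)]
    genes.append(
        GeneRecord(
            gene_id="E00006",
            symbol="MANYEXON363",
            chromosome="2",
            refseq_status="REVIEWED",
            transcripts=[
                TranscriptRecord(
                    accession="NM_E0000601.1",
                    exons=exons,
                    cds_span=iv(acc, 10050, exons[-1].start + 49, "+"),
                    refseq_status="REVIEWED",
                    protein_accession="NP_E0000601.1",
                )
            ],
        )
    )
    return AnnotationSet(
        genes=genes, provenance={"source_format": "synthetic", "fixture": "edges"}
    )
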