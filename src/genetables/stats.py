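"""Descriptive statistics over curated gene sets.

Produces the number/length summary blocks for genes, mRNAs, exons,
coding exons and introns (raw and non-redundant, with and without
last exons), plus release-over-release comparisons.

Conventions, chosen to reproduce spreadsheet-style summaries:

* median uses the midpoint rule (mean of the two central order
  statistics for even n);
* SD is the sample standard deviation (n-1 denominator, spreadsheet
  STDEV default); population SD is available behind a flag;
* rounding for display is half-away-from-zero — lengths to integer
  bp, per-transcript counts and percentages to one decimal;
* the mean number of genes per chromosome divides by a fixed 24
  (22 autosomes + X + Y) regardless of which chromosomes are present.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import UndefinedStatisticError
from .features import FEATURE_CLASSES, split_utrs
from .model import FeatureRow, GeneRecord, SummaryStats

#: Fixed divisor for "mean genes per chromosome": 22 autosomes + X + Y.
N_CHROMOSOMES = 24


def summarize(
    values: Sequence[float],
    labels: Optional[Sequence[str]] = None,
    population_sd: bool = False,
) -> SummaryStats:
    """n, median, mean, SD, min, max, total of one batch of values.

    An empty batch returns the empty-stats marker (n=0, everything else
    None) — never zeros, since 0 is a valid-looking length.  SD is None
    for n=1.  ``labels`` (same length as ``values``) identify the
    extreme features; all tied extremes are reported, sorted.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n == 0:
        return SummaryStats(n=0)
    total = float(vals.sum())
    mean = total / n
    if n == 1:
        sd = None
    else:
        sd = float(vals.std(ddof=0 if population_sd else 1))
    vmin = float(vals.min())
    vmax = float(vals.max())
    min_labels: list[str] = []
    max_labels: list[str] = []
    if labels is not None:
        if len(labels) != n:
            raise ValueError("labels and values length mismatch")
        min_labels = sorted({l for v, l in zip(vals, labels) if v == vmin})
        max_labels = sorted({l for v, l in zip(vals, labels) if v == vmax})
    return SummaryStats(
        n=n,
        median=float(np.median(vals)),
        mean=mean,
        sd=sd,
        min=vmin,
        max=vmax,
        total=total,
        min_labels=min_labels,
        max_labels=max_labels,
    )


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (spreadsheet ROUND), e.g. 2.5 -> 3."""
    q = Decimal(1).scaleb(-decimals)
    r = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(r) if decimals > 0 else float(int(r))


def mean_from_totals(total: float, n: int, decimals: int = 0) -> float:
    """Mean computed from a printed total and count, display-rounded.

    The division is done in decimal arithmetic and rounded
    half-away-from-zero, so the result matches a spreadsheet ROUND of
    the same ratio exactly.
    """
    if n == 0:
        raise UndefinedStatisticError("mean over zero entries")
    q = Decimal(1).scaleb(-decimals)
    r = (Decimal(repr(float(total))) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP)
    return float(r)


def percent_change(old: float, new: float, decimals: int = 1) -> float:
    """Percent change from ``old`` to ``new``: 100*(new-old)/old."""
    if old <= 0:
        raise UndefinedStatisticError("percent change with non-positive base")
    q = Decimal(1).scaleb(-decimals)
    r = (
        Decimal(100) * (Decimal(repr(float(new))) - Decimal(repr(float(old))))
        / Decimal(repr(float(old)))
    ).quantize(q, rounding=ROUND_HALF_UP)
    return float(r)


def per_chromosome_counts(
    genes: Iterable[GeneRecord],
) -> tuple[dict[str, int], list[str], list[str]]:
    """Gene count per chromosome, plus argmin/argmax chromosome lists.

    Chromosome keys are text; ties in the extremes are returned as
    sorted lists.  An empty set yields an empty table.
    """
    counts: dict[str, int] = {}
    for g in genes:
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
    if not counts:
        return {}, [], []
    lo = min(counts.values())
    hi = max(counts.values())
    return (
        counts,
        sorted(c for c, v in counts.items() if v == lo),
        sorted(c for c, v in counts.items() if v == hi),
    )


_LEN_FIELD = {"exon": "exon_len", "coding": "coding_len", "intron": "intron_len"}
_NR_FIELD = {"exon": "nr_exon", "coding": "nr_coding", "intron": "nr_intron"}
_SERIAL_PREFIX = {"exon": "E", "coding": "E", "intron": "I"}


def _feature_label(row: FeatureRow, feature_class: str) -> str:
    # coding portions are named after their host exon's serial, the way
    # the extremes are conventionally cited (e.g. "GSTP1, E1")
    serial = row.intron_serial if feature_class == "intron" else row.exon_serial
    return f"{row.symbol}, {_SERIAL_PREFIX[feature_class]}{serial}"


def feature_lengths(
    rows: Iterable[FeatureRow],
    feature_class: str,
    non_redundant: bool = False,
    exclude_last_exon: bool = False,
) -> tuple[list[int], list[str]]:
    """Length batch for one feature class under the standard filters."""
    len_field = _LEN_FIELD[feature_class]
    nr_field = _NR_FIELD[feature_class]
    values: list[int] = []
    labels: list[str] = []
    for row in rows:
        v = getattr(row, len_field)
        if v is None:
            continue
        if non_redundant and not getattr(row, nr_field):
            continue
        if exclude_last_exon and row.last_exon:
            continue
        values.append(v)
        labels.append(_feature_label(row, feature_class))
    return values, labels


def not_last_exon_stats(
    rows: Iterable[FeatureRow],
    feature_class: str = "exon",
    non_redundant: bool = False,
) -> SummaryStats:
    """Length stats excluding rows of each transcript's last exon.

    The last exon is usually the longest (it carries the 3' UTR), so
    the not-last variant describes internal feature lengths.  A set of
    only mono-exonic transcripts yields the empty-stats marker.
    """
    values, labels = feature_lengths(
        rows, feature_class, non_redundant=non_redundant, exclude_last_exon=True
    )
    return summarize(values, labels)


def per_transcript_count_stats(
    genes: Iterable[GeneRecord], feature_class: str
) -> dict:
    """Distribution of feature counts per transcript.

    ``feature_class`` is "exon" (exons per mRNA), "coding" (coding
    exons per mRNA) or "intron" (exons - 1 per mRNA).  Median, mean,
    SD and total include every transcript; the *intron* minimum is
    taken excluding mono-exonic transcripts (which trivially have
    zero introns) and the excluded transcript/gene tallies are
    reported alongside.
    """
    counts: list[int] = []
    labels: list[str] = []
    gene_of: list[str] = []
    for g in genes:
        for t in g.transcripts:
            if feature_class == "exon":
                c = t.n_exons
            elif feature_class == "coding":
                c = (
                    sum(1 for ex in t.exons if ex.intersection(t.cds_span))
                    if t.cds_span
                    else 0
                )
            elif feature_class == "intron":
                c = t.n_exons - 1
            else:
                raise ValueError(f"unknown feature class {feature_class!r}")
            counts.append(c)
            labels.append(f"{g.symbol}, chr{g.chromosome}")
            gene_of.append(g.gene_id)
    stats = summarize(counts, labels)
    block = {"stats": stats}
    if feature_class == "intron" and counts:
        positive = [(c, l, gid) for c, l, gid in zip(counts, labels, gene_of) if c >= 1]
        if positive:
            mn = min(c for c, _, _ in positive)
            stats.min = float(mn)
            stats.min_labels = sorted({l for c, l, _ in positive if c == mn})
            block["min_n_transcripts"] = sum(1 for c, _, _ in positive if c == mn)
            block["min_n_genes"] = len({g for c, _, g in positive if c == mn})
        else:
            stats.min = None
            stats.min_labels = []
    elif counts:
        mn = stats.min
        block["min_n_transcripts"] = sum(1 for c in counts if c == mn)
        block["min_n_genes"] = len(
            {g for c, g in zip(counts, gene_of) if c == mn}
        )
    return block


@dataclass
class StatsReport:
    """Full descriptive report for one curated, derived annotation set.

    Values are stored unrounded; display rounding happens only in
    :meth:`render_text`.
    """

    genes: dict = field(default_factory=dict)
    mrnas: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)

    def flatten(self) -> dict[str, float]:
        """Flat ``{"genes.length.mean": value, ...}`` view of every cell."""
        flat: dict[str, float] = {}

        def walk(prefix: str, obj) -> None:
            if isinstance(obj, SummaryStats):
                for k in ("n", "median", "mean", "sd", "min", "max", "total"):
                    flat[f"{prefix}.{k}"] = getattr(obj, k)
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (int, float)) and not isinstance(obj, bool):
                flat[prefix] = obj

        walk("genes", self.genes)
        walk("mrnas", self.mrnas)
        walk("features", self.features)
        return flat

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, SummaryStats):
                return asdict(obj)
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [conv(v) for v in obj]
            return obj

        return {
            "genes": conv(self.genes),
            "mrnas": conv(self.mrnas),
            "features": conv(self.features),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, ensure_ascii=False)

    def render_text(self) -> str:
        """Human-readable two-table layout (genes/mRNAs, then features)."""
        out: list[str] = []

        def fmt(v, dec=0):
            if v is None:
                return "N/A"
            return f"{round_half_away(v, dec):,.{dec}f}"

        def stat_lines(name: str, s: SummaryStats, dec=0):
            if s.is_empty:
                out.append(f"  {name}: (empty)")
                return
            out.append(
                f"  {name}: n={s.n:,} median={fmt(s.median, dec)} "
                f"mean={fmt(s.mean, dec)} sd={fmt(s.sd, dec)} "
                f"min={fmt(s.min, dec)}{_lab(s.min_labels)} "
                f"max={fmt(s.max, dec)}{_lab(s.max_labels)} total={fmt(s.total, dec)}"
            )

        def _lab(labels):
            return f" ({'; '.join(labels)})" if labels else ""

        g = self.genes
        out.append("== Genes ==")
        out.append(f"  Total entries: {g['n']:,}")
        out.append(f"  Mean per chromosome (/24): {fmt(g['mean_per_chromosome'])}")
        if g["min_chromosomes"]:
            out.append(
                f"  Min per chromosome: chr{','.join(g['min_chromosomes'])}; "
                f"Max per chromosome: chr{','.join(g['max_chromosomes'])}"
            )
        stat_lines("Length (bp)", g["length"])
        m = self.mrnas
        out.append("== mRNAs ==")
        out.append(f"  Total entries: {m['n']:,}")
        for key, name in (
            ("length", "Length (bp)"),
            ("utr5", "5' UTR (bp)"),
            ("cds", "CDS (bp)"),
            ("utr3", "3' UTR (bp)"),
        ):
            stat_lines(name, m[key])
        names = {"exon": "Exons", "coding": "Coding exons", "intron": "Introns"}
        for cls in FEATURE_CLASSES:
            f = self.features[cls]
            out.append(f"== {names[cls]} ==")
            out.append(f"  Total entries: {f['raw']['n']:,}")
            out.append(f"  Total non-redundant entries: {f['non_redundant']['n']:,}")
            pt = f["per_transcript"]["stats"]
            stat_lines("Per transcript", pt, dec=1)
            stat_lines("Length (bp)", f["raw"]["length"])
            stat_lines("Length non-redundant (bp)", f["non_redundant"]["length"])
            if "not_last" in f["raw"]:
                stat_lines("Length, not last exon (bp)", f["raw"]["not_last"])
                stat_lines(
                    "Length non-redundant, not last exon (bp)",
                    f["non_redundant"]["not_last"],
                )
        return "\n".join(out)


def build_report(
    genes: Sequence[GeneRecord], rows: Sequence[FeatureRow]
) -> StatsReport:
    """Assemble the full report from a curated gene set and derived rows."""
    report = StatsReport()

    counts, min_chrs, max_chrs = per_chromosome_counts(genes)
    gene_lengths = [g.gene_length for g in genes]
    gene_labels = [f"{g.symbol}, chr{g.chromosome}" for g in genes]
    report.genes = {
        "n": len(genes),
        "per_chromosome": counts,
        "min_chromosomes": min_chrs,
        "max_chromosomes": max_chrs,
        "mean_per_chromosome": len(genes) / N_CHROMOSOMES,
        "length": summarize(gene_lengths, gene_labels),
    }

    tx = [(g, t) for g in genes for t in g.transcripts]
    tx_labels = [f"{g.symbol}, chr{g.chromosome}" for g, _ in tx]
    utr5s, cdss, utr3s = [], [], []
    for _, t in tx:
        if t.cds_span is not None:
            u5, c, u3 = split_utrs(t)
            utr5s.append(u5)
            cdss.append(c)
            utr3s.append(u3)
    report.mrnas = {
        "n": len(tx),
        "length": summarize([t.transcript_len for _, t in tx], tx_labels),
        "utr5": summarize(utr5s),
        "cds": summarize(cdss),
        "utr3": summarize(utr3s),
    }

    report.features = {}
    for cls in FEATURE_CLASSES:
        raw_vals, raw_labels = feature_lengths(rows, cls)
        nr_vals, nr_labels = feature_lengths(rows, cls, non_redundant=True)
        block = {
            "raw": {"n": len(raw_vals), "length": summarize(raw_vals, raw_labels)},
            "non_redundant": {"n": len(nr_vals), "length": summarize(nr_vals, nr_labels)},
            "per_transcript": per_transcript_count_stats(genes, cls),
        }
        if cls in ("exon", "coding"):
            block["raw"]["not_last"] = not_last_exon_stats(rows, cls)
            block["non_redundant"]["not_last"] = not_last_exon_stats(
                rows, cls, non_redundant=True
            )
        report.features[cls] = block
    return report


@dataclass
class MetricDelta:
    metric: str
    old: Optional[float]
    new: Optional[float]
    delta: Optional[float]
    percent: Optional[float]


def compare_reports(a: StatsReport, b: StatsReport) -> dict:
    """Release-over-release comparison of two reports.

    Emits old value, new value, absolute and percent change for every
    metric present in both reports; metrics present in only one side
    are listed as missing, never treated as errors.
    """
    fa, fb = a.flatten(), b.flatten()
    deltas: list[MetricDelta] = []
    for key in sorted(set(fa) & set(fb)):
        old, new = fa[key], fb[key]
        if old is None or new is None:
            deltas.append(MetricDelta(key, old, new, None, None))
            continue
        delta = new - old
        pct = percent_change(old, new) if old > 0 else None
        deltas.append(MetricDelta(key, old, new, delta, pct))
    return {
        "deltas": deltas,
        "missing_in_old": sorted(set(fb) - set(fa)),
        "missing_in_new": sorted(set(fa) - set(fb)),
    }


def comparison_to_json(comparison: dict, indent: int = 2) -> str:
    return json.dumps(
        {
            "deltas": [asdict(d) for d in comparison["deltas"]],
            "missing_in_old": comparison["missing_in_old"],
            "missing_in_new": comparison["missing_in_new"],
        },
        indent=indent,
        ensure_ascii=False,
    )


def nan_safe(x: Optional[float]) -> Optional[float]:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else x
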