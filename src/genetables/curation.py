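"""Record-selection policy defining the curated analysis set.

The default policy keeps nuclear protein-coding genes whose RefSeq
status is human-curated (REVIEWED or VALIDATED) at both gene and
transcript level, that are part of the current annotation release, and
that retain at least one curated mRNA with an "NM_" accession.  Genes
are tested against the rules in a fixed order and a removed gene is
counted once, at the first rule it fails, so removal accounting is
reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields

from .model import GeneRecord, PROTEIN_CODING, TranscriptRecord

#: Rule application order; a gene is charged to the first failing rule.
RULE_ORDER = (
    "gene_type",
    "gene_status",
    "not_current",
    "chromosome",
    "no_passing_transcript",
)


@dataclass(frozen=True)
class CurationPolicy:
    """Which gene and transcript records belong in the curated set.

    ``transcript_accession_prefix`` restricts mRNAs to curated RefSeq
    records (``NM_``), excluding model predictions (``XM_``).  Status
    ``NA`` (no annotation) always fails the status tests: curation is
    conservative.
    """

    allowed_gene_types: frozenset[str] = frozenset({PROTEIN_CODING})
    allowed_gene_statuses: frozenset[str] = frozenset({"REVIEWED", "VALIDATED"})
    allowed_transcript_statuses: frozenset[str] = frozenset({"REVIEWED", "VALIDATED"})
    require_current_annotation: bool = True
    exclude_chromosomes: frozenset[str] = frozenset({"MT"})
    transcript_accession_prefix: str = "NM_"

    def __post_init__(self) -> None:
        if not self.allowed_gene_types or not self.allowed_gene_statuses:
            raise ValueError("allowed type/status sets must be non-empty")
        if not self.allowed_transcript_statuses:
            raise ValueError("allowed transcript status set must be non-empty")

    def transcript_passes(self, t: TranscriptRecord) -> bool:
        return t.refseq_status in self.allowed_transcript_statuses and t.accession.startswith(
            self.transcript_accession_prefix
        )

    def first_failing_rule(self, gene: GeneRecord) -> str | None:
        """Name of the first rule the gene fails, or None if it passes."""
        if gene.gene_type not in self.allowed_gene_types:
            return "gene_type"
        if gene.refseq_status not in self.allowed_gene_statuses:
            return "gene_status"
        if self.require_current_annotation and not gene.in_current_annotation:
            return "not_current"
        if gene.chromosome in self.exclude_chromosomes:
            return "chromosome"
        if not any(self.transcript_passes(t) for t in gene.transcripts):
            return "no_passing_transcript"
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "CurationPolicy":
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = frozenset(v) if isinstance(v, (list, set, tuple)) else v
        return cls(**kwargs)


@dataclass
class FilterReport:
    """Accounting of what the curation filter removed, per rule."""

    input_genes: int = 0
    retained_genes: int = 0
    removed_by_rule: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in RULE_ORDER}
    )
    input_transcripts: int = 0
    retained_transcripts: int = 0
    #: transcripts dropped inside genes that were themselves retained
    transcripts_removed_within_kept_genes: int = 0

    @property
    def removed_genes(self) -> int:
        return sum(self.removed_by_rule.values())


def apply_curation(
    genes: list[GeneRecord], policy: CurationPolicy | None = None
) -> tuple[list[GeneRecord], FilterReport]:
    """Filter a gene list down to the curated analysis set.

    Returns new gene records (inputs are not mutated): kept genes carry
    only their passing transcripts.  A gene whose transcripts all fail
    is removed entirely — "at least one curated transcript" is a
    gene-level condition.  Filtering never raises; malformed records
    are a reader-level concern.
    """
    policy = policy or CurationPolicy()
    report = FilterReport(input_genes=len(genes))
    report.input_transcripts = sum(len(g.transcripts) for g in genes)
    kept: list[GeneRecord] = []
    for gene in genes:
        rule = policy.first_failing_rule(gene)
        if rule is not None:
            report.removed_by_rule[rule] += 1
            continue
        g = copy.copy(gene)
        g.transcripts = [t for t in gene.transcripts if policy.transcript_passes(t)]
        report.transcripts_removed_within_kept_genes += len(gene.transcripts) - len(
            g.transcripts
        )
        report.retained_transcripts += len(g.transcripts)
        kept.append(g)
    report.retained_genes = len(kept)
    return kept, report
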