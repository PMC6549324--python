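"""Property-based invariants over randomly generated gene models."""

import random

from hypothesis import given, settings, strategies as st

import genetables as gt
from genetables.features import build_feature_rows, mark_non_redundant
from genetables.model import GeneRecord, GenomicInterval, TranscriptRecord
from genetables.stats import mean_from_totals, summarize


@st.composite
def transcripts(draw, coding=True):
    """A random valid transcript on either strand."""
    strand = draw(st.sampled_from("+-"))
    n_exons = draw(st.integers(1, 8))
    pos = draw(st.integers(1, 1000))
    exons_lr = []
    for i in range(n_exons):
        # first exon >= 3 bp so a stop-inclusive CDS always fits
        ln = draw(st.integers(3 if i == 0 else 1, 60))
        exons_lr.append((pos, pos + ln - 1))
        pos += ln + draw(st.integers(1, 120))
    order = exons_lr if strand == "+" else list(reversed(exons_lr))
    L = sum(e - s + 1 for s, e in order)
    cds = None
    if coding and L >= 3:
        u5 = draw(st.integers(0, L - 3))
        u3 = draw(st.integers(0, L - 3 - u5))
        first, last = u5 + 1, L - u3

        def to_genomic(mpos):
            cum = 0
            for s, e in order:
                ln = e - s + 1
                if mpos <= cum + ln:
                    off = mpos - cum
                    return s + off - 1 if strand == "+" else e - off + 1
                cum += ln
            raise AssertionError

        a, b = to_genomic(first), to_genomic(last)
        cds = GenomicInterval("NC_1", min(a, b), max(a, b), strand)
    return TranscriptRecord(
        "NM_T.1",
        [GenomicInterval("NC_1", s, e, strand) for s, e in order],
        cds_span=cds,
    )


@given(transcripts())
def test_exon_intron_span_conservation(t):
    introns = gt.derive_introns(t)
    assert len(introns) == t.n_exons - 1
    assert (sum(e.length for e in t.exons) + sum(i.length for i in introns)
            == t.span.length)


@given(transcripts())
def test_utr_cds_partition_and_coding_sum(t):
    u5, c, u3 = gt.split_utrs(t)
    assert u5 + c + u3 == t.transcript_len
    assert sum(p.length for _, p, _ in gt.derive_coding_exons(t)) == c


@given(transcripts())
def test_exactly_one_last_exon(t):
    flags = gt.flag_last_exons(t)
    assert sum(flags) == 1 and flags[-1]


@given(transcripts())
def test_strand_mirror_preserves_all_lengths(t):
    """Reflecting the model through the chromosome midpoint changes no length."""
    chrom_length = t.span.end + 100
    mirrored = TranscriptRecord(
        t.accession,
        [e.mirror(chrom_length) for e in t.exons],
        cds_span=t.cds_span.mirror(chrom_length) if t.cds_span else None,
    )
    assert [e.length for e in mirrored.exons] == [e.length for e in t.exons]
    assert ([i.length for i in gt.derive_introns(mirrored)]
            == [i.length for i in gt.derive_introns(t)])
    assert gt.split_utrs(mirrored) == gt.split_utrs(t)
    assert ([p.length for _, p, _ in gt.derive_coding_exons(mirrored)]
            == [p.length for _, p, _ in gt.derive_coding_exons(t)])


@given(st.lists(st.integers(1, 10**6), min_size=1, max_size=50))
def test_mean_paths_agree(values):
    s = summarize(values)
    assert mean_from_totals(s.total, s.n, 9) == round(s.total / s.n, 9)


@given(st.integers(0, 2**31 - 1), st.data())
def test_nr_partition_property(seed, data):
    """Exactly one non-blank label per identity group, any row order."""
    rng = random.Random(seed)
    # build 1-3 genes with isoforms that reuse exon coordinates heavily
    genes = []
    for gi in range(rng.randint(1, 3)):
        base = [(i * 100 + 1, i * 100 + 50) for i in range(rng.randint(2, 5))]
        txs = []
        for j in range(rng.randint(1, 3)):
            picked = sorted(rng.sample(range(len(base)), rng.randint(1, len(base))))
            exons = [GenomicInterval(f"NC_{gi}", *base[k]) for k in picked]
            txs.append(TranscriptRecord(f"NM_{gi}_{j}.1", exons))
        genes.append(GeneRecord(f"G{gi}", f"S{gi}", "1", refseq_status="REVIEWED",
                                transcripts=txs))
    rows = []
    for g in genes:
        rows.extend(build_feature_rows(g))
    rng.shuffle(rows)
    mark_non_redundant(rows, "exon")
    groups = {}
    for r in rows:
        groups.setdefault((r.chrom_accession, r.strand, r.exon_start, r.exon_end),
                          []).append(r.nr_exon)
    for labels in groups.values():
        non_blank = [l for l in labels if l]
        assert len(non_blank) == 1


@settings(max_examples=20)
@given(st.integers(0, 10**6))
def test_curation_idempotent_and_conserving(seed):
    aset, _ = gt.generate(gt.GeneratorParams(n_genes=12, seed=seed))
    once, r1 = gt.apply_curation(aset.genes)
    twice, r2 = gt.apply_curation(once)
    assert [g.gene_id for g in twice] == [g.gene_id for g in once]
    assert r2.removed_genes == 0
    assert r1.removed_genes + r1.retained_genes == r1.input_genes
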