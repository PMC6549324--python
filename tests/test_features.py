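"""Intron/coding-exon/UTR derivation and non-redundancy labelling."""

import random

import pytest

import genetables as gt
from genetables.errors import NoCdsError, ZeroLengthIntronError
from genetables.features import (
    YES_MERGED,
    YES_UNIQUE,
    build_feature_rows,
    flag_short_introns,
    mark_non_redundant,
)
from genetables.model import GeneRecord, GenomicInterval, TranscriptRecord


def iv(s, e, strand="+", acc="NC_1"):
    return GenomicInterval(acc, s, e, strand)


class TestDeriveIntrons:
    def test_plus_strand_gaps(self):
        t = TranscriptRecord("NM_1.1", [iv(101, 200), iv(301, 400), iv(501, 600)])
        introns = gt.derive_introns(t)
        assert [(i.start, i.end) for i in introns] == [(201, 300), (401, 500)]
        assert [i.length for i in introns] == [100, 100]

    def test_mono_exonic_has_none(self):
        assert gt.derive_introns(TranscriptRecord("NM_1.1", [iv(101, 200)])) == []

    def test_minus_strand_transcription_order(self):
        t = TranscriptRecord("NM_1.1", [iv(501, 600, "-"), iv(301, 400, "-")])
        introns = gt.derive_introns(t)
        assert [(i.start, i.end) for i in introns] == [(401, 500)]

    def test_count_is_exons_minus_one(self, small_curated):
        kept, _ = small_curated
        for g in kept:
            for t in g.transcripts:
                assert len(gt.derive_introns(t)) == t.n_exons - 1

    def test_zero_gap_is_an_error(self):
        t = TranscriptRecord("NM_1.1", [iv(101, 200), iv(201, 300)])
        with pytest.raises(ZeroLengthIntronError):
            gt.derive_introns(t)


class TestDeriveCodingExons:
    def test_intersection_with_cds(self):
        t = TranscriptRecord("NM_1.1", [iv(1, 300)], cds_span=iv(101, 250))
        [(idx, part, serial)] = gt.derive_coding_exons(t)
        assert (part.start, part.end, part.length, serial) == (101, 250, 150, 1)

    def test_single_base_coding_exon(self):
        # CDS starting on the very last base of the first exon
        t = TranscriptRecord(
            "NM_1.1",
            [iv(1000, 1300), iv(2000, 2399)],
            cds_span=iv(1300, 2100),
        )
        coding = gt.derive_coding_exons(t)
        assert coding[0][1].length == 1
        assert [c[2] for c in coding] == [1, 2]

    def test_fully_untranslated_exon_skipped_but_counted_as_exon(self):
        t = TranscriptRecord(
            "NM_1.1",
            [iv(1, 100), iv(201, 300), iv(401, 500)],
            cds_span=iv(250, 450),
        )
        coding = gt.derive_coding_exons(t)
        assert [c[0] for c in coding] == [1, 2]  # exon 1 is all 5' UTR
        assert t.n_exons == 3

    def test_sum_equals_cds_length(self, small_curated):
        kept, _ = small_curated
        for g in kept:
            for t in g.transcripts:
                total = sum(p.length for _, p, _ in gt.derive_coding_exons(t))
                assert total == gt.split_utrs(t)[1]

    def test_no_cds_error(self):
        with pytest.raises(NoCdsError):
            gt.derive_coding_exons(TranscriptRecord("NR_1.1", [iv(1, 100)]))


class TestSplitUtrs:
    def _model(self, strand):
        if strand == "+":
            exons = [iv(1, 400), iv(1001, 1300), iv(2001, 2300)]
        else:
            exons = [iv(2001, 2300, "-"), iv(1001, 1300, "-"), iv(1, 400, "-")]
        # 1000-bp mRNA; CDS starts 150 bp into the mRNA, 600 bp long
        L = sum(e.length for e in exons)
        assert L == 1000
        if strand == "+":
            # mRNA pos 151 -> genomic 151 (exon 1); mRNA pos 750 ->
            # genomic 2050 (exon 3, offset 50)
            cds = iv(151, 2050)
        else:
            # in transcription order mRNA 151 -> genomic 2150 (first exon),
            # mRNA 750 -> genomic 251 (third exon, offset 150)
            cds = iv(251, 2150, "-")
        return TranscriptRecord("NM_1.1", exons, cds_span=cds)

    def test_partition_plus(self):
        assert gt.split_utrs(self._model("+")) == (150, 600, 250)

    def test_partition_minus_mirrored_is_identical(self):
        assert gt.split_utrs(self._model("-")) == (150, 600, 250)

    def test_cds_from_first_base(self):
        t = TranscriptRecord("NM_1.1", [iv(101, 400)], cds_span=iv(101, 250))
        assert gt.split_utrs(t) == (0, 150, 150)

    def test_parts_sum_to_transcript_length(self, small_curated):
        kept, _ = small_curated
        for g in kept:
            for t in g.transcripts:
                u5, c, u3 = gt.split_utrs(t)
                assert u5 + c + u3 == t.transcript_len


class TestFlagLastExons:
    def test_three_exon_plus(self):
        t = TranscriptRecord("NM_1.1", [iv(1, 10), iv(21, 30), iv(41, 50)])
        assert gt.flag_last_exons(t) == [False, False, True]

    def test_minus_strand_last_is_genomically_leftmost(self):
        t = TranscriptRecord("NM_1.1", [iv(41, 50, "-"), iv(21, 30, "-"), iv(1, 10, "-")])
        flags = gt.flag_last_exons(t)
        assert flags == [False, False, True]
        assert t.exons[flags.index(True)].start == 1

    def test_mono_exonic(self):
        assert gt.flag_last_exons(TranscriptRecord("NM_1.1", [iv(1, 10)])) == [True]


def _two_isoform_gene():
    shared = iv(101, 200)
    t1 = TranscriptRecord("NM_1.1", [shared, iv(301, 400)], cds_span=iv(150, 350))
    t2 = TranscriptRecord("NM_2.1", [shared, iv(501, 600)], cds_span=iv(150, 550))
    return GeneRecord("G1", "S1", "1", refseq_status="REVIEWED", transcripts=[t1, t2])


class TestNonRedundancy:
    def test_shared_exon_merged_once(self):
        rows = build_feature_rows(_two_isoform_gene())
        mark_non_redundant(rows, "exon")
        labels = sorted(
            r.nr_exon for r in rows if (r.exon_start, r.exon_end) == (101, 200)
        )
        assert labels == ["", YES_MERGED]

    def test_unique_exon_labelled_unique(self):
        rows = build_feature_rows(_two_isoform_gene())
        mark_non_redundant(rows, "exon")
        [row] = [r for r in rows if (r.exon_start, r.exon_end) == (301, 400)]
        assert row.nr_exon == YES_UNIQUE

    def test_labels_match_bruteforce_grouping(self, small_rows):
        for cls, f_start, f_end, f_label in [
            ("exon", "exon_start", "exon_end", "nr_exon"),
            ("coding", "coding_start", "coding_end", "nr_coding"),
            ("intron", "intron_start", "intron_end", "nr_intron"),
        ]:
            groups = {}
            for r in small_rows:
                if getattr(r, f_start) is None:
                    continue
                key = (r.chrom_accession, r.strand, getattr(r, f_start), getattr(r, f_end))
                groups.setdefault(key, []).append(r)
            for key, members in groups.items():
                labels = [getattr(r, f_label) for r in members]
                non_blank = [l for l in labels if l]
                assert len(non_blank) == 1, (cls, key)
                assert non_blank[0] == (YES_UNIQUE if len(members) == 1 else YES_MERGED)

    def test_partition_independent_of_row_order(self):
        rows = build_feature_rows(_two_isoform_gene())
        shuffled = rows[:]
        random.Random(9).shuffle(shuffled)
        mark_non_redundant(rows, "exon")
        mark_non_redundant(shuffled, "exon")
        by_key = lambda rs: {
            (r.transcript_accession, r.exon_serial): r.nr_exon for r in rs
        }
        assert by_key(rows) == by_key(shuffled)

    def test_nonredundant_counts_never_exceed_raw(self, small_rows):
        for f_start, f_label in [
            ("exon_start", "nr_exon"),
            ("coding_start", "nr_coding"),
            ("intron_start", "nr_intron"),
        ]:
            raw = [r for r in small_rows if getattr(r, f_start) is not None]
            nr = [r for r in raw if getattr(r, f_label)]
            assert len(nr) <= len(raw)


class TestShortIntrons:
    def test_26bp_intron_flagged(self, edge_rows):
        report = flag_short_introns(edge_rows)
        assert [(h.symbol, h.length) for h in report.hits] == [("INTRON26BP", 26)]
        assert report.hits[0].classification == "non-canonical-excision-candidate"

    def test_30bp_boundary_not_flagged(self, edge_rows):
        lengths = [r.intron_len for r in edge_rows
                   if r.symbol == "INTRON30BP" and r.intron_len]
        assert min(lengths) == 30
        assert not any(h.symbol == "INTRON30BP"
                       for h in flag_short_introns(edge_rows).hits)

    def test_threshold_zero_empty(self, edge_rows):
        assert flag_short_introns(edge_rows, threshold=0).hits == []

    def test_artifact_classification(self):
        # a 2-bp gap is an annotation artifact, not a splicing product
        g = GeneRecord(
            "G1", "ART", "1", refseq_status="REVIEWED",
            transcripts=[TranscriptRecord(
                "NM_1.1", [iv(1, 100), iv(103, 200)], cds_span=iv(50, 150),
            )],
        )
        rows = gt.derive_all([g])
        [hit] = flag_short_introns(rows).hits
        assert (hit.length, hit.classification) == (2, "annotation-artifact")
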