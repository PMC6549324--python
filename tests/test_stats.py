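"""Summary statistics, spreadsheet-style rounding and release deltas."""

import math

import numpy as np
import pytest

import genetables as gt
from genetables.errors import UndefinedStatisticError
from genetables.model import GeneRecord, GenomicInterval, TranscriptRecord
from genetables.stats import (
    build_report,
    compare_reports,
    mean_from_totals,
    not_last_exon_stats,
    per_chromosome_counts,
    per_transcript_count_stats,
    percent_change,
    round_half_away,
    summarize,
)


class TestSummarize:
    def test_hand_checkable_batch(self):
        s = summarize([100, 200, 300])
        assert (s.median, s.mean, s.sd, s.total) == (200, 200, 100, 600)

    def test_single_value_has_no_sd(self):
        s = summarize([7])
        assert (s.n, s.median, s.mean, s.sd, s.total) == (1, 7, 7, None, 7)

    def test_empty_marker_not_zero(self):
        s = summarize([])
        assert s.is_empty and s.total is None and s.mean is None

    def test_even_n_median_midpoint(self):
        assert summarize([1, 2, 3, 10]).median == 2.5

    def test_matches_two_pass_reference(self):
        rng = np.random.default_rng(123)
        vals = rng.integers(1, 10**6, size=1000).tolist()
        s = summarize(vals)
        # brute-force two-pass oracle
        n = len(vals)
        mean = sum(vals) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        srt = sorted(vals)
        median = (srt[n // 2 - 1] + srt[n // 2]) / 2
        assert math.isclose(s.mean, mean, rel_tol=1e-9)
        assert math.isclose(s.sd, sd, rel_tol=1e-9)
        assert math.isclose(s.median, median, rel_tol=1e-9)
        assert s.total == sum(vals) and s.min == min(vals) and s.max == max(vals)

    def test_extreme_labels_report_all_ties_sorted(self):
        s = summarize([5, 1, 1, 9], labels=["d", "b", "a", "c"])
        assert s.min_labels == ["a", "b"] and s.max_labels == ["c"]

    def test_population_sd_flag(self):
        s = summarize([1, 2, 3], population_sd=True)
        assert math.isclose(s.sd, math.sqrt(2 / 3), rel_tol=1e-12)


class TestRatios:
    @pytest.mark.parametrize(
        "total,n,decimals,expected",
        [
            (1_274_002_474, 19_116, 0, 66_646),  # mean gene length
            (19_116, 24, 0, 797),                # mean genes per chromosome
            (10, 4, 0, 3),                       # 2.5 rounds away from zero
            (174_797_813, 49_632, 0, 3_522),     # mean mRNA length
            (562_164, 49_632, 1, 11.3),          # exons per transcript
        ],
    )
    def test_mean_from_totals(self, total, n, decimals, expected):
        assert mean_from_totals(total, n, decimals) == expected

    def test_zero_count_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            mean_from_totals(10, 0)

    @pytest.mark.parametrize(
        "old,new,expected",
        [
            (53_827_863, 59_281_518, 10.1),  # non-redundant transcriptome growth
            (412_641, 562_164, 36.2),        # exon-count growth
            (100, 100, 0.0),
            (18_255, 19_116, 4.7),           # gene-count growth
        ],
    )
    def test_percent_change(self, old, new, expected):
        assert percent_change(old, new) == expected

    def test_percent_change_undefined_base(self):
        with pytest.raises(UndefinedStatisticError):
            percent_change(0, 5)

    def test_round_half_away_negative(self):
        assert round_half_away(-2.5) == -3

    def test_mean_paths_consistent(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(1, 1000, size=257).tolist()
        s = summarize(vals)
        assert mean_from_totals(s.total, s.n, 6) == pytest.approx(s.mean, abs=5e-7)


def _gene(gene_id, chrom, exon_spans, acc="NM_X.1", cds=None, symbol=None):
    ivs = [GenomicInterval(f"NC_{chrom}", s, e) for s, e in exon_spans]
    t = TranscriptRecord(acc, ivs, cds_span=(
        GenomicInterval(f"NC_{chrom}", *cds) if cds else None))
    return GeneRecord(gene_id, symbol or f"SYM{gene_id}", chrom,
                      refseq_status="REVIEWED", transcripts=[t])


class TestPerChromosome:
    def test_counts_and_extremes(self):
        genes = [_gene(str(i), "1", [(100, 200)]) for i in range(3)]
        genes.append(_gene("x", "X", [(100, 200)]))
        counts, mins, maxs = per_chromosome_counts(genes)
        assert counts == {"1": 3, "X": 1}
        assert mins == ["X"] and maxs == ["1"]

    def test_empty(self):
        assert per_chromosome_counts([]) == ({}, [], [])


class TestNotLastExon:
    def test_excludes_last_exon_lengths(self):
        g1 = _gene("1", "1", [(1, 100), (201, 1100)], cds=(50, 300))
        g2 = _gene("2", "2", [(1, 50), (201, 1100)], cds=(25, 300))
        rows = gt.derive_all([g1, g2])
        s = not_last_exon_stats(rows)
        assert s.n == 2 and s.mean == 75  # {100, 50}

    def test_mono_exonic_only_is_empty(self):
        rows = gt.derive_all([_gene("1", "1", [(1, 500)], cds=(100, 400))])
        assert not_last_exon_stats(rows).is_empty


class TestPerTranscriptCounts:
    def _genes(self):
        return [
            _gene("1", "1", [(1, 100)], cds=(10, 90)),
            _gene("2", "1", [(1, 100), (201, 300), (401, 500)], cds=(50, 450)),
            _gene("3", "1", [(i * 200 + 1, i * 200 + 100) for i in range(5)],
                  cds=(50, 850)),
        ]

    def test_exon_counts(self):
        block = per_transcript_count_stats(self._genes(), "exon")
        assert block["stats"].mean == 3.0 and block["stats"].n == 3

    def test_intron_min_excludes_mono_exonic(self):
        block = per_transcript_count_stats(self._genes(), "intron")
        assert block["stats"].min == 2  # mono-exonic transcript not counted
        assert block["stats"].mean == pytest.approx(2.0)  # zeros still included
        assert block["min_n_transcripts"] == 1 and block["min_n_genes"] == 1

    def test_all_mono_exonic_intron_min_undefined(self):
        genes = [_gene("1", "1", [(1, 100)], cds=(10, 90))]
        block = per_transcript_count_stats(genes, "intron")
        assert block["stats"].min is None


class TestReport:
    def test_hand_worked_two_gene_report(self):
        # gene A: exons 100+900 bp, genomic CDS 51..900 -> 50/750/200 split;
        # gene B: mono-exonic 300 bp, CDS 551..750 -> 50/200/50 split
        a = _gene("A", "1", [(1, 100), (201, 1100)], cds=(51, 900),
                  acc="NM_A.1", symbol="GENEA")
        b = _gene("B", "X", [(501, 800)], cds=(551, 750), acc="NM_B.1",
                  symbol="GENEB")
        genes = [a, b]
        rows = gt.derive_all(genes)
        rep = build_report(genes, rows)
        flat = rep.flatten()
        assert flat["genes.n"] == 2
        assert flat["genes.length.total"] == 1100 + 300
        assert flat["mrnas.n"] == 2
        assert flat["mrnas.length.total"] == 1000 + 300
        # feature conservation: exon total length equals mRNA total length
        assert flat["features.exon.raw.length.total"] == flat["mrnas.length.total"]
        assert flat["features.intron.raw.n"] == 1
        assert flat["features.intron.raw.length.total"] == 100
        assert flat["mrnas.utr5.total"] == 50 + 50
        assert flat["mrnas.cds.total"] == 750 + 200
        assert flat["mrnas.utr3.total"] == 200 + 50
        assert flat["genes.mean_per_chromosome"] == pytest.approx(2 / 24)
        assert rep.genes["per_chromosome"] == {"1": 1, "X": 1}

    def test_totals_conserved_on_synthetic_set(self, small_curated, small_rows):
        kept, _ = small_curated
        flat = build_report(kept, small_rows).flatten()
        assert flat["features.exon.raw.length.total"] == flat["mrnas.length.total"]
        assert (flat["mrnas.utr5.total"] + flat["mrnas.cds.total"]
                + flat["mrnas.utr3.total"]) == flat["mrnas.length.total"]
        for cls in ("exon", "coding", "intron"):
            assert (flat[f"features.{cls}.non_redundant.n"]
                    <= flat[f"features.{cls}.raw.n"])
            assert (flat[f"features.{cls}.non_redundant.length.total"]
                    <= flat[f"features.{cls}.raw.length.total"])

    def test_compare_report_with_itself_is_all_zero(self, small_curated, small_rows):
        kept, _ = small_curated
        rep = build_report(kept, small_rows)
        cmp = compare_reports(rep, rep)
        assert cmp["missing_in_old"] == [] and cmp["missing_in_new"] == []
        assert all(d.delta in (0, None) for d in cmp["deltas"])

    def test_compare_detects_gene_count_growth(self):
        old = gt.StatsReport(genes={"n": 18_255}, mrnas={}, features={})
        new = gt.StatsReport(genes={"n": 19_116}, mrnas={}, features={})
        [delta] = compare_reports(old, new)["deltas"]
        assert (delta.delta, delta.percent) == (861, 4.7)

    def test_render_text_contains_key_blocks(self, small_curated, small_rows):
        kept, _ = small_curated
        text = build_report(kept, small_rows).render_text()
        for heading in ("== Genes ==", "== mRNAs ==", "== Exons ==",
                        "== Coding exons ==", "== Introns =="):
            assert heading in text
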