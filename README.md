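# genetables

Feature tables and descriptive statistics for curated protein-coding
gene models.

Genome annotation is usually distributed as hierarchical records
(gene → mRNA → exon/CDS), which makes even simple quantitative
questions — median intron length, non-redundant exome size, how a
release changed — awkward to answer. `genetables` is for people who
want those numbers reproducibly: it reads GFF3/GTF (or its own
three-table TSV dialect), applies an explicit curation policy, derives
a per-exon feature table and computes the full battery of summary
statistics, comparable across annotation releases.

## What it computes

For each transcript with exons $e_1,\dots,e_n$ in transcription order
(1-based inclusive genomic coordinates, lengths $|e| = end-start+1$):

* introns $i_1,\dots,i_{n-1}$, each filling the genomic gap between
  consecutive exons and stored as companion of its upstream exon;
* the coding portion of each exon, $e_k \cap \mathrm{CDS}$, with the
  stop codon inside the CDS; and the mRNA partition
  $\mathrm{UTR5}+\mathrm{CDS}+\mathrm{UTR3}=\sum_k |e_k|$;
* last-exon flags and non-redundancy labels: identical-coordinate
  features shared by isoforms are collapsed to a single labelled
  representative (`Yes—Unique` / `Yes—Merged`), so filtering on a
  non-blank label yields the non-redundant exon/coding-exon/intron
  sets;
* per batch of lengths or counts: n, median, mean, sample SD, min,
  max (with labelled ties) and total, plus release-over-release
  percent changes $100\,(new-old)/old$, all with spreadsheet-style
  half-away-from-zero rounding at display time.

The default curation policy keeps nuclear protein-coding genes with a
REVIEWED/VALIDATED RefSeq status at gene level and at least one
REVIEWED/VALIDATED `NM_` transcript, excluding records not in the
current annotation release; removals are counted per rule in a fixed
order. Sub-30-bp introns are flagged for review (splicing cannot
produce them; they are annotation artifacts or non-canonical
excisions), never silently dropped.

A seeded synthetic-data generator emits realistic multi-isoform gene
models together with independently tallied ground truth for every
report cell, so the entire pipeline is testable without downloads.

## Worked example

```python
import genetables as gt

aset, truth = gt.generate(gt.GeneratorParams(n_genes=200, seed=7))
kept, rep = gt.apply_curation(aset.genes)
print("retained:", len(kept), "of", aset.n_genes, rep.removed_by_rule)

rows = gt.derive_all(kept)            # per-exon rows with NR labels
report = gt.build_report(kept, rows)
print(report.render_text())
```

prints (abridged):

```
retained: 162 of 200 {'gene_type': 10, 'gene_status': 7, 'not_current': 8,
                      'chromosome': 4, 'no_passing_transcript': 9}
== Genes ==
  Total entries: 162
  Mean per chromosome (/24): 7
  Length (bp): n=162 median=24,134 mean=47,735 sd=58,965 ... total=7,733,142
== mRNAs ==
  Total entries: 337
  Length (bp): n=337 median=1,947 mean=2,504 ... total=843,730
== Exons ==
  Total entries: 4,009
  Total non-redundant entries: 1,888
  Per transcript: n=337 median=9.0 mean=11.9 ...
  Length (bp): n=4,009 median=134 mean=210 ... total=843,730
...
```

The 162 retained genes are the 200 minus the generator's planted
contaminants (10 non-protein-coding, 7 computational-status, 8
non-current, 4 mitochondrial, 9 with only model-predicted
transcripts). Exon total length (843,730 bp) equals the mRNA total —
a conservation law the test suite asserts — and every one of these
cells equals the generator's independently computed ground truth
(`truth.cells`).

The same pipeline runs from the shell:

```sh
genetables simulate --seed 7 --n-genes 200 --out-dir sim/
genetables derive    sim/synthetic.gff3 --out-dir tables/   # 3 TSV tables
genetables summarize sim/synthetic.gff3 --out report.json
genetables compare   old_report.json report.json --out delta.json
```

Column inventories of the three tables (`Genes.tsv`,
`Transcripts.tsv`, `Gene_Table.tsv`) are documented in
[docs/data_dictionary.md](docs/data_dictionary.md); the modelling
choices in [docs/methods.md](docs/methods.md).

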