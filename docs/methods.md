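# Methods

## The problem

Genome browsers expose human gene annotation as records, not as a
searchable, computable table. For questions like "what is the median
intron length in curated protein-coding genes?" or "how did the
non-redundant exome change between releases?", one needs the gene
models flattened into per-feature rows with consistent coordinate
arithmetic, a reproducible curation policy, and spreadsheet-grade
descriptive statistics. `genetables` implements that pipeline:
annotation in (GFF3/GTF or its own three-table dialect), curated
per-exon feature table and a full statistics report out.

## Data model and coordinate conventions

All coordinates are 1-based and inclusive at both ends (the NCBI
Gene / GFF3 convention), so every length is `end − start + 1`.
Intervals are stored genomically (`start ≤ end`) on both strands;
transcription order is carried by list position and serial numbers.
On the minus strand the first exon is the genomically right-most one,
and "upstream"/"downstream" always refer to the 5′→3′ direction of
the mRNA. Gene models spanning multiple chromosomes or strands
(trans-splicing) are rejected with a specific error rather than
silently split; they are outside this data model.

The CDS span is the genomic interval from the first base of the start
codon through the last base of the stop codon — the stop codon is
*inside* the CDS everywhere in this package. GTF input that annotates
`stop_codon` features separately is merged on read; GFF3 CDS features
are assumed stop-inclusive unless the reader is told otherwise.

Chromosome names are text throughout ("1".."22", "X", "Y", "MT").

## Curation policy

The default policy keeps genes that are (in this fixed test order):
protein-coding; REVIEWED or VALIDATED at gene level; part of the
current annotation release; nuclear (chromosome not in {MT}); and
carrying at least one transcript that is REVIEWED or VALIDATED *and*
has an `NM_` accession (curated mRNA, as opposed to `XM_` model
predictions). Kept genes retain only their passing transcripts. A
gene failing several rules is counted once, at the first failing
rule, so removal accounting is deterministic; a status of NA (no
annotation) fails the status tests — curation is conservative.

## Feature derivation

Per transcript, in transcription order:

* **Introns**: exactly `n_exons − 1`, filling the genomic gaps
  between consecutive exons. Directly adjacent exons (zero gap) are
  an annotation defect and raise an error. Each intron is stored on
  the row of its upstream exon (companion layout), so last-exon rows
  carry no intron fields.
* **Coding exon portions**: each exon's intersection with the CDS
  span; exons wholly inside a UTR contribute nothing but keep their
  exon serial. Coding serials count coding exons 1, 2, … along the
  mRNA. The portion lengths always sum to the CDS length.
* **UTR/CDS split**: the mRNA partitions into
  `utr5 + cds + utr3 = transcript length`, with 5′/3′ assigned by
  strand.
* **Last-exon flags**: exactly one exon per transcript (the 3′-most);
  the analogous coding flag marks the highest coding serial.

**Non-redundancy.** Isoforms of a gene frequently share exons; for
"how many distinct exons/introns exist" questions each group of
identical features must be counted once. Identity is exact
coordinate equality of (chromosome accession, strand, start, end),
scoped per feature class — partially overlapping features are
distinct elements, since fuzzy merging would change totals
unpredictably. Within each identity group exactly one representative
row is labelled: `Yes—Unique` for singletons, `Yes—Merged` for
duplicated groups, all other members blank. The representative is
the first row under the deterministic sort (gene id, transcript
accession, serial); the choice of representative is a tie-break the
underlying data do not determine, fixed here for reproducibility.
Coding portions are collapsed by *coding-portion* coordinates, not by
host-exon coordinates, because two isoforms can share an exon while
differing in where the CDS starts inside it.

**Short introns.** The spliceosome cannot excise introns below
roughly 30 bp, so anything shorter is either an annotation artifact
or a segment removed by a non-spliceosomal mechanism (the classic
example being the 26-nt segment excised from XBP1 mRNA by the IRE1
endonuclease). `flag_short_introns` lists non-redundant introns
strictly below the threshold (default 30 bp) for manual review,
classifying 1–3 bp cases as annotation artifacts; nothing is removed
automatically, so printed totals keep their plain meaning.

## Statistics

`summarize` reports n, median (midpoint rule for even n), mean, SD,
min, max and total. SD is the *sample* standard deviation (n−1
denominator, the spreadsheet STDEV default); population SD is
available behind a flag. An empty batch yields an explicit
empty-stats marker, never zeros. Extremes carry feature labels with
all ties reported, sorted.

Display rounding is half-away-from-zero (spreadsheet ROUND): lengths
to integer bp, per-transcript counts and percent changes to one
decimal. `mean_from_totals` and `percent_change` do their division
in decimal arithmetic so results match a spreadsheet ROUND of the
same ratio exactly. Report cells are stored unrounded; rounding
happens only at rendering.

Specific conventions:

* mean genes per chromosome divides by a fixed 24 (22 autosomes +
  X + Y) regardless of which chromosomes are present in the set;
* "not last" length statistics exclude rows of each transcript's
  last exon, which is usually the longest (it carries the 3′ UTR);
* intron counts per transcript include zeros from mono-exonic
  transcripts in median/mean/SD, but the *minimum* is taken excluding
  mono-exonic transcripts (which trivially have none), with the
  number of transcripts and genes at the minimum reported alongside;
* `compare_reports` emits old, new, absolute and percent change per
  metric; metrics present on one side only are listed as missing,
  never errors.

## Synthetic data and what passing tests show

The generator builds, per gene, a master exon/intron chain and then
isoforms as sub-ranges of that chain, occasionally trimming terminal
exon boundaries so some coordinates are isoform-unique while internal
exons are shared — exactly the structure the non-redundancy collapse
must handle. Defaults emulate the curated human protein-coding set:
log-normal exon lengths (median 131 bp) and intron lengths (median
1747 bp, floor 30 bp), truncated-geometric exon counts calibrated to
a per-transcript median of ~9, ~2.6 isoforms per gene, half the genes
on the minus strand, 5% mono-exonic, a REVIEWED/VALIDATED status mix,
and ~22% contaminant genes (non-protein-coding, computational-status,
mitochondrial, non-current, or XM_-only) each violating exactly one
curation rule, plus occasional XM_ transcripts inside clean genes.
The distribution families are pragmatic choices to hit those medians,
not claims about biology.

Ground truth is tallied at emission time from the generator's own
mRNA-coordinate bookkeeping, using the standard library's
`statistics` module — a fully independent route from the pipeline's
genomic re-derivation (numpy-based). The central recovery test runs
the whole pipeline on generated sets (5 seeds × 200 genes; ~0.5 s per
seed on one core) and requires every integer cell to match exactly
and every real cell to 1e-9 relative, and the curation report to
match the generator's contaminant accounting.

What this does *not* show: the generator produces clean hierarchies
only (no orphan records except where tests construct them), no
overlapping genes sharing exons across gene ids, no trans-splicing,
no UTR introns-vs-CDS subtleties beyond exact intersection, and no
realistic chromosome-level gene density. Conclusions about messy
real-world annotation files rest on the reader's strict/lenient error
handling tests, not on the generator. Headline published totals for
the 2019 human set (19,116 genes; 562,164 exons; …) depend on that
specific release snapshot and are exercised through ratio
reproduction, not recomputation.

A separate committed fixture builder covers the boundary shapes the
human set is known to contain: a 2-bp internal exon, a 1-bp coding
exon (CDS starting on the last base of an exon), a 26-bp intron
(flagged) beside a 30-bp intron (not flagged), a mono-exonic gene and
a 363-exon transcript.

## Numerical and degenerate-input choices

* Interval construction rejects `start > end`; transcripts reject
  overlapping or mis-ordered exons at construction, while the
  zero-gap (absent intron) case is reported by `derive_introns` as
  its own error.
* Empty annotation input produces header-only tables and an empty
  report, exit code 0 in the CLI.
* Table reading verifies every stated length against its coordinates
  and re-derives introns/coding portions from the reconstructed
  exons, refusing tables that contradict themselves.
* TSV output is byte-deterministic (fixed column order, `\n`
  newlines, empty cells for absent values); write→read→write is
  byte-identical.

## Known limitations

* Non-coding transcripts are carried through I/O and derivation
  (empty UTR/CDS fields) but the default curation policy excludes
  them by accession prefix.
* The `.xlsx` convenience export writes values only; no spreadsheet
  formatting or formula fidelity.
* Percent change is undefined for a non-positive base and raises; the
  release comparison reports such metrics with a null percent instead
  when comparing whole reports.
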