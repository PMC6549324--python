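# Data dictionary: the three-table export

All three tables are TSV (UTF-8, Unix newlines) with the column names
in the first row. Chromosome columns are always text ("1".."22", "X",
"Y", "MT") so sex chromosomes are never misread as numbers by
spreadsheet tools. Absent optional values are empty cells, never 0.
Coordinates are 1-based and inclusive at both ends; all lengths are
`end − start + 1` bp.

The column *order* below is fixed by this package; no byte-level
compatibility with any third-party spreadsheet export is claimed.

## Genes.tsv — one row per gene

| column | meaning |
|---|---|
| GeneID | gene identifier |
| Gene_Symbol | official gene symbol |
| Chromosome | chromosome name, text |
| Gene_Type | `protein-coding` or the source biotype verbatim |
| Gene_RefSeq_Status | REVIEWED / VALIDATED / MODEL / PROVISIONAL / INFERRED / PREDICTED / NA |
| Transcript_RefSeq_Statuses | `;`-joined distinct statuses of the gene's retained transcripts |
| Gene_Length_bp | span length from lowest to highest annotated coordinate |

## Transcripts.tsv — one row per mRNA

| column | meaning |
|---|---|
| GeneID, Gene_Symbol, Chromosome, Gene_Type, Gene_RefSeq_Status | as above |
| Transcript_Accession | mRNA accession (e.g. `NM_...`) |
| Transcript_RefSeq_Status | per-transcript curation status |
| Transcript_Length_bp | sum of exon lengths |
| UTR5_Length_bp | 5′ untranslated length in mRNA coordinates |
| CDS_Length_bp | coding-sequence length, stop codon included |
| UTR3_Length_bp | 3′ untranslated length |
| Exons_per_RNA | number of exons |
| Coding_Exons_per_RNA | number of exons intersecting the CDS |

`UTR5 + CDS + UTR3 = Transcript_Length` always holds; non-coding
transcripts have empty UTR/CDS cells and `Coding_Exons_per_RNA = 0`.

## Gene_Table.tsv — one row per (transcript, exon)

Intron data are companions of their upstream exon (in transcription
order), so rows with `Last_Exon = Yes` have empty intron columns.

| column | meaning |
|---|---|
| GeneID, Gene_Symbol, Gene_Type, Chromosome | gene identity |
| Chromosome_Accession | sequence accession the coordinates refer to |
| Strand | `+` or `-` |
| Gene_Start, Gene_End, Gene_Length_bp | gene span |
| Transcript_Accession, Transcript_RefSeq_Status, Transcript_Length_bp | transcript identity |
| CDS_Start, CDS_End | genomic span of the CDS, stop codon included |
| UTR5_Length_bp, CDS_Length_bp, UTR3_Length_bp | the mRNA partition |
| Exon_Start, Exon_End, Exon_Length_bp, Exon_Serial | this exon; serials count 1,2,… in transcription order |
| Coding_Start, Coding_End, Coding_Length_bp, Coding_Serial | the exon's intersection with the CDS, if any |
| Intron_Start, Intron_End, Intron_Length_bp, Intron_Serial | companion intron (gap to the next exon), absent on last exons |
| Last_Exon | `Yes` on each transcript's 3′-most exon |
| Last_Coding_Exon | `Yes` on the exon carrying the highest coding serial |
| Non_Redundant_Exon, Non_Redundant_Coding_Exon, Non_Redundant_Intron | `Yes—Unique` (feature occurs once in the data set), `Yes—Merged` (representative of a group of identical-coordinate features shared by isoforms), or blank (non-representative duplicate). Filtering on a non-blank value yields the non-redundant feature set. |
| Protein_Accession | protein product accession |
| Live_Status | `live` or `dead` |
| Genome_Annotation_Status | `current` or `not in current annotation release` |
| Gene_RefSeq_Status | gene-level curation status |
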