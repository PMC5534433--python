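# File formats and coordinate conventions

All coordinates written or read by this package are **0-based,
half-open, transcript-space**.  Nucleotide positions index the mature
transcript; codon index `k` of an ORF covers nucleotides
`[cds_start + 3k, cds_start + 3k + 3)`.

## Transcriptome FASTA

Plain FASTA, one record per transcript, DNA alphabet (U is normalized
to T on input).  Record ids are the transcript ids used everywhere else.

## ORF table (`orfs.tsv`)

TSV with header: `transcript_id  cds_start  cds_length_nt`.
`cds_start` is the 0-based nt offset of the first CDS base;
`cds_length_nt` is a multiple of 3 (no requirement that a stop codon is
included).

## Raw reads (FASTQ)

Standard 4-line FASTQ.  Simulated reads are laid out as
`insert + UMI + multiplex barcode + constant linker`, clipped to the
configured read length; qualities are constant Phred-33 `I`.

## Alignment table (`alignments.tsv`)

TSV with header: `transcript_id  pos5_0based  length  umi`.  One row
per aligned footprint (duplicates included); `pos5_0based` is the 5'
end on the transcript, `length` the footprint length in nt.

## SAM (read-only, plus simulator output)

Transcriptome-space SAM: `@SQ` lines name transcripts, alignments are
forward-strand perfect matches (`<length>M`).  The simulator encodes
the UMI as a `_<umi>` suffix on the query name; the reader recovers it
from there.  Only primary mapped records are consumed.

## Footprint table (`footprints.tsv`)

Output of preprocessing: `transcript_id  pos5  length  umi  length_class`
with `length_class` in `{short, long}` (20-22 / 27-29 nt).

## A-site calls (`asite_calls.tsv`)

Footprint table plus `a_codon`, `p_codon` (0-based codon indices within
the CDS; `p_codon = a_codon - 1`) and `in_cds` (boolean).  Out-of-CDS
calls are retained with `in_cds = False` and ignored by counting.

## Pause scores (`pause_scores.tsv`)

`transcript_id  codon_index  length_class  count  score` for interior
codons (indices `[5, codon_count - 5)`) of ORFs passing the density
filter.

## Di-codon table (`dicodon_scores.tsv`)

`p_codon  a_codon  length_class  n  mean  sd  low_n` — occurrence
count, mean and standard deviation of the A-site pause score over all
occurrences of the (P, A) pair in retained ORFs; `low_n` flags pairs
below the minimum-occurrence threshold.  Absent pairs are not
zero-filled.

## Polybasic tracts (`polybasic_tracts.tsv`)

`transcript_id  start_codon_index  kr_count_in_window` — the start is
the first residue of the first qualifying >=6-K/R-in-10 window of a
merged run.

## Metagene profile (`metagene.tsv`)

`length_class  rel_position  mean  n` — position relative to tract
start in codons (-W..+W), mean normalized density, number of
contributing tracts.  Positions with no contributing tract carry NaN.

## Reporter segments sidecar (`segments.tsv`)

`segment_name  start_codon  end_codon` — 0-based half-open codon
intervals within the reporter CDS, non-overlapping, ordered
upstream < insert < downstream.

## Run report (`report.json`)

JSON with `version`, `parameters` (every stage parameter of the run)
and `counts` (per-stage read/ORF tallies).  No timestamps, so repeated
runs of one configuration are byte-identical apart from the output
directory recorded in `parameters`.
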