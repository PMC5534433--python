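# Methods

## Background and model

Ribosome profiling recovers ribosome-protected mRNA fragments whose
length reflects the conformational state of the ribosome: 20-22 nt
footprints arise from ribosomes in the rotated (hybrid-tRNA) state and
27-29 nt footprints from the classical, non-rotated state.  Ribosomes
stalled in the rotated state at particular (P-site, A-site) codon pairs
are the substrates recognized by ribosome-associated quality control
(RQC), so the analytical task is to locate and quantify codon-pair
specific accumulation of the *short* footprint class, separately from
the *long* class.

The package implements that analysis as a pipeline over
transcript-space alignments:

1. **Preprocessing.**  Raw reads are trimmed of the ligated linker; the
   random barcode (UMI) adjacent to the insert is recovered; PCR
   duplicates are collapsed on the key (transcript, 5' position,
   length, UMI); reads are restricted to the two analyzed length
   classes, 20-22 nt (short) and 27-29 nt (long).
2. **A-site assignment.**  Each footprint's A-site is a fixed,
   length-specific offset from its 5' end: 16 nt for 22 and 29 nt
   reads, 15 nt for 20, 21 and 28 nt reads, 14 nt for 27 nt reads.
   The codon index is the floor of the offset position relative to the
   CDS start divided by 3.
3. **Pause scores.**  For each ORF and length class, the per-codon
   A-site counts are divided by the ORF's mean interior density — the
   mean over all codons excluding the first and last five.  ORFs with
   interior mean density below 0.5 footprints/codon are excluded
   (the boundary value is retained).
4. **Di-codon statistics.**  Every interior codon position i with
   i >= 1 is an occurrence of the pair (codon[i-1], codon[i]) at the
   (P, A) sites and is attributed the A-site codon's pause score.  The
   per-pair, per-class table averages occurrences unweighted across all
   retained ORFs; pairs are ranked by mean score with deterministic
   tie-breaking (occurrence count, then lexicographic pair).
5. **Polybasic metagene.**  A polybasic tract is >= 6 lysine/arginine
   residues in a 10-residue window; runs of overlapping qualifying
   windows merge into one tract anchored at the first qualifying
   window's start.  Per tract, the host ORF's normalized density
   (counts / interior mean) is extracted over a symmetric window around
   the tract start and averaged position-wise across tracts, per class.
6. **Reporter readthrough.**  A reporter transcript (upstream ORF —
   arrest insert — downstream ORF, e.g. GFP-R(CGA)12-FLAG-HIS3) is
   analyzed like any transcript; the readthrough index is the mean
   density of the downstream segment over that of the upstream segment,
   excluding five codons at each segment boundary.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| length classes | 20-22 / 27-29 nt | rotated / classical footprints; other lengths dropped |
| A-site offsets | 22,29→16; 20,21,28→15; 27→14 nt | 5' end to first nt of A-site codon |
| edge exclusion | 5 codons | per ORF end, excluded from density, scores and occurrences |
| density filter | ≥ 0.5 footprints/codon | inclusive, on the class-specific interior mean |
| di-codon min. occurrences | 5 | pairs below are flagged and not ranked |
| polybasic rule | ≥ 6 K/R in 10 aa | tract definition |
| metagene window | ±25 codons | tracts closer than this to the interior edge are dropped |
| boundary flank | 5 codons | excluded from reporter segment means |
| UMI length | 7 nt | the random-barcode portion of the linker/RT layout |

The offset table, filters and windows are all overridable through the
pipeline configuration; defaults are the published calibration.

## Design choices where the procedure was open

- **Class-specific denominators.**  Density, the 0.5 filter and pause
  scores are computed per length class independently (the short
  analysis sees only short reads), because the two classes report
  different conformations and a shared denominator would mix them.  A
  combined-class denominator is available via `combined_class_density`.
- **Dedup before length restriction.**  The UMI collapse applies to all
  aligned reads, then the length filter; the opposite order is exposed
  via `dedup_before_length_filter: false`.  On libraries whose lengths
  are all analyzable the two orders coincide (tested).
- **Dedup key includes length**, distinguishing nested reads with a
  shared 5' end, since length carries conformational information here.
  Multimapping reads (exact-match test mapper only) are discarded and
  counted.
- **A-site convention.**  The offset points at the first nucleotide of
  the A-site codon and the codon index is obtained by floor division;
  no sub-codon frame correction is applied, since the analysis claims
  codon resolution only.  A read whose A-site is codon 0 has no P-site
  and is excluded from di-codon statistics.
- **Di-codon attribution.**  An occurrence is scored by the A-site
  codon's pause score (not the P/A mean), and averaging is unweighted
  across occurrences rather than read-weighted or per-gene.
- **Metagene normalization.**  Per-tract normalization by the host
  ORF's interior mean precedes averaging, preventing high-coverage
  genes from dominating the profile; the window is ±25 codons.
- **Zero counts.**  No pseudocounts anywhere; a zero-count interior
  codon scores 0, and di-codon pairs with no occurrences are absent
  from the table rather than zero-filled.

## Synthetic data generator

The generator emulates the features of the real libraries that the
pipeline depends on: transcript-space ORFs with UTRs; two footprint
classes mixed at a configurable fraction with a length distribution
over {20,21,22,27,28,29}; per-read 5' ends back-computed from a sampled
A-site codon by inverting the offset table; a ligated tail of
UMI + multiplex barcode + constant linker on each raw read; and an
injected fraction of exact PCR duplicates.  Dwell positions are drawn
over interior codons with weight 1, multiplied by the class
fold-enrichment of any stalling structure at that codon:

- pair-driven stalls (every sequence occurrence of a (P, A) pair, with
  a configurable number of occurrences planted explicitly),
- site-driven stalls at exact (transcript, codon) positions, and
- attenuators, which multiply all weights downstream of a boundary
  codon by a readthrough probability (emulating ribosome loss at an
  arrest sequence).

Everything planted is recorded (`SyntheticTranscriptome`,
`SimulationTruth`) so downstream estimates can be checked against
ground truth.  UMIs are resampled on accidental key collision, so with
`duplicate_fraction = 0` every dedup key is unique and deduplication is
exactly the identity.

What the generator does **not** model: sequencing errors and
quality-score structure, UMI collision statistics, genome-space
alignment and splicing, library-preparation sequence biases
(ligation/RNase preferences), codon-usage-dependent background dwell
variation, and translation dynamics such as ribosome queuing upstream
of stalls.  Passing tests therefore demonstrate that the pipeline's
statistics are correct and its parameters recoverable under clean,
known-truth conditions — not that the biological findings would
reproduce from noisy real libraries.

## Numerical and scale choices

Recovery checks run at sizes chosen to keep the whole suite fast while
leaving clear statistical margins: di-codon parameter recovery uses 24
transcripts of 600-800 codons at 4 reads/codon (2 per class) over three
seeds, where the planted fold-enrichments {2, 10, 50} are re-estimated
within 15% relative error and the 50× pair ranks first; the metagene
check uses 30 tract-bearing transcripts of 150-200 codons at 6
reads/codon.  The mean di-codon pause score is a mildly biased
estimator of an injected fold: the stall's own reads inflate the
interior-mean denominator by roughly (E−1)/L for one planted site of
enrichment E in an ORF with L interior codons, which is why recovery
conditions use long ORFs with one planted occurrence per ORF per pair.
Ties in rankings and argmax peak reports are deterministic (stable
sorts; tied peaks reported as sets).  Degenerate inputs are explicit
outcomes, not crashes: ORFs with ≤10 codons have no interior and are
excluded with a report; profiles with zero interior density cannot be
scored and are filtered; zero upstream reporter density flags the
readthrough index undefined (`None`) rather than dividing by zero.

## Known limitations

- Offsets are fixed constants; data-driven offset calibration (e.g.
  from start-codon metagenes) is not implemented.
- No statistical testing of pause-score differences between classes,
  and no cross-library normalization.
- The built-in exact-match mapper is test plumbing (full-length perfect
  match, multimappers dropped); real data should arrive as
  transcriptome-space SAM or the tabular alignment format.
- The readthrough index quantifies a contrast the source analysis
  reported qualitatively; there is no published reference value for it.
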