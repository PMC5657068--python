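# Methods

## Coordinate model

Everything is computed on an ORF-centric transcriptome: one sequence per
gene consisting of a fixed-width 5′ buffer, the CDS (ATG through stop
codon, length divisible by 3), and a fixed-width 3′ buffer. Internal
coordinates are 0-based half-open on the transcript; GFF3 input
(1-based inclusive) is converted once at parse time, which removes ±1
ambiguity from every downstream positional statistic. Genes whose CDS
length is not divisible by 3 are excluded (not truncated): frame
statistics are meaningless on them. A non-ATG start codon is a warning,
not an error, since real annotations contain exceptions.

The buffers stand in for UTRs in the sequence features (UTR GC content,
upstream ATG count); upstream ATGs are counted at overlapping matches in
all three frames within the 5′ buffer, the conservative superset of any
frame-restricted definition. The buffer width is a free parameter of the
reference (default 25 nt in the generator), not a biological claim.

## Read preparation

* **Adapter trimming.** Scanning 5′→3′, the first read position whose
  remaining suffix matches a prefix of the adapter (overlap ≥
  `min_overlap`, default 5; mismatch fraction ≤ `max_mismatch_rate`,
  default 0.1) is the cut point; everything 3′ of it is removed. A full
  internal adapter occurrence is the special case of a whole-adapter
  overlap. Leftmost-first scanning makes ties impossible.
* **Length window.** Default [15, 50] nt; footprint preset [25, 35].
  The footprint mode of ~30 nt motivates the preset; the wide default
  keeps over-trimmed reads (inserts whose 3′ end resembles an adapter
  prefix, ~1/4^5 of reads) in play.
* **rRNA filtering** is exact k-mer membership (default k = 15) against
  the contaminant set, sense strand only (footprint libraries are
  strand-specific). Mismatch-tolerant contaminant removal is out of
  scope.
* **Alignment.** The built-in aligner places a read only if it occurs
  exactly once as an exact sense-strand substring across all transcripts
  (seed-and-verify on a 15-mer index; exhaustive for reads ≥ 15 nt, with
  a naive-scan fallback below that). Zero occurrences → unaligned; two
  or more anywhere → multimapped and discarded, the least-assumption
  policy and the one the frame statistics need. Real datasets should be
  aligned externally (mismatch-tolerant) and ingested as SAM/BAM: primary,
  mapped, forward-strand, unclipped records are kept (clipping is
  rejected so that the leftmost coordinate always means the sequenced 5′
  terminus); reverse-strand and clipped records are tallied with the
  unaligned; secondary/supplementary records are skipped without
  counting since they duplicate an already-counted read.
* **Accounting.** `n_input = n_too_short + n_rrna_removed + n_unaligned
  + n_multimapped + n_accepted` is asserted on every run.

## The count store

Per gene, accepted alignments are tallied into an integer matrix indexed
by (read length, 5′-end position). Counts are deliberately keyed by the
5′ end rather than the A-site: offset rules vary across studies, so the
store stays rule-agnostic and A-site shifting (`a = x + δ(l)`) is a
cheap downstream view. The packaged default offset table is 15 nt for
28–30-mers (the common yeast convention) and is fully user-overridable;
reads whose length has no offset are skipped and counted, never guessed.
HDF5 layout: one group per gene under the dataset id, gzip-chunked whole
matrices, per-gene coordinate attributes, a schema_version (readers
refuse unknown majors), and the config snapshot as JSON. TSV exports
(one file per gene plus a summary) re-import to identical matrices.

## QC statistics

* **Frame** is defined on 5′-end positions inside the ORF, not A-sites,
  so the diagnostic does not depend on the offset table it helps
  calibrate. Translating footprints concentrate in frame 0 at the
  library's frame fidelity; RNA-seq is uniform.
* **Periodicity.** The primitive takes any positional count profile,
  mean-subtracts it, and evaluates discrete Fourier power at candidate
  periods (default 2–10 nt); the dominant period is the argmax if its
  power is ≥ 2× the mean candidate power, ties toward the smaller
  period (a delta comb of period 4 genuinely ties with its 2-nt
  harmonic). At dataset level, spectra are computed per gene on
  mean-subtracted ORF profiles, normalised by each gene's mean candidate
  power, and averaged with equal gene weight (a Welch-style averaged
  periodogram). This choice matters: a single profile pooled across
  genes of different lengths carries a coverage staircase (distal
  positions are covered by fewer genes) whose low-frequency power can
  exceed the 2× threshold on perfectly aperiodic data, while gene
  averaging concentrates the noise spectrum near 1 and leaves the
  footprint/RNA-seq contrast unambiguous.
* **Metagene profiles** mean-normalise each eligible gene's window
  (total reads ≥ `min_reads`, default 64; window inside the transcript)
  and average genes with equal weight, so high-coverage genes do not
  dominate the shape. For the stop anchor the orchestration mirrors the
  window (long arm upstream into the ORF) because the 3′ buffer bounds
  the downstream arm. With a 15-nt offset, the initiation peak appears
  at position −15 relative to the start codon in 5′-end coordinates.
* **Positional distribution** bins each read's relative ORF position
  (clipped to [0, 1)) into `n_bins` (default 50) equal bins using exact
  integer arithmetic at the edges, normalises per gene, and averages.
* **Nucleotide frequencies** per read position flag library-preparation
  biases. Note the exact aligner drops reads whose biased base no longer
  matches the transcript, so bias is best measured on alignments from a
  mismatch-tolerant aligner (or, in the test harness, on truth-table
  alignments).

## Quantification

ORF membership of a read uses its 5′-end position, consistent with the
store and independent of the offset table. RPKM follows the invariant
`1e9 · count / (total · orf_length_nt)`; it is invariant under uniform
count scaling and halves under ORF-length doubling. Feature correlations
use Spearman's rank coefficient (pairwise-complete, average ranks for
ties) because the features span orders of magnitude and rank correlation
is monotone-invariant; missing features are reported with their n, never
imputed. Relative abundance is log₂ of the gene's RPKM over the median
(robust, not mean) across a reference panel, with a pseudo-RPKM floor
(0.01) applied — and flagged — only when the numerator is zero.

## Synthetic data

The generator emulates exactly the structure the QC suite assumes:

* transcripts with ATG starts, 61-sense-codon bodies (internal in-frame
  stops impossible by construction), random stop codons, fixed 25-nt
  buffers; ORF lengths uniform over 80–500 codons;
* per-gene abundances lognormal (σ = 1), normalised;
* footprints: the A-site codon is drawn with start/stop peak weights
  (defaults 5 and 3, emulating initiation/termination accumulation);
  with probability `frame_fidelity` (default 0.9) the 5′ end is placed
  at codon start − 15 nt, otherwise jittered ±1 nt; lengths are drawn
  from a distribution with mode 30 nt over 28–32
  ({28: 0.1, 29: 0.2, 30: 0.4, 31: 0.2, 32: 0.1}), matching the ~30-nt
  protected fragment;
* optional per-read-position base bias (specified bases get their stated
  probabilities, the remainder spread uniformly — so the recovered
  frequency equals the stated probability in expectation), adapter
  appending, and rRNA contamination by verbatim substrings;
* RNA-seq-like reads: uniform positions, same length profile, no frame
  structure — the no-periodicity control;
* a truth table records origin, gene, position, length, frame, and
  adapter status per read.

Contaminant sequences are generated k-mer-disjoint (k = 15) from the
transcriptome — colliding windows are mutated until clean — so the
exact-k-mer filter removes precisely the planted reads and the
removed-equals-planted check is deterministic. All generators are pure
functions of (annotation, config, seed); each stage derives its own
numpy Generator from the single seed.

The closed-form 5′-end density implied by this model
(`expected_fiveprime_density`) is exact under the defaults (the 25-nt
buffers cover the 15-nt offset, so no boundary resampling occurs) and is
what the parameter-recovery tests compare against.

**What passing tests do and do not show.** The simulation has no
sequencing errors, no codon-specific dwell times, no mismatch or spliced
alignment, no UMI structure, and constant-high quality strings (the
pipeline ignores quality by design). Tests therefore verify the
bookkeeping, the statistics, and the detection logic — not robustness to
real-library noise, which for real data is delegated to an external
aligner upstream.

## Statistical conventions and problem sizes

Stochastic checks compare an estimate to its generator expectation
within 4 standard errors under the generator's sampling model (binomial
or multinomial bounds; a delta-method SE for the start-peak count
ratio), with seeds fixed in the suite. The test and acceptance runs use
20–100 genes with 2 000–50 000 reads for unit and recovery checks and
200 genes with 100 000 reads (20 % rRNA, adapters on) for end-to-end
truth recovery — sizes at which every 4-SE band is a few parts per
thousand wide while the whole suite stays quick on one CPU.

## Known limitations

* The exact aligner is a documented stand-in for external aligners, not
  a reproduction of any published mapping rule; it cannot place reads
  containing mismatches.
* P/E-site views are derivable (A-site − 3/−6 nt) but not separately
  stored; codon dwell-time models, translation-efficiency ratios, and
  differential expression are out of scope.
* The HDF5 schema is this package's own versioned contract.
* Relative positions in the positional distribution use 5′ ends, so the
  apparent ORF occupancy is shifted upstream by the (unapplied) A-site
  offset; this is a presentation choice, consistent across datasets.
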