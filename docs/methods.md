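# Methods

This note documents the model behind `lncscout`, the tunables that matter,
the numerical conventions, and what the synthetic cohorts do and do not
demonstrate.

## Model and assumptions

The pipeline assumes that a novel transcript shows up in a sample cohort as
a contiguous block of read coverage outside annotated genes, expressed
strongly in a minority of samples against a quiet background. It therefore
works entirely from per-base coverage and gapped alignments; it does not
assemble reads, quantify isoforms, or test predefined sample groups. One
representative transcript model is reported per merged region.

Coordinates are 0-based half-open everywhere internally. GTF input
(1-based inclusive) is converted on read; BED is taken as-is; GFF3/BED12
are written per their specifications. The RPM denominator is the number of
primary mapped read records (secondary and supplementary alignments are
excluded; duplicates are kept — no deduplication step is part of the
method). Multi-mapped reads are used as they appear in the BAM. N bases in
the genome are a hard mask: they contribute to no GC/Chargaff/T-fraction
denominator and never match a motif position.

## Window scan

* `window` = 500 bp, `step` = 250 bp. Tiling emits full windows
  `[i·step, i·step+window)`; after the last full window one partial tail
  window is appended when it extends past the covered end and is ≥ `step`
  long, so short chromosome tails are still scanned without emitting a
  redundant sub-window of the last full one.
* Per window and sample the value is mean per-base RPM. With < 5 samples
  the scan refuses to run: the 20% quantile must contain ≥ 1 sample.
* The "highest/lowest 20%" is the mean of the `ceil(0.2·n)` highest
  (lowest) sample values — a mean rather than a single order statistic, so
  the rule is well defined for every n ≥ 5. The median is the standard
  midpoint-interpolated median.
* Selection fires when *either* extreme passes both thresholds:
  `|extreme − median| > 1` RPM (linear scale — the quantities compared are
  RPM coverages) and `|log2((extreme + c)/(median + c))| > 1` with
  pseudocount `c = 0.1` RPM, which keeps the fold change defined over the
  common all-zero-median background. Both thresholds and the pseudocount
  are configurable.
* Gene filtering is strand-agnostic and uses full gene spans (exons plus
  introns): the target class is *intergenic* transcripts, so anything
  inside a gene body is discarded regardless of exon structure.
* Overlapping **and book-ended** selected windows merge: adjacent
  250 bp-step windows covering one transcript should form a single region.

## Structure expansion

* Boundary refinement links bases with pooled (cohort-mean) RPM ≥
  `min_rpm` (default 0.5), bridging runs of up to `max_gap` (50)
  sub-threshold bases, capped at `max_extension` (10 kb) per side, and
  never crossing an annotated gene span or a chromosome end. The walk both
  extends outward *and trims inward*: merged windows are step-grid aligned
  and typically overshoot the true transcript ends by up to one window
  length, so without trimming the terminal exon boundaries could never be
  exact. A region with no base at `min_rpm` is skipped with a warning.
* Junctions come from CIGAR `N` operations ≥ `min_intron` (30 bp; shorter
  skips are treated as deletions, following standard short-read practice),
  aggregated across samples, and kept at `support ≥ min_support` (3).
* A "valid" splice junction is canonical GT..AG in transcript orientation
  (genomic CT..AC on the minus strand). Strand is a majority vote of
  canonical junction motifs; with no junctions or a tie the candidate is
  scored in both orientations and the better total is reported with a
  `strand_assumed` flag.
* Mutually exclusive junction chains are resolved greedily by support,
  highest first; accepted introns must leave a nonempty exon around them.

## Scoring

* Promoter window: `[TSS − 200, TSS + 50)` on the sense strand (both
  extents configurable). GC and Chargaff (G+T skew) fractions are measured
  on that sense-strand sequence.
* Motif consensi and positional windows (motif start relative to TSS):
  TATA box `TATAAA` in `[−33, −23]`; Initiator `YYANWYY` overlapping the
  TSS; DPE `RGWYV` in `[+21, +35]` (+28 ± 7). A perfect IUPAC match of any
  one of them sets `S_motif = 1`.
* Poly(A) signal `AATAAA` is searched in the final 50 nt of the spliced
  transcript plus 20 nt of downstream genomic sequence; leftmost perfect
  hit wins, otherwise leftmost single-mismatch hit. The T-rich fraction is
  taken over the 80 bases following the hit (crossing the transcript end
  into genomic sequence when needed); with no hit both 3'UTR sub-scores
  are 0.
* The piecewise maps use strict outer inequalities as printed, making the
  closed middle branch continuous at both breakpoints; the linear/sqrt
  ramps are clamped so floating-point division can never leave [0, 1].
  Note the T-rich ramp is a square root, so its slope at the lower
  breakpoint is unbounded (f(0.3 + ε) = √(10ε)).
* `S_ORF` with no ORF (no ATG..stop in any forward frame) is defined as 0;
  the printed formula does not cover `n_ORF = 0`. The ORF score is additive
  in the total as printed, i.e. coding potential *raises* the rank; this is
  a deliberate fidelity-to-formula choice even though it is conceptually
  debatable for noncoding RNA screening.
* Ranking ties are broken by mean cohort RPM (descending) and then genomic
  coordinate, purely for determinism.

## Synthetic cohorts

The generator emulates exactly the statistical structure the scan assumes:

* a random 50 kb genome (uniform base composition) with annotated decoy
  genes and planted intergenic transcripts;
* plant sequences are rewritten so each declared feature is realized
  *exactly*: promoter windows get exact-count base compositions, motifs are
  written at their expected offsets, introns are `GT..AG`, the ORF is a
  stop-free codon run from an ATG to a stop inside the last exon, and the
  poly(A)/T-rich block is placed in the transcript tail. Accidental motif
  or poly(A) hits that would change the intended score class are scrubbed
  by deterministic point mutations (mutations near the T-rich window only
  touch non-T positions so the realized T fraction is preserved);
* reads are error-free, fixed-length (100 nt), and deterministic given the
  seed; spliced reads span the planted junctions. Expressed transcripts are
  covered at depth ~10; the fixture cohort has 5 samples with each plant
  expressed in 2 of them.
* background reads share identical positions across samples, plants get a
  300 bp read-free buffer, and per-sample mapped-read totals are equalized
  with filler reads placed *inside* an annotated decoy gene. The buffer
  makes exact boundary recovery well-posed, and the equalization realizes
  "uniform background" in RPM space: without it, differing RPM denominators
  between expressed and non-expressed samples would make the flat raw
  background itself look like a cohort-wide outlier. Decoy genes are given
  their own subset-expressed reads so the known-gene filter is actually
  exercised rather than trivially empty.
* the truth table is computed by running the scoring engine on the planted
  sequence and the planted exon chain — scoring is deterministic given the
  sequence, so the end-to-end tests check that scan + structure expansion
  reconstruct exactly the planted model, and that the reconstructed model
  scores identically.

What passing these tests does **not** show: robustness to alignment
artifacts, sequencing error, coverage bias, duplicated reads, overlapping
isoforms, or fuzzy transcript ends — real cohorts have all of these, and
the boundary refinement in particular will land on coverage edges, not
biological TSSs. The fixture sizes (5 samples, 50 kb, ~4,000 reads per
sample) were chosen as the smallest cohort on which every rule in the
method — quintile selection, gene filtering, merging, junction assembly,
strand inference, and all nine sub-scores — is exercised end to end.

## Known limitations

* One transcript model per region; no isoform enumeration.
* The statistical-test variant of window selection (group comparisons) is
  out of scope; only the outlier rule is implemented.
* bedGraph input supports the scan only; junctions (and hence multi-exon
  models and `S_ex > 0`) require BAM input.
* Candidate curation (e.g. browser inspection) is intentionally left to
  the user; the ranked table is the final output.
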