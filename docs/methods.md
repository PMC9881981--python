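# Methods

## The model

A nanopore reports ionic current over a pore occupied by Q consecutive
bases (Q = 6 here), so the raw signal is a function of Q-mers, not single
bases, and basecalling errors are biased toward substitutions whose Q-mers
produce similar currents.  `hqalign` exploits this without touching raw
signal: a *Q-mer map* assigns each of the 4^Q Q-mers a median current
(pA); sliding a Q-window over a basecalled sequence and hard-thresholding
the currents into L levels (L = 3 by default, the "HQ3" alphabet) yields a
*quantized sequence* of length n − Q + 1.  Sequences that are confusable
in current space become identical after quantization, so alignment in the
quantized alphabet is blind to exactly the error mode the sequencer makes.

Alignment is two-staged.  Stage 1 aligns the nucleotide read to the
nucleotide reference with a minimizer seed–chain–extend engine and yields
regions of interest (ROIs) `[s, e)`.  Each ROI is extended by
`b = round(max(1 − f, 0.25) · n)` bases on both sides, where
`f = (e − s)/n` is the aligned fraction clamped to [0, 1]; overlapping
extended ROIs merge.  Stage 2 quantizes the read and the extended target
slice and re-aligns in the L-letter alphabet.  Because current levels have
no complement structure, the quantized reverse complement cannot be
derived from the forward quantized sequence; stage 2 therefore aligns two
independent queries — quantize(x) and quantize(revcomp(x)) — against each
ROI slice and keeps the best-scoring orientation as primary.  This is what
lets one read produce a +/−/+ split alignment across an inverted segment.
Quantized coordinates back-translate to nucleotides as
`[s_q + p, s_q + p + Q − 1)` for a quantized symbol at position p; since
one base error at a read end corrupts every window covering it, the
quantized alignment is blind to the outermost few bases, and short
unaligned remainders are extrapolated diagonally (capped at 2Q) when the
nucleotide span is estimated.

## The alignment engine

One engine serves both alphabets (`align_core`):

* **Seeding.** Minimizers (window w over k-mers, splitmix64 hashing, all
  ties kept), k = 15/w = 10 for nucleotides, k = 18 for the ternary
  alphabet.  Quantized seeding is denser (w = 5, chains from 2 anchors):
  one base error corrupts up to Q consecutive quantized symbols, so exact
  18-mers survive rarely, and stage 2 operates inside a small ROI where
  sparse seeding cannot be compensated by genome-wide context.
* **Chaining.** Colinear DP, one point per anchor minus a
  diagonal-difference penalty (0.01/base, capped at 2 so SV-scale gaps
  remain joinable), predecessor window 192 anchors — large enough to
  bridge the dense many-to-many anchor blocks of tandem repeat arrays.
* **Extension.** Banded Gotoh ("glocal": full query, free leading/trailing
  target gaps) with the band following the chain diagonal; the band is
  widened ×4 and the alignment retried when the traceback presses against
  an edge inside the anchored stretch.  Nucleotide scoring is
  match 2 / mismatch −4 / gap open 24 / extend 2 — the high open cost
  keeps SV-scale gaps contiguous instead of fragmenting around chance
  matches.  Quantized scoring is 4 / −8 / 32 / 2: a correct quantized
  alignment of a 10%-error read runs at ~30% symbol mismatch and must
  still score positive, while a long gap must stay cheaper per symbol
  than "soup" (sliding through unrelated sequence, which the
  autocorrelated ternary alphabet matches ~45% of the time).
* **Splitting.** Inverted middles are cut out by *seed evidence*: an
  opposite-orientation rival chain nested inside the primary's query span
  triggers a three-way split.  A score-drop (Z-drop) scan with lightly
  charged gap runs handles other collapses; leftover query intervals
  ≥ 100 symbols are re-chained into supplementary records.  Alignment
  ends are trimmed to the maximum-score point under a fixed +2/−2 scale
  (break-even at 50% identity), with gap bases neutral, so forced
  low-identity tails are clipped while a genuine trailing SV gap
  survives.  Unanchored read ends up to 400 symbols are carried through
  the band; longer tails are soft-clipped.
* **Guide anchors.** Stage-2 chaining additionally receives sparse anchors
  sampled every 256 aligned bases from the stage-1 CIGAR, converted to
  the quantized frame.  Quantized seeds decide wherever they exist; the
  guides keep the re-alignment in phase across tandem repeats and seed
  deserts, where the ternary alphabet alone is ambiguous.
* **Primary designation.** Among a read's records the primary is the one
  with the largest error-adjusted aligned span (query span minus edit
  operations), not the best raw DP score: under the high-mismatch
  quantized scoring a short clean shard can out-score a long noisy but
  structurally correct alignment.
* **Mapping quality.** 60 for unique chains, otherwise
  `40·(1 − second/best)·min(1, anchors/10)` using competing chains that
  share the record's query interval (counted by anchors, so a chain that
  merely spans the interval without evidence inside it does not compete).

Levenshtein distances (the numerator of the normalized edit distance) are
computed with edlib; the CIGAR-level aligner above is validated in the
test suite against a full-matrix affine DP oracle, exhaustive chaining,
and a recursive edit-distance oracle.

## Metrics

A read is *well-aligned* when its primary record spans ≥ 90% of the read
in the record's domain (n nucleotides, n − Q + 1 quantized symbols) with
mapping quality > 20.  *Normalized edit distance* divides the nucleotide
edit distance between the (orientation-matched) full read and the genome
slice at the alignment's coordinates by the read length; for quantized
records only the coordinates come from the quantized alignment,
back-translated.  *Normalized alignment length* is target span over
domain read length.  Cohort comparisons fit ordinary least squares to the
per-read scatter of one method's normalized edit distance against the
other's, over reads aligned by both.

## SV calling

The caller (`sv_call`) is deliberately minimal — enough to benchmark the
aligner, not a production caller.  Signatures per read: CIGAR indel runs
(runs ≥ 20 bases merged when separated by < 500 aligned bases, because
long gaps fragment inside repeats; merged runs ≥ 50 emitted); split-read
pairs of opposite strand ((+,−) → inversion [end(+), end(−)); (−,+) →
[start(−), start(+)); a +/−/+ triple yields the same interval twice, and
single-junction pairs are what detect inversions longer than a read);
split-read pairs of same strand (reference/query gap imbalance ≥ 200,
recovering SVs whose gap did not survive in one CIGAR).  Records below
mapping quality 20 are ignored.

Clustering is single-linkage by position within (chromosome, type) at
500 bp, then each positional cluster is divided into length modes (break
at 1.8× + 50) and the best-supported mode that passes the noise gates
becomes the locus call (median position/length; ≥ 3 distinct reads).
The noise gates target tandem-repeat slippage, the dominant artifact of
noisy long reads in VNTR arrays:

* *allele fraction*: a germline SV is carried by every read spanning the
  locus; clusters supported by < 60% of spanning records are minority
  slippage.  Spanning counts use individual records at any mapping
  quality (coverage is coverage, even where it is ambiguous).
* *length consistency*: short calls (≤ 500) whose supporting lengths have
  a coefficient of variation > 0.35 are slippage; true short SVs are
  reproduced near-exactly by every read.
* *coverage inside deletions*: a deletion ≥ 1 kb is rejected when reads
  map inside it at ≥ 35% of flank coverage (split pairs bridging repeat
  copies fabricate such deletions).
* *balanced pairs*: a nearby small INS/DEL pair of similar length is
  repeat-phase slippage, and small indel calls within 150 bp of a called
  inversion breakpoint are junction debris.

Benchmarking (`sv_eval`) is Truvari-flavored: candidates require same
type and chromosome, breakpoint score (mean absolute start/end offset;
|Δstart| for insertions, whose END is degenerate) ≤ 500 and length
similarity (min/max) ≥ 0.7, matched one-to-one greedily by ascending
breakpoint score.  Precision = TP/(TP+FP) over calls, recall = TP/(TP+FN)
over truth, F1 their harmonic mean.  The *union model* keeps every call
of set A plus each call of B with no A-counterpart under the same gate;
its recall is provably ≥ each constituent's.  Complementary calls can be
re-matched at a relaxed similarity threshold, and call sets can be masked
by BED intervals.

## Synthetic data

`synthetic_data` emulates the experimental inputs end to end:

* *Genome*: i.i.d. bases (GC 0.5) seasoned with VNTR-style tandem arrays
  (unit 5–50 bp, 5–30 copies, arrays capped at 3 kb) until a target
  repeat fraction is reached.  The SV benchmark uses 0.2 — a deliberate
  stress level — and the alignment-parity regression uses 0.1, closer to
  ordinary chromosome content.
* *SVs*: INS/DEL/INV planted non-overlapping with ≥ 1 kb spacing (so
  breakpoints stay attributable), INDELs split evenly, lengths uniform on
  [50, 10000]; truth coordinates refer to the original genome while reads
  are simulated from the mutated one — the discovery direction.
* *Reads*: log-normal lengths fit to (mean, median); the default profile
  is mean 14 kb / median 4.5 kb capped at 50 kb (the unbounded tail of
  the fit is impractical), with a 200 bp floor; benchmarks use a scaled
  mean of 3 kb.  Either strand with probability 0.5.  Errors at a
  per-base rate split 40/30/30 substitution/insertion/deletion; with
  probability `confusion_weight` a substitution is drawn among the bases
  keeping the local Q-mer in its quantization bin.  That bias is the
  mechanism the pipeline exploits: at equal nucleotide error rate, fully
  confusable reads are strictly closer to their source in quantized
  space, which the test suite verifies.
* *Q-mer map*: synthetic, uniform currents on [60, 120] pA with one
  forced near-degenerate pair; thresholds are the equal-occupancy
  quantiles of the 4^Q model currents (maximum-entropy ternary alphabet),
  ties resolved to the lower level, windows containing non-ACGT bases
  assigned the middle level.

What passing on this generator does **not** show: real pore models have
structured (non-uniform) current distributions, real error rates vary
along the read and by homopolymer context, and real genomes carry far
richer repeat families; results here validate the machinery and its
relative behavior, not absolute performance on real flow-cell data.

## Benchmarks and problem sizes

`benchmarks.simulated_sv_benchmark` is one replicate of the simulated SV
experiment: 1.2 Mb genome (repeat fraction 0.2), 100 INDELs + 20
inversions uniform on [50, 10000], reads at 40× with mean 3 kb and 10%
errors (confusion weight 0.5); the hybrid pipeline and the stage-1
nucleotide alignments are each fed to the caller and benchmarked, plus
their union.  `benchmarks.edit_distance_regression` aligns ~4,500 reads
(13×, 1 Mb, no SVs) in both modes and regresses quantized-coordinate
against nucleotide-coordinate normalized edit distance.  Reported values
average three replicate seeds: the SV metrics are ratios over only ~120
events each, and the OLS slope carries most of its leverage in a handful
of high-edit-distance reads, so single-seed values scatter by a few
hundredths.

A note on the cross-mode regression: its slope balances two opposing
effects.  One base error corrupts up to Q quantized symbols, which makes
the quantized sequence noisier than the basecalls and pushes the
quantized-coordinate edit distance up (slope above 1); error
confusability hides errors from the quantized alphabet and pushes it
down.  The balance point depends directly on the similarity structure of
the Q-mer map and the bias of the error process: with an independent
synthetic map and half-biased errors (the configuration used here) the
two modes sit near parity with a slight quantized penalty, while a map
with realistic additive structure tips the balance firmly toward the
quantized mode.  The slope is therefore the most delicate quantity this
package reports, and it is averaged over replicates.

## Known limitations

* One locus, one call: two SVs of the same type within the 500 bp cluster
  window would merge (the generator's 1 kb spacing avoids this by
  construction).
* Inversions shorter than ~200 bp are absorbed as mismatch stretches in
  both alphabets and are not called; inversions longer than a read are
  detected from single-junction split pairs only.
* The caller has no genotyping, no duplication/translocation classes, and
  its slippage gates assume homozygous events at uniform coverage.
* Whole-genome scale is out of scope; the engine is tuned for megabase
  references at desk scale.
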