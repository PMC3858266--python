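# Methods

This note records the models, defaults and design choices behind
`srnaome`, and what the synthetic benchmark does and does not establish.

## Read cleaning

"Clean reads" are operationalised as an explicit filter chain, since
different studies bundle different rules under that phrase:

1. **Adapter trimming** — the first exact occurrence of the 3′ adapter's
   8-nt prefix marks the trim point (no mismatches, no indels). Reads
   beginning with the adapter are discarded (`adapter_only`).
2. **Ambiguity** — more than `max_N` (default 0) `N` bases discards the
   read.
3. **Quality** — mean phred of the trimmed read below
   `min_mean_quality` (default 20) discards it; applied only when
   qualities exist, so pre-cleaned FASTA input passes through.
4. **Length window** — 18–30 nt kept (`min_len`/`max_len`).

Every discard is tallied by reason, making the filter chain auditable
rather than a black box. Exact-prefix adapter matching is deliberate: it
is deterministic and testable, and this package does not attempt to
reconstruct any particular instrument's error behaviour.

All sequences are normalised to uppercase DNA (U→T) on ingest; RNA
flavour is re-emitted only on request when writing FASTA.

## Profiles and dominance

The per-length profile carries redundant counts (read occurrences),
nonredundant counts (distinct tags), their ratio (redundancy frequency,
always ≥ 1), and both share vectors (each sums to 1). `dominant_length`
is the argmax of the chosen share vector with ties broken toward the
smaller length, so the call is deterministic.

## Hierarchical annotation

Matching is ungapped, full-length substring alignment of the 18–30 nt
tag inside a catalog sequence. With reads this short, full scans are
tractable and exactly testable; the implementation's `str.find`
shortcuts and early exits are speedups only and are held equal to a
brute-force all-offsets scan by oracle tests. Tie-breaks are fixed:
fewer mismatches, earlier catalog entry, smaller offset, sense before
antisense.

Defaults: 2 mismatches for the homology-based miRNA search (common
plant-sRNA practice; the tolerance is configurable), 0 elsewhere;
repeats and mRNA fragments are searched on both strands, structural RNAs
and matures sense-only. Category precedence (rRNA > tRNA > snRNA >
snoRNA > miRNA > repeat > mRNA) resolves multi-category hits; an
alternative would be to discard ambiguous reads, and the precedence
order is exposed in `AnnotationConfig` for exactly that reason. Repeat
hits are reported as repeat(ra-siRNA) regardless of length; read length
is reported alongside, not used as a filter.

## Hairpin discovery

**Folding.** The default engine maximises nested base pairs
({AU, UA, GC, CG, GU, UG}, hairpin loops ≥ 3 nt) by dynamic programming
with a deterministic traceback (position *i* pairs with the smallest
admissible partner achieving the optimum). Pair maximization was chosen
over free-energy minimisation because it is self-contained and
oracle-testable by exhaustive enumeration; an energy-based engine
(ViennaRNA `RNAfold`) satisfies the same `FoldResult` contract and can
be passed as `fold_fn`, but nothing requires it.

**Windows.** For each exact occurrence of an unannotated tag on a
scaffold (either strand), two windows test the mature-on-5′-arm and
mature-on-3′-arm hypotheses: `[occ_start − flank, occ_end + 15)` and
`[occ_start − 15, occ_end + flank)` with `flank` = 250 nt, clipped to
scaffold bounds. Antisense occurrences fold the reverse complement.

**Duplex criteria** (all configurable; declared assumptions in the
spirit of community plant-miRNA annotation practice, not reconstructions
of any one study): mature pairing fraction ≥ 0.60; ≤ 4 unpaired mature
bases in the duplex; bulges ≤ 2 nt; partners strictly antiparallel; the
mature must not intersect the terminal loop. Loop clearance is measured
from the mature's loop-*distal* end: the mature must sit ≥ 3 nt into the
stem, so a mature ending flush against the loop of an ample stem passes
while one squeezed onto a tiny stem does not (this also keeps the
perfect-inverted-repeat case well-defined).

**Star prediction and classification.** The predicted miRNA* locus is
the mature's pairing span shifted by +2 nt, giving both duplex strands
the canonical Dicer 2-nt 3′ overhang; the same rule applied to the star
recovers the mature (involution, tested). A sequenced read placed within
±1 nt at either end of the prediction (Dicer imprecision) with ≥ 1 read
promotes the candidate to novel. One hairpin legitimately yields several
passing readings (star-as-mature, antisense arm); verdicts are therefore
aggregated per scaffold locus with novel > candidate.

## Differential expression

`tpm = count / total_clean_reads × 10⁶` — the denominator is the
library's total clean reads, not its total miRNA reads (both conventions
exist; this package follows the clean-read convention and takes the
denominator as explicit input). The contrast is `log2(tpm_D/tpm_G)` with
±1 cutoffs. Zero counts route to the exclusive-detection rule
(≥ 3 reads in the nonzero library → exclusive call, else
`below_detection`) instead of pseudo-counting, mirroring the
threshold-call methodology; no dispersion model or p-values are fitted.
miRNA* rows are excluded from regulation calling by default
(`include_star=True` includes them).

## Synthetic benchmark

`paired_embryo_config` fixes the study conditions: two 100k-read
libraries.

* **Length structure** — dormant-like background peaks at 24 nt (0.50 of
  background mass, minor 21/22 peaks); germinated-like peaks at 21 nt
  (0.35), with 24 nt reduced to 0.18.
* **Category structure** — background mix dominated by unknown tags
  (~0.90), rRNA ~7–8%, small structural/repeat/mRNA fractions; the miRNA
  mass is the sum of the spike proportions: ≈ 21.9% (dormant) vs ≈ 35.6%
  (germinated), so the miRNA share rises on germination.
* **Spikes** — nine conserved-family matures with per-library
  `tpm = base × 2^(±lfc/2)` spanning 180,000 tpm (a miR950-like
  conifer-dominant family) down to 400 tpm, and fold changes from −1.5
  to +1.6 with most families germinated-up. Defining the miRNA mass from
  the spike sums (rather than an independent category probability) keeps
  every spike's realised expected fold change exactly equal to its
  nominal one. Abundances were chosen so that spikes above the 50-read
  evaluation floor carry hundreds of reads, where binomial sampling
  error on the log₂ ratio is ≈ 0.07–0.13 — comfortably inside the ±0.2
  recovery band — while miR160 (400 tpm) deliberately sits below the
  floor.
* **Hairpin loci** — six EST-like scaffolds (~98 nt, shorter than 200 nt
  as real short ESTs can be), three emitting star reads (expected
  verdict novel) and three not (candidate). Scaffolds are
  `flank + mature + ATTA + C₈ + rc(ATTA) + rc(mature) + rc(flank)` with
  20-nt A/C flanks. The low-complexity choices are intentional: the
  all-C loop pairs only with G, the A/T stem extension offers it none,
  and A/C flanks cannot pair among themselves, so the designed duplex is
  the strict pair-maximization optimum for any mature sequence and star
  recovery does not depend on the seed. Star reads are placed by a
  closed-form overhang computation independent of the pipeline's folder.
* **Redundancy** — background tags are drawn from finite per-length
  pools shared between libraries (pool ≈ expected reads / target
  redundancy; 24 nt targets 1.6, 21/22 nt target 8/12), reproducing the
  "24 nt most diverse, 21/22 nt most redundant" structure.
* **Noise** — default per-base substitution rate 0, so closed-loop
  category recovery is exact; raising it exercises mismatch-tolerant
  matching.

What passing the benchmark shows: the pipeline recovers known
composition, fold changes and hairpin verdicts under ideal sequencing
from catalogs that exactly cover the data. What it does not show:
robustness to adapter read-through, indel errors, incomplete or
mis-versioned reference databases, cross-mapping between near-identical
family members, or ligation bias — real libraries add all of these.
Consequently the published library-scale percentages of the original
larch study (e.g. 98.96% clean reads or the exact 27.40%/44.05%
annotated fractions) are emulated structurally, not reproduced
numerically.

## Numerical and reporting choices

* Coordinates are 0-based half-open throughout; strands are `+`/`-` with
  antisense handled by reverse-complementing the query or window.
* Probability vectors are validated to sum to 1 within 1e-9; simulation
  draws are single multinomials per library, seeded through
  `numpy.random.SeedSequence` sub-streams, and identical configurations
  produce byte-identical output.
* Pipeline TSVs print floats at 4 decimals with a fixed column order so
  reruns are byte-comparable; the run log records a config hash that
  changes iff a configurable value changes, plus per-stage read counts
  (conservation is asserted, not assumed).
* Problem sizes used by the test suite: 100k reads per library for
  recovery checks, 20k for pipeline-level tests, 500 sequences ≤ 14 nt
  for the folding oracle and 200 read/catalog pairs (catalogs ≤ 2 kb)
  for the matching oracle.

## Known limitations

* Ungapped matching cannot annotate reads whose references require
  indels; covariance-model scanning (Rfam-style) is out of scope and a
  catalog FASTA stands in.
* Pair-maximization folding ignores thermodynamics; structures with
  equal pair counts are disambiguated by a fixed traceback rule, which
  on highly ambiguous windows may route mature partners differently
  than an energy model would. The `RNAfold` plug-in exists for exactly
  that comparison.
* The packaged larch table preserves the published values verbatim,
  including one internal inconsistency (llemiR-7's printed length is
  22 nt against a 21-nt printed sequence).
* Genome mapping, phased-siRNA (ta-siRNA) locus detection and
  conservation-based candidate rescue are out of scope.
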