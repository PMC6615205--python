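# Methods

This note documents the models, algorithms, defaults and numerical choices
behind the toolkit, and what its synthetic-data experiments do and do not
demonstrate about real sequencing data.

## Synthetic genomes and digestion

`generate_genome` draws i.i.d. bases with P(G)+P(C) equal to `gc_target`
(G/C and A/T equiprobable within their class), optionally with a linear GC
gradient along each chromosome for exercising GC-bias correction.  An
i.i.d. genome has no repeats, no chromatin structure and no assembly gaps;
consequences are noted per component below.

Digestion scans the forward strand for exact occurrences of the
recognition site and cuts at `site_start + cut_offset`.  Both built-in
sites (SaqAI `TTAA`, Hin1II `CATG`) are palindromic, so forward-strand
scanning finds every double-strand cut; non-palindromic enzymes would need
a second scan of the reverse strand and are out of scope.  `N` never
matches a site, so gap runs are uncuttable; chromosome-end pieces are
included in fragment-length statistics (they are a vanishing fraction at
genome scale).  On an i.i.d. GC-0.5 genome the expected inter-cut distance
for a 4 bp site is 4^4 = 256 bp; the test suite checks the observed mean
within 10%.  On a GC-0.41 genome (the human composition) the same scan
gives ≈132 bp for `TTAA` and ≈273 bp for `CATG` — an i.i.d. model brackets
but does not reproduce the empirical means on a real assembly, where local
composition is strongly non-uniform.

## Read simulation

Fragments are sampled **with replacement**, each with probability
proportional to the planted copy number at its midpoint; strand is
Bernoulli(0.5) per fragment (ligation has no orientation preference).
Reads are built by packing fragments in sampled order until the next
fragment would exceed `target_read_len`; molecules are never split, so
read length spreads by about one fragment.  With ~256 bp fragments packed
to 6.75 kb this yields ≈26.5 fragments per read, matching the regime the
protocol operates in (~27 fragments per ~7 kb read).

The error model applies, per original base: deletion with `del_rate`,
else emission with substitution at `sub_rate` (to a uniformly random
different base) and insertion of a random base after it at `ins_rate`.
Defaults 0.05/0.03/0.04 give ~12% edit distance, emulating R9-era nanopore
identity.  The model is independent per base: it has no homopolymer
structure, no quality correlation and no chimeric artifacts, so mapper
recall measured here is an idealized upper bound for real basecalls.
Fragment truth is re-expressed in post-error coordinates so that
evaluation operates in final read space.  Per-read error streams are
seeded from (model seed, read id), making every read reproducible in
isolation.

`splice_from_reads` reproduces the alternative simulation design in which
fragments are substrings cut from longer reads with known origins; the
fragment-length distribution is deliberately a free parameter (an
empirical pool sampled with replacement) since no canonical choice exists.

## Split-read mapping

The mapper is a minimal seed-chain-extend aligner honoring the scoring
constants tuned for this read type: match +4, mismatch 10, gap open 6,
gap extend 3 (a gap of length k costs 6 + 3k), seed length 12, minimum
chain weight 12, report threshold 120.  The index is a sorted table of
2-bit-packed 12-mers (both strands resolved at query time); k-mers with
more than 64 reference placements are skipped as a repeat guard.  This is
deliberately not an FM-index: at the tens-of-megabase references this
toolkit targets, a flat sorted table is simpler and fast enough.

Seeds (maximal exact matches ≥ 12 bp) are grouped into chains by
(chromosome, strand, diagonal): sorted by diagonal, split where the
diagonal jumps by more than 100 bp, then split again where consecutive
seeds are more than 500 bp apart on the read.  The read-gap cap matters:
a stray 12-mer collision landing near a real chain's diagonal would
otherwise stretch the chain's span across unrelated fragments.  Chains
lighter than 12 are dropped; chains buried (>50% of the shorter span) under
a strictly heavier chain are suppressed, with equal-weight alternatives
kept so multi-mapping can be detected.  Because a suppressed chain can
still own the only alignment for its stretch of the read (when the
suppressor's span was inflated), suppressed chains whose read interval is
left mostly uncovered by the winners' actual alignments are rescued and
extended as well.

Extension is local affine-gap Smith–Waterman over a window covering the
chain plus 50 bp of slack, banded to the chain's diagonal corridor widened
by 40 (out-of-band cells read as fresh local starts, a lower bound, so a
banded score never exceeds the unbanded one; the test suite checks
reported scores against an independent full Smith–Waterman
implementation).  A fragment is reported only at score ≥ 120 — by
arithmetic, a perfect 30 bp match.  Overlapping reports are resolved
greedily by score (ties by lowest (chromosome, start)); `is_unique` is
false when another candidate covering ≥ half of the fragment's read
interval scores as high, the analogue of MAPQ 0, and only unique fragments
are counted for CNV.  Boundaries are score-determined, not truth-
determined: local extension can over- or under-run a fragment end by a few
bases, which the 50%-reciprocal-overlap evaluation convention tolerates.

Study conditions for mapper evaluation: fragments are sampled with a
100 bp minimum length.  ~100 bp is the shortest molecule that maps
uniquely in practice, and below 30 bp the report threshold is
unreachable by arithmetic, so including the full exponential tail of an
i.i.d. digest would only measure that arithmetic, not the mapper.

## Mapping evaluation

A predicted fragment matches a truth fragment iff same read, chromosome
and strand and reciprocal reference overlap ≥ 0.5 (the usual structural-
variant convention; exposed as a parameter).  Matching is one-to-one,
greedy by overlap with ties broken by smaller start.  Base-level metrics
compare multisets of covered (chromosome, position) reference bases per
read, then pool — reference positions rather than read positions, so both
boundary and placement errors are penalized.  With zero predictions,
precision is reported as 1.0 with an explicit `no_predictions` flag rather
than 0/0.  Multi-mapped predictions are included by default
(`unique_only` mirrors the CNV pipeline's stricter view).

## CNV pipeline

**Mappability.** Position p is uniquely mappable iff the 40-mer starting
there contains no N and occurs exactly once in the genome counting both
strands.  Probes longer than 32 bases are keyed by a mixed 64-bit hash of
the two packed halves (exact below 33 bp); distinct probes collide with
probability ~2⁻⁶⁴ per pair, negligible at these genome sizes.

**Bins.** A genome-order sweep closes a bin at every
`ceil(total_mappable / n_bins)` mappable positions; bins never cross
chromosome boundaries, and each chromosome's last bin absorbs the
remainder (pre-masked if >10% off target).  Equal mappable content
equalizes expected counts under uniform coverage, which is the property
that makes the ratio interpretable.  GC is computed over the bin's full
physical span.  Fragments are assigned by reference midpoint so long
fragments straddling a boundary count once, without start-position bias.

**Bad bins.** Masked iteratively when the raw count exceeds
`median + 5·MAD` (MAD scaled ×1.4826, i.e. a robust z of 5) **and**
`3 × median`.  The fold floor is this package's concretization of
"spuriously high": on read-count data the robust z alone would flag
genuine 2× amplifications, because a clean count distribution is far
tighter than a factor of two; artifact pileups sit an order of magnitude
above the bulk.  The complement is a known limitation — amplifications
beyond 3× the genome median cannot be separated from artifacts by a
sample-only rule and would require a reference sample or blacklist.

**GC correction.** LOWESS (tricube-weighted local linear regression,
span 0.3, 3 robustness iterations) of raw count on bin GC over unmasked
bins; corrected = raw − fitted + grand mean, floored at 0.  Span 0.3
tracks the broad GC trend without absorbing megabase-scale CNV signal;
constant GC makes the correction the identity (with a warning).  Ratios
are corrected counts divided by the unmasked mean, so the mean ratio is
exactly 1 — note this normalizes to *average* ploidy: segment means read
as copy number over 2 only when the genome-wide mean copy number is 2.

**Segmentation.** From-scratch circular binary segmentation, per
chromosome: find the arc [i, j) maximizing the pooled-variance two-sample
t statistic between arc and complement; assess by permutation
(p = (1 + #{perm ≥ obs}) / (1 + n_perm), default 1000 permutations,
early-stopped once significance is impossible); if p < α (default 0.01)
split into up to three children and recurse.  The maximizer of the t
statistic is also the between-group sum-of-squares maximizer, so for a
single change point it coincides with the exhaustive SSE-minimizing split
— the oracle the tests check against.  Ties take the first maximum in
scan order; determinism follows from seeding every permutation stream.
Permutation granularity is a real floor at small n: with 8 bins, any
permutation keeping the high half contiguous ties the observed statistic,
so p cannot drop below ≈0.07 and an α of 0.01 correctly refuses to split.

**Spurious-segment merging.** Segments shorter than 5 bins, or within 0.1
of a neighbor's mean, are merged into the neighbor with the closer mean,
recomputing means, to a fixpoint.  These two thresholds are this package's
parameterization of the customary post-CBS filter; they are exposed as
flags and should not be assumed to match any external implementation
bin-for-bin.

**Event calls.** Per bin, from its segment mean: amplified ≥ 1.25,
deleted ≤ 0.8, boundary inclusive.

## Profile comparison

Pearson correlation over bins unmasked in both profiles (pairwise
exclusion; error below 10 shared bins).  Event comparison requires state
agreement — an amplification only matches an amplification —
with `ignore_direction` recovering the looser any-event definition; a
directional mismatch counts as both a false positive and a missed event.
Downsampling operates at read granularity by default (whole reads kept,
preserving the correlated fragment structure of concatenated reads);
fragment-level sampling is available.

## Problem sizes and study conditions

The test suite and `scripts/acceptance.py` run entirely from seeds, on
sizes chosen to exercise every claim at desk scale:

- Mapper evaluation: 10 Mb two-chromosome genome, ~5000 error-free reads
  of ~25 fragments (≥100 bp) each, 2000 reads under the error model
  (1000/500 in the acceptance script).  Checks: fragment precision and
  recall ≥ 0.99 error-free; recall ≥ 0.90 with errors.
- Copy-number recovery: 10 Mb four-chromosome genome, planted CN {2,4,1}
  over 85% / 5% / 10% of the genome — mean copy number exactly 2, so the
  expected segment means are exactly {1.0, 2.0, 0.5} — one million
  fragments over 500 equal-mappability bins (≈2000 expected per bin).
  Checks: segment means within 5%; event precision/recall ≥ 0.95;
  a neutral genome ≥ 99% neutral calls; quarter-depth downsampling keeps
  bin-ratio r ≥ 0.95.
- CBS calibration: 1000 null runs of 100 i.i.d. bins (200 in the script):
  split rate within binomial tolerance of α = 0.01; step fixtures with
  height ≥ 4 SD recovered within ±1 bin.

Passing these demonstrates internal correctness and statistical
calibration on idealized data.  It does not demonstrate performance on
real genomes (repeats, mappability holes, GC extremes, basecaller error
structure), for which the pipeline accepts externally produced SAM and
real references through the same interfaces.
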