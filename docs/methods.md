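# Methods

## Model and assumptions

`panmum` computes a colinear multiple alignment: every aligned block
covers an interval in each sequence and blocks appear in the same order in
all sequences.  The approach assumes the inputs are near-identical copies
of one underlying sequence (same chromosome of many individuals);
divergence is expected to be dominated by SNPs and short indels.  Large
inversions or transpositions violate colinearity and are not modelled —
regions affected by them end up low-coverage or unaligned, which is the
intended failure mode, not an error.

## Prefix-free parsing

A rolling polynomial Karp–Rabin hash (odd base 257, 61-bit Mersenne
modulus 2⁶¹−1; fixed constants so runs are reproducible) hashes every
window of `window` symbols.  A window whose hash is ≡ 0 (mod `modulus`)
is a trigger and closes a phrase at its last character; the first
`window−1` positions cannot close a phrase, and the trailing phrase is
admitted without a trigger end.  Phrases do not overlap, so concatenating
them reproduces the input exactly (property-tested round trip).  The
prefix-free property of the original construction plays no role here and
is not relied upon.

One dictionary is built jointly over all m sequences.  This is the only
reading under which parse-level matches across sequences are meaningful:
two parse symbols must be equal iff their phrases are base-identical.

Parameters: `window` = 10 (parsing is insensitive to it once it is a few
symbols wide), `modulus` = 100 for the backbone, 20 inside large gaps
(shorter phrases find anchors in less-conserved sequence at the cost of a
~5× larger parse).  Expected phrase length is roughly the modulus.

## Enhanced generalized suffix array

Documents are concatenated with one separator rank per document, ordered
by document index and smaller than every regular symbol.  Because each
separator occurs exactly once, suffix comparisons never cross a document
boundary, and equal suffixes from different documents tie-break to the
smaller document index — exactly the m-sentinel semantics.  One generic
integer-alphabet construction serves both base level (bytes) and parse
level (ranks).

Suffix arrays are built by numpy prefix doubling (O(n log² n)); LCP by
Kasai's algorithm; the BWT is defined per document (the suffix starting
at position 0 of document j gets sentinel #j).  lcp-intervals are
enumerated with the standard stack algorithm in one pass.  Correctness is
established against a sort-all-suffixes oracle: exhaustively for all
single-document strings up to length 7 over a 3-letter alphabet and all
multi-document partitions of strings up to total length 5, plus ~1300
seeded random larger instances (these sizes were chosen to keep the
default suite fast; the oracle and property are the same at any size).

## multiMUM detection

A width-m lcp-interval whose document-array values are pairwise distinct
and whose BWT values are not all equal corresponds one-to-one to a
multiMUM; relaxing the width to `min_occ ≤ width ≤ m` yields partial
multiMUMs.  The interval width equals the total number of occurrences of
the interval's prefix across all sequences, so DA-distinctness certifies
per-sequence uniqueness *and* absence elsewhere; right-maximality is
implied by lcp-interval-hood, and left-maximality by the BWT condition
(sentinel BWT symbols are pairwise distinct, so suffixes starting at
position 0 always witness it).  The default `min_occ = ⌊m/2⌋+1` makes
partial-fragment chains totally orderable.

## Chaining

`chain_dp` is the exact O(mk²) dynamic program over the ≪ relation; it is
used up to `dp_max_fragments` (2000) fragments, above which the
sorted-by-score heuristic runs (near-optimal when nearly all fragments
belong to the optimum, the expected regime here).  Ties are broken
deterministically: higher score, then smaller end position in the
reference sequence, then smaller fragment id.  For partial fragments, ≪
is evaluated on the sequences where both occur; the k-subset construction
(chain only fragments occurring in all of the k best-covered sequences,
for every k > m/2, keep the chain covering the most bases) guarantees
every compared pair shares a sequence.  Coverage ties pick the lower
sequence index; equal-coverage chains over different k keep the larger k.
Note the subset choice is itself heuristic: a different subset of the same
size can occasionally admit a better chain (the tests pin the
implemented choice exactly and bound it by the all-subsets optimum).

The heaviest-increasing-subsequence step runs independently per sequence:
among candidate occurrences of chain fragments (from wider intervals or
from the mapper), it selects a maximum-weight subset whose positions
increase with the fixed fragment order and avoid existing anchors.

## Backbone extension

Chain anchors are lifted through the parse coordinate maps and extended
left then right, base-by-base in lockstep across all sequences.  A
disagreeing column is crossed — and recorded as a mismatch column, i.e. a
SNP candidate — only if at least `extension_min_match` (default 10) bases
then agree in every sequence before the next disagreement or a bound.
Only substitutions are crossed: every sequence advances exactly one base
per column, so indels (no clean run arrives in shifted register) end the
extension.  Anchors are processed left to right with first-come bounds
(the previous anchor's extended end, the next anchor's unextended start),
which keeps anchors disjoint and the result deterministic regardless of
thread count.

## Gap completion

A gap's per-sequence slices are closed as follows.  Small gaps (max slice
≤ `small_gap_threshold`, default 10 000 bases — sized for workstation-
scale inputs, configurable upward) go to the center-star aligner.  Larger
gaps search partial multiMUMs: on the parse level (modulus
`gap_modulus` = 20) when the gap is at least `parse_gap_factor` = 10×
the small-gap threshold, otherwise on the base level (minimum anchor
length `min_base_anchor` = 20); a fruitless parse-level attempt falls
back to the base level.  The `>half` occurrence rule uses the number of
sequences with a non-empty slice in this gap (requiring more than half of
all m can be unsatisfiable when many slices are empty).

Chained anchors are mapped into sequences they are absent from with a
seed-and-verify mapper: exact seeds of ≥ 21 bases, semi-global (infix)
unit-cost verification, and a quality score calibrated so a unique
near-exact placement scores 60 ≫ 30 while ambiguous (two placements
within 5 % distance of each other) or weak placements score 3 < 30.  Only
length-preserving hits (substitutions, no indels) are accepted, because a
mapped occurrence shares the anchor's columns one-for-one.  An external
mapper can be substituted (PAF in, MAPQ column filtered at `mapq_min`,
reverse-strand hits dropped); matches are then chained with the same HIS
step.

The gap is split at the ordered anchors (crossing anchors are excluded,
lighter first) and the sub-gaps recurse.  A sequence in which an ordered
anchor is absent contributes its whole region between the two
neighbouring present anchors to the first sub-gap after the earlier one —
the data gives no information about a finer distribution, and any choice
preserves the projection property.  Anchors inherited as residuals
constrain lower-level chains (incompatible candidates are filtered,
residuals are forced into the chain).  Gap-level anchors are not
base-extended; extension is a backbone-only step.

A sequence with no anchor at all is removed from the gap — its slice
re-inserted verbatim as an `unaligned` block after the gap — but only
when some anchor of ≥ `removal_min_anchor` (500) bases spans all other
sequences, i.e. when the rest of the gap demonstrably aligns without it.
Recursion is capped at `max_depth` = 10; at the cap (or when no anchor is
found at either level) the gap is delegated to the small-gap aligner.

## Small-gap alignment

Center-star under unit costs: the star is the slice minimizing total
pairwise edit distance (exact over all pairs for ≤ 8 non-empty slices,
estimated against 8 sampled slices otherwise); the other slices are
aligned to the star optimally and merged through the star's gap pattern.
The induced sum-of-pairs cost is within a factor 2 of optimal (asserted
on exhaustively solved 3-sequence instances).  Pairwise alignment uses an
in-house dynamic program with traceback up to 250 000 cells and edlib's
banded aligner (same unit-cost model) beyond.  Empty slices become
all-gap rows.  An external MSA tool can be hooked in as a subprocess
(FASTA in, gapped FASTA out); its output is accepted only if it projects
exactly onto the slices, otherwise the built-in aligner is the fallback.

## Metrics

Coverage = bases inside aligned (non-`unaligned`) blocks / all input
bases, in percent.  Identity = gap-free unanimous columns / columns, in
percent, optionally excluding a column interval from both numerator and
denominator (for regions where no meaningful alignment exists).  SP-value
= sum over unordered row pairs of their distance, divided by m.  Whether
the distance should be induced by the alignment (gap-vs-residue and
mismatch 1, gap-vs-gap 0) or recomputed as the true Levenshtein distance
of the ungapped rows is ambiguous; both modes are provided (`induced` is
the default and always ≥ `exact`).

## Synthetic data

The generator derives each of m individuals independently from one
i.i.d.-uniform ACGT ancestor: per-base SNPs (default rate 1e-3, the
small-divergence regime the aligner targets), per-base indels (default
1e-4, geometric lengths with mean ≈ 3), optional missing segments
(leading/trailing/internal deletions emulating fragmented contig-based
assemblies, up to the configured fraction) and optional inversions (only
to demonstrate the documented coverage collapse; recovering them is out
of scope).  All randomness flows from one seeded generator; a fixed seed
gives byte-identical output, and re-applying the recorded truth variants
to the ancestor reproduces every sequence exactly.

What the fixtures do *not* model: shared ancestry between individuals
(every pair's divergence is twice the per-individual rate), recombination,
repeat families, compositional bias, and mutation-rate heterogeneity.
Passing tests therefore demonstrate the mechanics of parsing, anchoring,
chaining and gap completion under controlled divergence — not performance
on real chromosomes, whose repeat structure (e.g. centromeres) is known
to defeat unique-match anchoring locally.

## Numerical and engineering choices

Internal coordinates are 0-based half-open everywhere; 1-based inclusive
positions appear only in reports and worked examples.  The gap symbol is
`-`; non-ACGT characters are kept verbatim and match only themselves.
MAF rows of size 0 are emitted (correct srcSize) so every block has m
rows.  `threads` is accepted for interface parity but execution is
serial; all outputs are deterministic functions of the inputs and the
configuration.  Problem sizes in the default test suite (fixtures up to
60 kb × 8 sequences, exhaustive oracle enumerations up to length 7) are
the package's own choices to keep the suite fast while exercising every
code path; all properties are size-independent.

## Known limitations

* Strictly colinear; no inversion/transposition handling.
* The k-subset and sorted-by-score chaining steps are heuristics; only
  `chain_dp` is exact.
* Center-star is a 2-approximation; no iterative refinement.
* The built-in mapper accepts only length-preserving placements; an
  occurrence containing an indel is left to the recursion below.
* Identity/coverage are column/base counts, not statistical estimates of
  divergence.
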