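# Methods

## Linking model

A scaffold is an ordered, oriented list of components tracing back to
original contigs; a bare contig is a single-component scaffold. Each
scaffold has a begin (B) and end (E) terminus, and the end distance of
a position p on a scaffold of length L is p (toward B) or L − 1 − p
(toward E). A read pair with one locus on scaffold i and one on
scaffold j is counted toward end combination (X, Y) ∈ {B,E}² when the
triangle predicate holds:

    d_X(i) + d_Y(j) < l

with l the current window length. The predicate is strict and uses
0-based distances from the terminal base, making the triangle the
near-junction half of the l × l square: its area scales with l² exactly
as the square's does, so the 1.4 growth factor doubles the evidence
region every two iterations for both shapes. A square ablation
(d_X < l and d_Y < l) is available behind the same code path
(`WindowParams.window = "square"`) for benchmarking. Pairs with both
loci on one scaffold carry no junction information and are ignored.

The link count between two scaffolds is the maximum of the four
end-combination counts, and its arg-max labels the junction hypothesis
(BB/BE/EB/EE). Per scaffold only the five strongest partners by raw
count enter the normalisation; each retained candidate's score is its
count divided by the top-5 sum, so nonzero scores per scaffold sum to
exactly 1. The degenerate all-zero candidate list yields all-zero
scores rather than a division error.

### Edge retention

An edge must clear the weight cutoff at both of its endpoints, then win
its scaffold end at both endpoints (at most one edge per B and per E of
every node). Mutual per-end retention is stricter than "keep the two
best edges per node": two edges on the same end of a node cannot both
be realised in a linear chromosome, so admitting them could only create
conflicts for the path stage to undo. Resulting graph components are
simple paths or cycles.

### Deterministic tie-breaking

All ties are broken by the fixed label order EB > BE > EE > BB, then by
lexicographic partner id. The label order prefers the two orientations
that keep both scaffolds forward (EB) or both reversed (BE — the mirror
of EB) over the inverting labels, but its real purpose is determinism:
identical inputs give identical assemblies on every run.

## Path extraction and merging

Traversing an edge (i, j) with label XY means leaving i through end X
and entering j through end Y; a scaffold traversed B→E is '+', E→B is
'−'. Chains are walked from free ends; a cycle (every end in the
component saturated) is broken at its lowest-weight edge, weight being
max of the edge's two endpoint scores. Each emitted path is
canonicalised against its mirror (smallest first id, '+' preferred) so
output does not depend on traversal direction. Merging concatenates
member components — reversed and orientation-flipped for '−' members —
with no gap positions in scaffold coordinates: window counting in later
iterations then remains exact, and contact pairs are never rewritten
between iterations (loci are re-mapped through the current component
trees on the fly).

## The iteration loop

Per round: scaffolds shorter than l are set aside (they re-enter
nothing automatically and are reported as unplaced), the graph is built
over the active set, paths are merged, and l grows by the factor 1.4.
Termination: total scaffold count within the configured tolerance
(default 0) of the target chromosome number, or three consecutive
merge-free rounds, or the iteration cap (default 30). If applying every
retained edge in a round would drop the count below the target, edges
are applied in descending weight order and merging stops exactly at the
target.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| initial window l₀ | 50 000 | bp | below the smallest contig sizes the method is built for (≥ 100–200 kb), so no contig is filtered in round 1; small enough that round-1 evidence is strictly local |
| growth | 1.4 | — | doubles the window every two rounds (1.4² = 1.96) |
| weight cutoff w_min | 0.2 | — | one-fifth of a scaffold's top-5 link mass; a true neighbour at adequate coverage scores ≳ 0.35 (observed in the reference simulation), random partners ≲ 0.1 |
| top_k | 5 | partners | candidates entering the score normalisation |
| gap | 100 | bp | N run inserted between joined contigs at build time |
| chromosome tolerance | 0 | scaffolds | "close to the target" margin for stopping |
| max iterations | 30 | rounds | l₀ × 1.4³⁰ exceeds any chromosome length; guarantees termination |

## Simulator

The generator draws, per contact pair: a chromosome proportional to
length; a cis distance x with **joint locus density ∝ x^(−α)**
(α = 1 by default, truncated below x_min = 1 kb where the law
diverges), realised by inverse-CDF sampling of x^(−α) thinned with
acceptance probability (L − x)/L and a uniform feasible left endpoint —
the thinning matters, because without it pairs spanning nearly the
whole chromosome concentrate between the two chromosome termini and
create a spurious terminus-to-terminus link stronger than true
junctions. Trans pairs (probability 0.05 by default, the order observed
in clean Hi-C libraries) place both loci uniformly on two distinct
chromosomes. Long-range enrichment blocks multiply the sampled
background count inside a chosen interval-pair rectangle by a
weight factor, emulating TAD/compartment contact structure; they are a
deliberately adversarial feature for stress-testing, not part of the
clean reference conditions.

The simulator emulates only the statistical structure the scaffolder
consumes. It does not model reads, ligation junctions, restriction
fragments, mapping error, duplicates, coverage waves, or
assembly-error contigs; passing tests therefore demonstrate the
correctness of the ordering/orientation/clustering machinery under the
assumed contact statistics, not robustness to mapping artifacts of
real libraries.

## Evaluation

Junctions (adjacent contig pairs in an assembled layout) are classified
against the truth with priority translocation > inversion > relocation;
a junction is correct iff the two contigs are truth-adjacent in the
direction their orientations imply. The rule is invariant under
mirroring a whole scaffold — equivalent to normalising scaffold
orientation before counting — so the chromosome-scale mirror ambiguity
that Hi-C evidence cannot resolve is never penalised. Unplaced contigs
are excluded from junction statistics and reported as a completeness
fraction.

The edit distance uses four edits: split a scaffold between two
contigs, join two scaffold ends, move a contiguous block, invert a
contiguous block. States are mirror-canonical (a scaffold is identified
with its mirror, scaffold order and names ignored); for the move edit
the block may land in either orientation — on mirror-canonical states
an orientation-preserving move on one representative is a flipped move
on the other, so only the orientation-free move is well defined. All
four edits are invertible, which permits bidirectional breadth-first
search: exact for universes of at most 8 contigs (configurable), with a
state-count cap that falls back to the upper bound. The bound first
greedily applies block inversions while any strictly reduces the
incorrect-junction count (inverting a block changes only its two
boundary junctions), then splits at every remaining incorrect junction
and rejoins the truth-consistent fragments chromosome by chromosome.
Results carry an exact/bound flag.

## Problem sizes used in tests and acceptance runs

The reference recovery experiment uses 5 chromosomes × 2 Mb split into
100 kb contigs with 500 000 pairs (≈ 250 triangle-window pairs per true
junction at l₀ = 50 kb) — comfortably above the ~30-pairs-per-junction
regime where assignment becomes noisy, and small enough to run in
seconds. The subsampled benchmark draws 25 samples of 5 chromosomes
from an 8 × 1 Mb genome. The decay-slope check uses a single 10 Mb
chromosome at 10⁶ pairs so the (L − x) finite-chromosome factor is
negligible over the fitted 10 kb–1 Mb range.

## Known limitations

- The triangle-vs-square ablation at the reference coverage assembles
  cleanly under both windows even with 20-fold enrichment blocks: with
  ~250 pairs per true junction, per-end retention is hard to flip. The
  triangle advantage at these conditions shows up in the window
  coefficient-of-variation diagnostic (`window_cv`: corner blocks
  inflate the square CV, not the triangle CV) rather than in error
  counts; error-count separation requires sparser coverage or weaker
  junction signal than the reference conditions produce.
- Input contigs are trusted: mis-joins inside a contig are neither
  detected nor broken.
- Short scaffolds filtered by a growing window never re-enter the
  assembly and are reported unplaced.
- The greedy edit-distance bound is not tight for rearrangements that
  a single block move would fix across scaffolds.
- No contact-matrix normalisation (ICE/KR) is applied; raw counts are
  assumed comparable across ends, which holds for the simulator but
  only approximately for real libraries.
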