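# Methods

This note records the modelling and numerical choices behind `graphmsa`,
in the order the pipeline runs, together with the choices that were
genuinely open and how they were settled.

## Pairwise alignment

Gap convention: a gap of length L costs `gap_open + L * gap_extend`
(opening charged once per gap, extension per gapped residue), so with the
default −13/−1 a single-residue gap costs −14.  This is stated explicitly
because the two published numbers alone do not pin the convention down;
every score in the package and every test oracle uses it.  Terminal gaps
are charged full affine cost by default — the simplest reading of a
global Gotoh alignment — with `ScoringParams(free_end_gaps=True)`
available where semi-global behaviour is wanted.

The DP is a three-state Gotoh recursion (match, gap-in-b, gap-in-a) with
row-vectorized NumPy fills; gap-to-gap transitions are excluded, which is
lossless here because the worst BLOSUM62 substitution (−4) always beats
two adjacent gap openings (2 × −14).  Traceback tie-breaking is diagonal
over vertical over horizontal, making reported segment matches
platform-independent.  Suboptimal local alignments use Waterman-Eggert
declumping at the level of reported residue *pairs* only (forbidding the
pairs, not whole rows/columns), so later local alignments may overlap
earlier ones on one sequence — intentionally, as the top-4 local matches
are meant to capture repeated motifs.  LCS ties resolve toward the
earliest coordinates in the first sequence via a suffix-table walk.

All three aligners are checked against independent brute-force oracles
(recursive enumeration for global, substring-pair enumeration composed
from the global oracle for local, subsequence enumeration for LCS) on
random pairs of length ≤ 6.

## Graph construction

Refinement propagates cut points through matches to a fixed point; each
match is then split at every interior cut projected from either of its
sides.  Because all match endpoints are cut points, segments on one
sequence afterwards either coincide or are disjoint, and the multiset of
aligned residue pairs is conserved exactly (asserted over 500 random
match sets).

Edge weighting is per residue pair: BLOSUM62 entry + offset, summed over
the pair's positions.  The offset is +5, the smallest shift making every
entry strictly positive (minimum entry −4 → +1).  Non-canonical residue
letters (B, Z, U, O, J) are mapped to X on input with a warning so matrix
lookup can never fail.  Evidence from different sources landing on the
same refined vertex pair is merged **by summing** — the natural analogue
of pooling pairwise libraries; counting repeated support once was the
alternative and was rejected because it discards the multiplicity signal.
One consequence, worth knowing when reading edge weights: a duplicate
match contributes double weight.

Whether edge weight should live on whole segments or on residue pairs is
not observable from the outside; the per-residue-pair sum is the only
mode implemented, and the progressive DP spreads each edge uniformly
(w/length per pair), which makes the two views equivalent on refined
graphs.

## Score transformations

All transforms compute from a frozen snapshot of the input weights and
apply updates at the end, so results are independent of edge iteration
order.  The triplet update adds `min(w(u,x), w(v,x))` over common
neighbours x; the edge-creating variant additionally connects unconnected
different-sequence pairs with a common neighbour (never same-sequence
pairs).  On a refined graph every edge joins equal-length vertices, so
any two vertices sharing a neighbour have equal lengths and created edges
are always well-formed; the code still guards the impossible unequal
case by skipping it.

The neighbourhood-consistency transform needed a normalisation decision:
"common neighbours relative to the total neighbours of the pair" is read
as the Jaccard index of the two neighbour sets with the endpoints
themselves excluded, scaled ×100 and rounded to the nearest integer so
the weights stay commensurate with the integer substitution weights.
The sum-of-degrees denominator was the rejected alternative; the choice
is isolated in one function and deliberately not configurable.

The clique transform builds a maximum-weight spanning forest with
Kruskal's algorithm (edges in decreasing weight, ties in lexicographic
vertex order → deterministic forest) and weights each new pair by the
weakest link of its tree path; by the classic maximin property this
equals the best bottleneck over *all* paths in the component, which is
what the property tests assert against a simple-path enumeration oracle.

## Guide trees

Distances are `1 − identity`, with identity defined as identical aligned
pairs over all aligned (non-gap) pairs of the optimal global alignment.
Dividing by the shorter sequence length instead was considered and
rejected: it conflates divergence with indel content, which the gap
economics already handle.  Without global alignments the fallback is
k-mer counting with k = 3 (shared k-mer multiplicity over the smaller
k-mer count); k = 3 is the conventional protein choice — the 20-letter
alphabet makes 3-mers specific enough at these lengths.

All five clustering methods break ties toward the lexicographically
smallest label pair.  Agglomerative merge heights are half the merge
distance; neighbor joining roots between the last two nodes joined and
clamps negative branch lengths to zero at output only (topology
unaffected).

## Progressive alignment and refinement

The merge DP works at column granularity rather than on segments: on a
refined graph the objectives coincide and column DP is far easier to
verify.  Gaps cost zero at the profile level — all gap economics live in
the edge weights.  Tie-breaking: columns are paired only when the pairing
carries positive benefit (an equal-scoring gap route always exists
otherwise), so profiles with no connecting evidence concatenate
deterministically, left block first.  All-gap columns are dropped as they
arise.

The refiner optimises the realized graph weight — the same currency the
consistency transforms manipulate — because that makes "consistency
before alignment" and "refinement after alignment" directly comparable
strategies.  Acceptance requires *strict* improvement; accepting ties
would allow cycling and break reproducibility.  Random bipartitions
assign each row to a side with probability ½ and resample degenerate
draws; tree-guided refinement cuts either a uniformly random tree edge
per iteration or every edge once in breadth-first order (root's children
first, left before right).

## Evaluation

SP counts reference residue pairs reproduced by the test alignment,
restricted to annotated core columns when an annotation is supplied.  A
reference column is TC-correct when all its non-gap residues are mutually
aligned in one test column; rows gapped in the reference column are
ignored rather than allowed to veto — reference tooling differs on this
point, and the non-veto reading keeps TC a function of the reference
column's own members.  FD/FM are the same correct-pair count normalised
by reference and test pairs respectively, reported as fractions
internally and ×100 at the CLI.  A 2-sequence reference makes SP the
pairwise Q score; no separate code path exists.

## Synthetic families

The generator evolves an ancestor (default 100 residues, uniform over the
20 amino acids) down a uniformly random rooted binary topology.  Per
branch, each site substitutes with probability `sub_rate`, the
replacement drawn with probability ∝ exp(BLOSUM62 score) excluding the
current residue; indel events occur at `indel_rate` expected events per
site, insertion or deletion with equal probability, lengths geometric
with mean 2.  True-alignment columns are tracked through every event, so
the truth is exact, and independent insertions in sibling lineages occupy
distinct columns (they are not homologous and must not be aligned).

The presets were calibrated by sweeping `sub_rate` against realized mean
pairwise identity: `superfamily` (sub 0.20, indel 0.015) lands at ~41%
identity, `twilight` (sub 0.42, indel 0.03) at ~21%, matching the
identity regimes the preset names refer to.  What the generator does
*not* emulate: rate variation across sites, conserved blocks/domains,
large terminal extensions, compositional bias, and over-represented
subfamilies.  Recovery results on these families therefore demonstrate
correctness of the machinery and the expected *ordering* of strategies
(consistency and tree refinement help most at low identity), not absolute
accuracy on real structural benchmarks.

## Problem sizes

Default experiment sizes are chosen for desk-scale reproducibility:
8-sequence families of ~100 residues, 10 families per preset in the
summary script, 20 seeds in the end-to-end recovery check, pairwise
oracle sweeps at length ≤ 6 where exhaustive enumeration is exact.

## Known limitations

Residues not covered by any segment match have no vertices and can only
be placed by gaps; with very sparse sources (e.g. LCS only) large parts
of the sequences carry no signal.  The progressive step is a heuristic
for the NP-hard maximum weight trace; no optimality is claimed beyond
the per-merge DP.  The clique transform densifies components
quadratically and is impractical on large graphs — included because it
is one of the compared strategies, not because it is recommended.
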