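# Methods

This note documents the models, numerical choices and limitations behind
`ribophylo`, in the package's own terms.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Substructure decomposition

A secondary structure is a sequence plus a non-crossing pair map
(1-based, closed intervals).  Maximal runs of stacked pairs form
ladders; a **helix region** is a chain of ladders linked only through
fully unpaired runs (bulges/interior loops).  Multibranched loops and
pseudoknotted positions break the chain.  Within a region, each ladder
is an S substructure (length in base pairs, two complementary spans),
each flanking unpaired run between consecutive ladders is a B (one per
strand pass, so an interior loop contributes two B segments), and the
run enclosed by the innermost ladder — if fully unpaired — is the H.
Everything else (exterior runs, multiloop runs, runs containing
pseudoknotted bases) is U.  The decomposition is a partition: summing
segment lengths with S counted on both strands recovers the sequence
length exactly, and the test suite asserts this on every fixture.

Pseudoknot pairs (brackets `[]`, `{}`, `<>`) are parsed and retained
but never form stems; they only delimit regions.  Parsing is lenient
about hairpin size (a 2-nt loop parses fine); a strict
`validate(min_hairpin=3)` check is available, and the folding baseline
enforces `min_loop=3` as its default.

Aligned data enter through a helix-map TSV (`taxon<TAB>slot...`, cells
= segment lengths).  This dialect replaces legacy structure-alignment
formats: the unit of information in this analysis is the per-slot
segment length, so carrying lengths directly is lossless for the
purpose and trivially diffable.  The loader synthesizes canonical
aligned structures (G/C stems, A loops, `-` padding) realizing those
lengths, so every downstream consumer sees ordinary structures and the
TSV round-trips exactly.

## Character coding and polarization

Lengths map to a 64-state ordered alphabet (`0–9`, `A–Z`, `a–z`, `@`,
`&`) by state index = length, saturating at index 63 (`&`).  The
saturation point is a documented choice: the alphabet offers 64 states
on a 0-based scale, so lengths 63 and above share the top state, which
keeps the map total and monotone; a `cap_at` knob moves the boundary.
Absent segments code as the minimum state `0`.

Polarization defaults to **max_ancestral**: the maximum observed state
of each character is declared ancestral.  This is the package's reading
of the premise that evolution proceeds towards increased conformational
order, and it matches the census convention where the maximal state `K`
is explicitly the most ancient.  The direction is configurable
(`min_ancestral`, `fixed:<symbol>`) because the premise, not the
machinery, is the scientific commitment; the synthetic generator has an
inverted mode to exercise the opposite direction.

## Parsimony engine

Characters are linearly ordered (Wagner): the cost of changing state
index *i* to *j* is `|i − j|`.  Tree length is Sankoff dynamic
programming; for this cost the node update is a min-convolution
computed with one forward and one backward sweep over states, so a
length evaluation is O(nodes × states × characters) in vectorized
numpy.  State vectors are truncated at the maximum observed (or
ancestral) index, since no optimal internal state exceeds it.

The search is stepwise addition followed by TBR branch swapping.
Addition inserts taxa in matrix row order ("simple" addition; random
permutations with restarts are available) at the cheapest branch.  TBR
bisects every edge and evaluates every reconnection pair using
precomputed edge-rooted cost vectors on both fragments, so one
reconnection costs O(states × characters) rather than a full re-score.
Sweeps accept the first improvement in canonical edge order and repeat
until no rearrangement shortens the tree — a deterministic rule that
doubles as the tie-break.  All distinct equally most-parsimonious
topologies reachable at the final length are collected, capped at
`maxtrees` (default 1,000) with a warning when the cap binds.

Fit statistics: CI = Σmin/L and RI = (Σmax − L)/(Σmax − Σmin) with
per-character min = the state range (no tree can bridge it for less)
and max = the star-tree cost (attained at the median state); HI = 1 −
CI by construction.  g1 is the adjusted Fisher–Pearson (small-sample
corrected) skewness of tree lengths over uniformly random topologies
(default 1,000), generated by sequential random-edge insertion, which
is uniform over unrooted binary shapes.

Rooting is Lundberg: a hypothetical taxon carrying every character's
ancestral state is scored against every branch, the cheapest branch
receives the root, and the hypothetical leaf is discarded.  Ties break
to the first branch in canonical order and are reported on the returned
tree (`root_attachment_ties`) and as a warning.  Ancestral states for
internal nodes are one minimum-cost Sankoff backtrace (ties towards the
smaller state index); the implied cost equals the tree length, which
the suite asserts on random fixtures.

Bootstrap resamples characters with replacement per pseudoreplicate
(the ancestral-state row is resampled in step), searches each
replicate, and reports majority-rule consensus supports in [0, 100].
Strict consensus retains exactly the bipartitions common to all input
trees.  Tree containers are `dendropy.Tree`; consensus and
Robinson–Foulds comparisons work on canonicalized bipartition sets.

## Chronology

For a rooted tree, nd(leaf) counts internal nodes strictly between the
root and the leaf, normalized by the maximum count: the most recent
leaf has nd = 1, and a leaf attached at the root split has nd = 0.  The
imbalance statistic N-bar instead counts the root itself (mean
root-to-leaf internal-node count over leaves), following the usual
definition of that statistic; both conventions are unit-tested so the
off-by-one cannot drift.  A tree whose leaves are all equidistant
yields a flagged, all-zero chronology rather than an error.

Null ensembles: Yule trees grow by splitting a uniformly chosen tip
until the target leaf count; uniform-random rooted topologies come from
uniform unrooted topologies on n+1 leaves re-rooted on the extra leaf's
edge.  Monte-Carlo p-values are two-sided with the +1 correction.  The
Yule cherry expectation n/3 is used as an external check of the
simulator, not assumed anywhere.

Timelines date each bridge by the nd of its acceptor element (default)
or by the older-of-pair maximum (`bridge_rule="max"` — both readings of
"first acceptor element" are exposed); contacts take their helix's nd.
Events sort by nd with ties broken lexicographically by id, and the
output is a permutation of the input annotations.

Protein ages: a protein takes the age of its *youngest* member domain
(largest nd_P) — a fusion cannot predate its newest part.  A known
domain-combination age is never substituted for the domain-based age;
if it postdates every member domain the result is flagged so the caller
can inspect the rearrangement scenario.  The early-era link between the
rRNA and protein timelines is ordinary least squares on (nd, nd_P)
pairs (default era cutoffs nd ≤ 0.35, nd_P ≤ 0.2, overridable), with
R², and F = (n−2)·R²/(1−R²); interpolation maps a query through the
fitted line in either direction.

Heat-map color tables bin values at 0.01 (101 bins) into a matplotlib
colormap sampled at 101 points (default `bwr`, a blue→red scale).  The
table, not the particular colors, is the contract; nd_P maps are
min-max rescaled to [0, 1] first.

## Domain census

Gap coding uses the natural-log transform
`round(20·ln(g+1)/ln(g_max+1))` with half-up rounding (pinned by a test
at an exact .5 boundary) and per-proteome `g_max`; a linear variant and
per-table normalization sit behind flags.  All-zero proteomes are
dropped with a warning; an all-zero domain is retained and codes as
state 0 everywhere (it is simply the youngest possible taxon).  The
transform is only approximately scale-free: multiplying a proteome's
counts by a constant can shift the smallest counts by more than one
bin, so the robustness test asserts exact invariance for the linear
scheme and the ≤ 1-bin property for moderate counts under the log
scheme.  Domain ages chain the census matrix (domains as rows) through
the search → all-`K` Lundberg rooting → node distance pipeline.

## Structure similarity

Structures convert to ordered forests (P node per pair with enclosed
children, B node per unpaired base).  The local score is the maximum
global tree-alignment score over all pairs of closed subforests
(contiguous sibling ranges), floored at 0, under structure-only
scoring: P–P match +10, B–B match +1, node deletion −5, P–B
substitution disallowed.  Sequence identity is deliberately ignored.
The absolute scale is arbitrary — it cancels in the Z-score, which is
the actual contract — and all weights are configurable.

Significance: the target sequence is shuffled preserving exact
dinucleotide counts (Eulerian-multigraph last-edge algorithm; first and
last residues fixed; the count vector is asserted on every call), each
shuffle is refolded, and the query is realigned.  Folding is base-pair
maximization (Nussinov) over Watson–Crick plus G·U pairs with
`min_loop=3` and a deterministic leftmost-pairing traceback; a caller
can plug an external thermodynamic folder through the `folder` hook.
Shuffled targets are aligned against the *raw* query (the documented
default; refolding the query too is the caller's choice).  Z = (score −
null mean)/null sd, significant at Z ≥ 3.0; a zero-variance null leaves
Z undefined and the pair non-significant, flagged by `null_sd = 0`.

## Synthetic data

The accretion generator represents what the pipeline needs from real
structural alignments and nothing more: a Yule guide tree over
organisms; helices h1…hK with a random birth-rank permutation; baseline
stem length decreasing linearly from `base_stem + K − 1` (rank 1,
oldest) to `base_stem` (default 4, so a 20-helix run spans 23…4 bp,
rRNA-stem-like sizes); constant hairpin (4 nt) and unpaired (2 nt)
baselines; and per-branch ±1 length drift with probability scaled from
0.5·p (oldest) to 1.5·p (youngest) around the default p = 0.1, so older
helices are both longer and quieter — the generator's encoding of the
polarization premise.  Defaults (30 taxa × 20 helices) are the study
conditions for the recovery checks.  What it does **not** emulate:
realistic base composition, helix gain/loss across lineages,
covariation structure, alignment error, or rate heterogeneity beyond
the age-scaled drift.  Recovery tests therefore show that the pipeline
inverts its own generative premise faithfully, not that real rRNA data
satisfy that premise.

The census generator draws domain ages uniformly on [0, 1] (1 =
oldest), presence with probability rising linearly from 0.3 to 1 with
age, and abundance 1 + Poisson(exp(0.7 + 2·age)) given presence —
spanning roughly 2–15 copies, with age-abundance coupling strong enough
to carry tree signal at the default 50 proteomes × 30 domains.  β = 0
with full presence is the negative control: no recoverable order.

Toy fixtures include a 5-taxon × 4-character matrix whose
most-parsimonious length (5) equals its per-character lower bound, so
the value is provable by hand and doubles as an exhaustive-search
oracle; and a planted structural homolog (12-bp mixed-composition stem
with a GAAA loop embedded in a ribozyme-like part) that the default
screen flags at Z ≈ 5 while an unpairable control sequence yields a
degenerate (all-equal) null and no call.

## Problem sizes and seeds

Every stochastic component takes an explicit seed; the pipeline derives
per-stage child seeds deterministically from one global seed, and rerun
bundles are byte-identical (asserted in the suite).  The test suite and
the acceptance script size their simulations for a single CPU: 20
accretion seeds at 30 × 20, a handful of census runs at 50 × 30,
1,000-shuffle screens for the planted pair, and 60–100-shuffle screens
for the shuffled-self controls — sizes at which the Monte-Carlo errors
are far smaller than the effects being checked.

## Known limitations

- The search is heuristic; optimality is only guaranteed against the
  exhaustive oracle at ≤ 7 taxa, and the equal-best tree collection
  explores one TBR neighborhood around each local optimum.
- Bootstrap replicates reuse the same (input-order) addition sequence;
  support values at the default settings are meant for synthetic-scale
  matrices, not publication-scale reanalyses.
- The forest-alignment memoization is exact but unbounded; very large
  or deeply branched structures (hundreds of nodes) will be slow.
- nd is a node-count clock: it assumes cladogenesis density tracks
  time, which holds for the highly unbalanced trees this method
  produces but is not enforced.
- No thermodynamic folding, no maximum-likelihood ancestral sequences,
  no 2D/3D rendering: ancestral inputs to the similarity screen come
  from the parsimony reconstruction or from the caller.
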