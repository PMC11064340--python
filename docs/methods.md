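# Methods

This note documents the models, conventions and design choices behind
`structphy`, in the order data flows through the pipeline.

## Sequence-structure encoding

A structured record is an RNA string over {A,C,G,U,N} plus a dot-bracket
string of equal length with balanced, nested brackets (pseudoknot
bracket families are rejected: the encoding models nested pairing only).
Each position's (nucleotide, structural state) pair maps to one letter
of a 12-letter alphabet; the default code keeps A/C/G/U for unpaired
positions and uses B/E/H/K (opening) and D/F/I/L (closing).  The code is
injective, so encoding is lossless and `decode(encode(x)) == x`; an
alternative published code can be loaded from a 12-line text file
(`nucleotide state letter`).  `N` encodes to a dedicated unknown symbol
regardless of state — the structural state at an `N` is deliberately not
preserved, so a record with `N` inside a helix decodes to a half-pair;
validation and distance computation treat the unknown symbol as missing
data throughout.

Input records are validated on read: length mismatch between sequence
and structure ("uneven length"), unbalanced brackets, characters outside
the alphabet, and duplicate ids are rejected with the record named. The
pipeline excludes failing records and lists them in its report rather
than aborting, as curated rRNA sets routinely contain a few such
records.

## Alignment

Pairwise alignment is global (Needleman–Wunsch sense, terminal gaps
penalized) with affine gap costs via a three-state Gotoh DP; a gap of
length L costs `gap_open + (L-1)·gap_extend` (defaults 8 and 1).
Traceback ties resolve diagonal > up > left, making output byte-stable.
The default 12×12 matrix decomposes additively — +2/−1 for nucleotide
agreement/disagreement plus +2/−1 for structural-state agreement — so
structure agreement is rewarded independently of sequence agreement;
the unknown symbol scores 0 against everything.  A full matrix can be
loaded from a file (first line alphabet, then a lower triangle).
Nucleotide mode uses match +2 / mismatch −1 over {A,C,G,U,N}.

Multiple alignment is progressive: UPGMA guide tree on
1 − pairwise-identity distances, then postorder profile–profile merges
where a column pair scores the frequency-weighted expected letter score
(gap mass contributes nothing) under the same affine gap costs.  Gaps
once introduced are never removed, and the de-gapping invariant (each
row reproduces its input exactly) is asserted after every merge.  The
aligner is exact for two sequences and heuristic beyond; tests compare
it against exhaustive small-instance enumeration and an independent
pairwise implementation.

## Distances and profiles

Distances are mismatch fractions with pairwise deletion (positions with
a gap or unknown in either row are skipped), corrected by the k-state
Jukes–Cantor transform d = −((k−1)/k)·ln(1 − k·p/(k−1)), with k = 4
(nucleotide) or k = 12 (encoded).  p at or beyond (k−1)/k raises a
saturation error by default; the pipeline uses the `cap` policy, which
assigns such pairs the correction evaluated just inside its domain
(≈ (k−1)/k · ln 1000 substitutions/site), keeping matrices finite while
preserving "very far" ordering.  Raw p-distances are available behind a
flag.

A profile summarizes a group of rows as per-column state frequencies
normalized over the informative (non-gap, non-unknown) mass, with the
missing fraction recorded separately.  A column is comparable between
two profiles when both have informative mass > 0.5; the expected
mismatch 1 − Σ_s fP(s)·fQ(s), averaged over comparable columns, is then
JC-k corrected.  On singleton profiles this reduces exactly to the
sequence distance, and merged profiles re-aggregate raw counts so the
member-count-weighted averaging identity holds exactly on gap-free data.

## Trees

Neighbor-joining follows Saitou–Nei with the Studier–Keppler Q
criterion.  Ties in Q are broken by the lexicographically smallest pair
of smallest-descendant labels (the Q matrix need not be bitwise
symmetric in floating point, so candidate pairs are orientation
normalized first).  Negative branch lengths are clamped to zero with the
deficit shifted to the sibling edge, preserving the pair sum.  The last
three lineages are resolved by the three-point formulas, giving exact
recovery (topology, and lengths to 1e−9) on additive matrices.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path, ties broken by the smallest leaf pair; if the midpoint falls
exactly on an internal vertex the tree is rerooted there.  Supports are
properties of edges (stored on the child node); when the split edge
carries a support it is kept on one half-edge only, so each bipartition
carries its support exactly once and the average support per node is
invariant under rerooting.  An all-zero-length tree roots at the first
internal node with a warning.

Bootstrap support resamples alignment columns with replacement,
rebuilds a tree per pseudo-replicate with the supplied deterministic
builder, and maps the percentage of replicates containing each internal
bipartition onto the reference tree.  All randomness flows from a
single integer seed.

### Profile neighbor-joining

Round 0 builds the predefined profiles, their distance matrix, the NJ
tree and bootstrap supports (default 100 pseudo-replicates).  Each
subsequent iteration (default 2) takes every *maximal* clade of the
midpoint-rooted profile tree whose edge support is strictly above the
threshold (default 75), merges its profiles into a super-profile with
frequencies re-aggregated from the leaf rows, and re-estimates NJ +
bootstrap over the merged units — the backbone is thus estimated
independently of the topology within each super-profile.  Merging is
applied highest-support-first, then by label order, and never reduces
the unit count below three (NJ over fewer units carries no internal
edge).  The final tree is expanded back to the original profiles:
every super-profile leaf is replaced by its stored subtree, keeping the
branch lengths and supports of the iteration in which it was formed.
An audit trail records, per iteration, the profiles in play, the
support of every bipartition, the merges performed, and the tree.
With all-singleton profiles and an unreachable threshold the procedure
reproduces plain NJ exactly.

Profiles can be supplied explicitly (TSV `profile<TAB>leaf`) —
mirroring manual profile definitions — or derived from a rooted tree:
either a fixed-depth cut, or (the pipeline default) a top-down size
rule that splits clades until each has at most `max(2, ⌈n/4⌉)` leaves
and accepts those with at least `min_size` (default 2).  Leaves left
over are reported as unassigned and excluded from PNJ, matching the
practice of leaving singletons out.  The pipeline roots PNJ trees on
the edge reproducing the overall NJ tree's root bipartition (majority
vote of each profile's members), falling back to the midpoint.  The
"branch-length" output tree is the same final tree serialized without
support labels, so both outputs share one leaf set.

## Parsimony and likelihood

Fitch parsimony counts state-set intersections bottom-up, vectorized
over columns as bitmasks; gaps and unknowns are the full state set.  A
trifurcating root is folded into an equivalent binary rooting (same
unrooted tree, same score).  The search is NNI hill-climbing from an
uncorrected-p NJ starting tree (p is monotone in the corrected distance
and cannot saturate, so the start topology is essentially the NJ one):
all neighbors are scored each round and the best strictly-improving one
is accepted, deterministically, until a local optimum.  This replaces
any particular legacy heuristic; its contract is the score, verified
against a unit-cost Sankoff DP and exhaustive topology enumeration on
small instances.

The likelihood engine is a k-state GTR with proportion-of-invariant
sites and discrete-gamma rates (category rates are the means of
equal-probability bins; 4 categories by default).  The generator
Q = S·diag(π) is scaled so −Σ π_i q_ii = 1; branch lengths are expected
substitutions per variable site, and per-site likelihood is
`p_inv · L_inv + (1 − p_inv) · mean_c L_c`, where L_inv is the
probability of an invariant state compatible with every row.  Gamma
rates are not divided by 1 − p_inv.  Transition matrices come from the
symmetric eigendecomposition of diag(√π)·Q·diag(1/√π); columns are
pattern-compressed before pruning.  This matches phangorn's `pml` to
10 decimals on a frozen GTR(+Γ) fixture.  For k = 12 the default model
uses empirical letter frequencies with equal exchangeabilities
(an F81-style compromise — a 66-parameter GTR on small encoded
alignments would be badly overfit); full exchangeability matrices can
be supplied.

Branch lengths are optimized by coordinate ascent with bounded Brent
search per branch (bounds [1e−9, 20], sweeps until the log-likelihood
gains < 1e−6); the log-likelihood is non-decreasing by construction and
the two-taxon optimum reproduces the closed-form JC distance.
`ml_bootstrap` maps NJ-per-replicate bipartition supports onto the
branch-length-optimized reference tree; replicate branch lengths are
not re-optimized, because supports depend only on replicate topologies
and the optimization would multiply runtime ~100× without changing any
reported value.  Full per-replicate ML topology search is out of scope.

## Consensus structures

For each ordered column pair (i, j), the consensus frequency is the
number of rows whose residues at i and j are base-paired, divided by
the number of *all* rows — a row gapped at either column counts as
absence, so the 100% consensus means literally "all taxa pair here".
(A denominator restricted to rows ungapped at both columns is available
behind a flag.)  Pairs with frequency ≥ threshold − 1e−12 are kept; the
epsilon avoids float-boundary misses at exactly 75%.  By construction
the 100% set is nested inside the 75% set.  For rendering, pairs are
admitted by decreasing frequency (then left column); any pair sharing a
column with, or crossing, an admitted pair is dropped and reported, so
the dot-bracket output is always balanced and nested.  Mapping onto a
reference renumbers columns to the reference's ungapped coordinates;
pairs touching a reference gap are reported unmappable, and mapped +
unmappable always equals the input count.

## Simulator

The generator emulates a homologous, structure-constrained RNA family:
a Yule pure-birth tree (birth rate 1.0) rescaled so the mean
root-to-tip path equals `scale`; a nested hairpin template (stems of
3–8 pairs, loops of 3–8 nt, geometric spacers) with roughly half the
positions paired, as in small-subunit rRNA; root states uniform, with
paired sites initialized Watson–Crick.  Unpaired sites evolve by
4-state Jukes–Cantor at rate `mu_unpaired` (closed form per branch).
Paired sites evolve event-wise: substitution events arrive as a Poisson
process at the same per-site rate on both partners, and each event
restores Watson–Crick complementarity of the partner with probability
`compensation` — event-based simulation makes that probability exact
per event rather than approximate.  Each taxon's *reported* structure
is the template minus pairs it loses independently with probability
`struct_noise` (dropped pairs become dots), giving per-taxon individual
structures.  No indels are introduced, so the true alignment is the
sequence set itself and tree-inference error is cleanly separated from
alignment error; an aligner-exercising indel mode is intentionally not
part of any benchmark.

Defaults, chosen as the study conditions for all in-silico claims:
`scale = 0.3` substitutions/site root-to-tip (moderate divergence for a
deep single-marker set), `mu_unpaired = 1.0` (rates are relative to
branch lengths), `compensation = 0.9` (stem covariation is strong but
imperfect), `struct_noise = 0.05` (individual structures of real
homologs differ in a few percent of pairs).  The recovery benchmark
runs both arms — plain nucleotide and 12-letter encoded — on the same
simulated records: NJ topology error (Robinson–Foulds to the true
tree) and average PNJ bootstrap support per node, with profiles
auto-derived per replicate and all seeds derived from one integer.

What passing these benchmarks does *not* show about real data: the
simulator has no indels (so alignment quality, a major real-world
advantage of structure-aware alignment, is untested), no
length-variable regions or rate heterogeneity along the molecule, no
G·U wobble pairs, and its per-taxon structure variation is independent
noise rather than heritable change, which if anything handicaps the
sequence-structure arm.

## Problem sizes and numerics

The shipped tests and the acceptance script use desk-scale sizes chosen
to exercise every code path: 20 replicates of 20 taxa × 1000 sites for
the two-arm comparison (with 100 bootstrap pseudo-replicates per PNJ
round), 200 random trees up to 32 taxa for NJ exactness, exhaustive
oracles up to length-6 alignments and 6-leaf topologies, and a full
pipeline determinism check at 10 taxa × 80 sites.  Comparisons of
computed quantities use explicit tolerances stated in each test
(1e−9 branch lengths, 1e−10 log-likelihood identities, 1e−6 for the
optimized branch length).  Known limitations: the progressive aligner
is O(L²) per merge in pure Python and is meant for desk-scale inputs;
NNI-only search can stop in local parsimony optima; ML supports reuse
NJ replicate topologies rather than per-replicate ML searches; and the
saturation cap, while order-preserving, compresses differences between
extremely divergent pairs.
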