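# Methods

## Graphlets, orbits and the counting model

A graphlet is a small connected non-isomorphic *induced* subgraph of the
host graph; induced means all host edges among the chosen nodes are part
of the instance, so a node triple that closes into a triangle is never
also counted as an open triad.  We enumerate all classes of 2–4 nodes
(and, for the atlas only, 5 nodes): at size 4 there are 9 classes with
15 node orbits and 13 edge orbits; extending to size 5 gives 30 classes
and 73 node orbits.  Orbits are equivalence classes of node (or edge)
positions under each class's automorphism group, computed exactly by
brute-force permutation — at ≤ 5 nodes this is cheap and has no failure
modes, so no canonical-labelling heuristics are involved.

Class numbering for sizes 2–4 follows the classic convention (G0 edge,
G1 3-path, G2 triangle, G3 4-path, G4 3-star, G5 4-cycle, G6 tailed
triangle, G7 4-chordal-cycle, G8 4-clique).  Within the sort key we
order classes by size, then edge count, then descending degree sequence,
which reproduces that convention; node orbits within a class are ordered
by representative degree (ascending), which pins the standard ids
(orbit 3 = triangle node, orbit 13 = diamond hub, orbits 9/10/11 = tail,
rim, hub of the tailed triangle).  Size-5 classes get a deterministic
but library-internal order: no published enumeration is reproduced
there, only the totals.  Tie-breaks beyond degree (possible at size 5)
fall back to neighbour-degree profiles and canonical node index.

### Egocentric restriction

An ego network has a focal node adjacent to every other node.  Of the
nine classes only seven admit such a dominating position (the 4-path and
4-cycle do not), and with the ego position fixed there is no orbit
distinction left, so egocentric vectors have 7 entries.  Egocentric
counting happens inside the ego's 1-hop induced subgraph; the ego's
pairs and triples of alters enumerate every instance, and the induced
alter–alter edges decide the class (0/1/2/3 closing edges among a triple
give 3-star / tailed-triangle / 4-chordal-cycle / 4-clique).  The
2-path graphlet counts the ego in the middle position only — the end
position does not dominate.

## Typed-edge vectors

Edge-type labels are registered once and mapped to dense codes
`0..|Te|−1` in sorted label order (reproducibility across runs and
platforms; the ordering itself is arbitrary).  Untyped edges carry a
sentinel code `|Te|`.  The typed-edge GDV adds a type dimension: every
edge of every detected instance — not only edges at the focal node —
adds one to its (orbit, type) cell.  Consequently the row sums obey
`Σ_t vec[o,t] = m(o)·GDV[o]` with `m(o)` the edge count of orbit `o`'s
graphlet, an identity the tests assert whenever the sentinel column is
included.

`include_sentinel` (default true) keeps that identity; setting it false
drops untyped edges from the tally, which matches ego-network surveys
where only ego–alter ties are typed, and intentionally breaks the
identity.  For the colored/heterogeneous variants an instance key is the
set (respectively sorted multiset) of its edge types; with the sentinel
excluded, an instance whose edges are all untyped has no admissible key
and is skipped.

The key spaces are `C(g) = Σ_{n=1..min(K,T)} C(T,n)` for colored and
`H(g) = C(T+K−1, K)` for heterogeneous, with `K` the typed slots and `T`
the type count.  `H ≥ C` always; equality holds exactly when repetition
adds nothing, i.e. `K ≤ 2` or `T = 1` (for `K = 2` the multisets
`{t,t}`/`{s,t}` biject with the subsets `{t}`/`{s,t}`).  Dense layouts
enumerate admissible keys in lexicographic order over sorted tuples.
For large `T` the dense spaces are impractically wide (hundreds of
thousands of columns at `T = 13`), so the feature transformer builds
its column vocabulary from the keys observed at fit time instead;
dense export remains available through `dense_index` for small `T`.

## Fast counter vs. oracle

The production counter enumerates instances at a focal node `u` by a
case analysis over how many instance nodes are neighbours of `u`:
neighbour pairs/triples (`C(N_u,2)`, `C(N_u,3)`), pairs plus one
outside node reached through them, and single neighbours with two
outside nodes.  Each connected induced subset containing `u` is produced
exactly once and classified by which edges close, never through graph
isomorphism at runtime.  The size-4 triple loop visits exactly
`Σ_u C(deg u, 3)` triples, which the suite asserts as the enumeration
budget.

The oracle is an entirely independent route: it filters *all* node
subsets of sizes 2–4 containing the focal node for connectivity and
classifies each instance through the atlas by permutation matching.
The acceptance suite requires cell-for-cell agreement of all six vector
families on 207 random typed graphs (n between 6 and 14, edge densities
0.15/0.3/0.5, type counts 1/3/13), alongside closed forms for complete
graphs and stars up to n = 10 and the marginalization identities.  The
oracle is O(n³) per node by design and is capped at small n; it exists
for exactness, not speed.

## Synthetic cohort

The generator emulates the shape of an egocentric social-support survey
of chronic-pain patients: 303 egos by default; each ego names up to 10
alters (62% of egos sit at the cap, the remaining mass spread uniformly
over 1–9 alters); each ego–alter tie gets one of 13 social-tie types
drawn i.i.d. with probabilities proportional to the published occurrence
counts (222, 209, 293, 493, 506, 207, 142, 69, 57, 233, 74, 15, 17);
alter–alter ties are untyped (sentinel) and each pair closes
independently with a per-grade probability; the group label is a pain
grade 1–4 drawn with probabilities proportional to 21/33/67/182.

The grade label affects *topology only*: closure probabilities default
to 0.6 / 0.45 / 0.25 / 0.10 for grades 1–4, so low grades produce
clique-like neighbourhoods and high grades star-like ones.  No per-grade
closure densities are published, so these values are free parameters
chosen once to produce that qualitative ordering with a clear margin;
they are configuration, not estimates.  Tie types are independent of
grade by default (the suite checks this with a chi-square test), so any
grade signal in the graphlet features is attributable to the planted
closure gradient.  Randomness uses one master seed with per-ego spawned
streams, making cohorts byte-reproducible and stable under reordering.

What passing tests on this cohort do and do not show: they validate the
counting machinery, the layout contracts and the direction of the
planted structure–label coupling; they say nothing about real survey
data, whose tie types correlate with structure and with the label, whose
alter counts are not i.i.d., and whose raw covariates
(demographics, pain descriptors) the generator does not model — the
classification command is labelled a demonstration for this reason.

## Numerical and design choices

- Counts are exact integers throughout; no floating point enters until
  group averaging and classification.
- Duplicate edges are rejected rather than merged (edges form a set);
  self-loops and directed inputs are errors.
- Targets are processed in sorted node order and results are
  order-independent (asserted); all iteration orders (neighbour sets,
  vocabulary keys) are explicitly sorted so outputs are byte-stable.
- The classification demonstration uses a 100-tree random forest under
  repeated stratified 5-fold cross-validation with macro-F1, with all
  fold and forest seeds derived from one input seed.  Problem sizes in
  the test suite (cohorts of 80–1500 egos, random graphs up to n = 14
  for oracle comparisons) keep the full suite under a minute apart from
  the 207-graph equivalence sweep, which runs in about half a minute.

## Known limitations

- Counters stop at 4-node graphlets; 5-node classes exist in the atlas
  for enumeration totals only.
- Edge orbits are exposed in the atlas but no link-level (edge-orbit)
  counter is built on them.
- No directed, weighted, temporal or multigraph support.
- The dense colored/heterogeneous layouts do not attempt the pruned
  "possible combinations only" vector lengths used in ego-survey
  settings where alter–alter ties are untyped; the observed-key
  vocabulary covers that use case instead.
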