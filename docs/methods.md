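# Methods

## The model

A retrosynthetic problem is an AND/OR graph.  An OR node is a molecule:
it is *provable* (synthesizable) if any one of its candidate reactions
is.  An AND node is a reaction: it is provable only if every reactant is.
Building blocks — commercially available starting materials supplied as a
structure list — are proven terminals.  A *synthetic route* is a proof
tree of this graph: exactly one reaction chosen for each included
non-building-block molecule, every leaf a building block, and no molecule
repeated on any root-to-leaf path.

A *reaction network* is the merge of many routes: OR nodes are unified by
canonical structure (RDKit canonical SMILES for real molecules, the
literal string for the toy backend), AND nodes by the key
`(product structure, template id, sorted reactant multiset)`.  The merge
key is a design choice; nothing finer-grained (atom maps, conditions) is
tracked, so two applications of the same template producing the same
reactant multiset are one reaction node.

## Network construction

`find_route` is a classical depth-first proof-number search: each node
carries a proof number (minimum leaf expansions to prove) and a disproof
number (minimum to refute), updated OR-wise as (min pn, saturating-sum dn)
and AND-wise as (saturating-sum pn, min dn), with the standard
top-two-children threshold scheme.  Infinity is a large finite cap
(`2^32`) with saturating arithmetic.  The transposition table is indexed
by `(structure, depth)` so the depth bound `md` is respected exactly; the
same molecule reached at two depths is two search entries.  `md` counts
reaction steps on the longest target-to-leaf path.  Tie-breaks everywhere
are template rank (frequency order), then insertion order, which makes
search, extraction and serialization fully deterministic — identical
inputs yield byte-identical network JSON.

Proof-tree extraction picks, per molecule, the first proven reaction in
rank order, validating the choice at the molecule's deepest occurrence in
the tree so the extracted route honours `md`.

`build_network` produces the *complete* network within `md` rather than a
single proof.  Because continuing a proof-number search until no new
proof tree remains is equivalent to expanding every node reachable within
the depth bound, the implementation does exactly that: breadth-first
expansion from the target of every molecule whose minimum depth is below
`md` (template application memoised per structure and charged against
`node_budget`; on exhaustion the network is returned flagged
`incomplete`), followed by a bottom-up minimum-synthesis-height pass, and
retention of every decomposition that participates in at least one
depth-valid route.

**Depth soundness vs completeness under merging.**  A structure-keyed
merged network cannot in general satisfy both "every enumerable route has
at most `md` steps" and "every route with at most `md` steps is
enumerable": a synthesis proved at a shallow occurrence of a molecule may
exceed the bound when an enumerated route re-uses it at a deeper
occurrence.  This package makes soundness the hard guarantee: after
assembly, decompositions are pruned to a fixpoint so that for every
molecule, its maximum network depth plus the tallest surviving choice
below it fits within `md`; molecule-level cycles (possible with real
templates, impossible for the strictly-shortening toy rules) are broken
conservatively during the same pass.  Completeness then holds whenever
`md` does not bind — in particular on the bundled toy suites, where `md`
is at least the longest possible route — and is verified there against an
exhaustive oracle.  When `md` binds tightly around shared intermediates,
the network may omit a depth-valid route that would force an
over-depth combination; this is the deliberate trade-off.

## Enumeration

The enumerator implements a binary partition with a prohibited list.  The
state is a set of committed (molecule → reaction) choices plus, per
molecule, a set of prohibited reactions.  At each step the closure of the
target under the commitments is computed, and the first undetermined
choice point in a stable topological order is split: *commit* its first
viable reaction, or *prohibit* it.  The two branches partition the
remaining route set (routes that use that reaction there, and routes that
do not), so no route is emitted twice; a branch in which any included
molecule has no viable reaction left is dead and pruned, so nothing
invalid is emitted; every fully determined assignment is a route, so
nothing is lost.  Emission is lazy — a generator — and each emission
costs time polynomial in network size.

Routes are identified by a canonical key: the frozen set of
`(product, template id, sorted reactants)` triples of the route's
reactions.  The brute-force oracle (`brute_force_routes`) enumerates
every total assignment of reactions to molecules, restricts each to the
closure from the target, validates, and dedupes by the same key; it
refuses instances beyond 10^6 raw assignments.  `count_routes` counts by
enumeration with an abort cap (default 1,500,000) and probes one extra
route so the `capped` flag means "more routes exist than the cap".

The naive sum/product recursion (`naive_route_count`) is kept as a
diagnostic: it equals the exact count exactly when no molecule in the
route-reachable subgraph feeds two reactions, and never undercounts.
Counts are arbitrary-precision integers — products overflow 64 bits
quickly on realistic networks.

## Template engines

Two backends satisfy one contract (`canonicalize`, `apply_retro`,
`forward`, fingerprints):

* **RDKit backend** — retro transforms are reaction SMARTS
  `product>>reactants` run with RDKit's reaction machinery.  Proposals
  are canonicalized, symmetric-match duplicates collapsed (same reactant
  multiset from different atom embeddings), and relevance-checked: the
  forward reaction (sides swapped, every reactant ordering tried) must
  regenerate the product's canonical structure, otherwise the proposal is
  discarded and logged.  Stereochemistry survives canonicalization where
  the SMARTS preserves it.
* **Toy backend** — molecules are token strings; a k≥2-reactant rule
  `f1f2>>f1.f2` cuts the product into k consecutive non-empty parts with
  part *j* containing fragment *j*; a 1-reactant rule `lhs>>rhs`
  (strictly shorter `rhs`) replaces one occurrence.  Every rule strictly
  shortens, so expansion terminates within `len(product)` steps and the
  molecule graph is acyclic by construction.  This backend exists so the
  search and enumeration layers can be tested end-to-end against an
  exhaustive expansion oracle with no chemistry toolkit in the loop.

Template files are TSV (`id, name, retro_smarts, frequency`); templates
are ranked by descending frequency, those with more than three reactant
patterns are dropped with a warning count, unparsable rows are collected
per-row, and a duplicate id is fatal.

## Scoring

* **STEP** — the longest target-to-leaf path in reactions.  The phrase
  "longest number of synthesis steps" could also mean total reaction
  count; the longest-path reading is the default and `mode="total"`
  exposes the alternative.
* **MSCS** — arithmetic mean of a complexity scorer over the route's
  *distinct* molecules (a shared intermediate counts once, consistent
  with routes being defined over merged nodes); bounded in [0, 5] when
  the scorer honours its contract, else clamped with a warning.  The
  scorer is pluggable.  The default is a transparent structural
  heuristic, `5·(1 − exp(−(heavy atoms + 2·rings)/25))`: deterministic,
  bounded in [0, 5), and strictly increasing under chain extension.  It
  is a stand-in with the right shape, not a trained model; any callable
  mapping structures into [0, 5] (e.g. a learned complexity score) can be
  dropped in.
* **REF** — both routes' distinct molecules are sorted by molecular
  weight (ties by structure string, for determinism), paired
  positionally, and the Tanimoto similarities of their fingerprints
  summed; 0 when the list lengths differ.  The default fingerprint is the
  2048-bit RDKit path fingerprint as a bit set; the function is a
  parameter, and the toy backend uses token sets.  Two empty bit sets
  have similarity 1 by convention.

Ranking sorts ascending for STEP and MSCS, descending for REF, with ties
broken by route id.

## Route fingerprints and embedding

A route fingerprint is the elementwise sum of its templates' structural
reaction fingerprints, with multiplicity — a template used twice
contributes twice (the summation is over the reaction multiset).  The
RDKit backend uses the structural reaction fingerprint (4096 bits); the
toy backend uses a token histogram of the rule core.  The 2-D embedding
is scikit-learn t-SNE with a fixed seed, random initialisation, and
perplexity `min(30, (n−1)/3)`; sampling below the input size is seeded.
Exact coordinates are implementation-sensitive and never part of any
contract — only coarse neighbour/cluster structure is asserted in tests.

## Synthetic test data

Fixtures are generated programmatically:

* the two canonical counting networks — the independent-alternatives
  network (3 routes, naive count exact) and the shared-intermediate
  network (naive 4, true 2, per-node count 2 at the joined molecule);
* random AND/OR networks grown top-down with creation-indexed edges
  (acyclic by construction), a sharing probability that redirects
  reactant slots to existing molecules, and a post-condition that forces
  at least one joined node when sharing is requested;
* toy chemistry suites whose expected route sets are computed at
  generation time by exhaustive depth-bounded expansion with consistency
  of shared-molecule choices enforced.

These emulate the combinatorial structure of real reaction networks —
joined nodes, convergent branches, depth bounds — but not real chemistry:
no selectivity, no protecting groups, no condition feasibility, and a
toy alphabet in place of real structural diversity.  Passing tests
therefore establish the graph-algorithmic guarantees (counting,
enumeration, search consistency, scoring arithmetic), not the chemical
plausibility of proposed routes, which is limited by the supplied
template set exactly as in any template-based planner.

## Problem sizes and numerical choices

The bundled suites run at desk scale by choice: random oracle-checked
networks stay under ~20 molecules (the brute-force oracle is exponential
in choice points), toy targets are 3–6 tokens with `md` ≤ 4, and the
default enumeration cap is 1,500,000 routes.  All randomness flows
through explicit seeds; saturating "infinity" is `2^32`; route counts are
exact integers.  Degenerate inputs: a building-block target yields the
one-node network and a single zero-step route; an unparsable structure
raises a parse error naming the input; a cyclic network JSON is rejected
at load; an all-identical fingerprint set embeds with a warning rather
than an error.

## Known limitations

* No learned policy or value guidance in the search, no parallel search,
  no in-scope/feasibility filter: routes are enumerated algorithmically
  and may include chemically unreasonable steps if the templates admit
  them.
* `build_network` favours depth soundness over completeness when `md`
  binds across re-used intermediates (see above).
* The default complexity scorer is a heuristic; MSCS values are only
  meaningful relative to a fixed scorer.
* DOT output is write-only; network JSON (`compret-network/1`) is the
  interchange format.
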