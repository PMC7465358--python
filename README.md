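# compret

Retrosynthetic reaction-network construction, **exact** synthetic-route
enumeration, and route ranking for computer-assisted synthesis planning.

Most synthesis-planning tools return one or a few "optimal" routes.
Chemists usually want the opposite: *all* feasible routes within a depth
bound, so they can pick by their own criteria (available starting
materials, step count, intermediate complexity, similarity to a known
route).  `compret` serves that workflow in three steps:

1. **Build** — depth-first proof-number search (DFPN) over retrosynthetic
   templates grows an AND/OR reaction network rooted at the target: OR
   nodes are molecules (any one child reaction suffices), AND nodes are
   reactions (every reactant is required).  Building blocks terminate the
   search as proven leaves; a maximum depth `md` bounds route length.
2. **Enumerate** — every synthetic route in the network is emitted exactly
   once.  A route is a proof tree: one reaction chosen per included
   molecule, all leaves building blocks.
3. **Rank** — routes are scored by STEP (longest number of synthesis
   steps, lower is better), MSCS (mean synthetic-complexity score of the
   route's molecules, in [0, 5], lower is better), and REF (sum of
   Tanimoto fingerprint similarities to a reference route over
   molecular-weight-sorted molecule pairs, higher is better; 0 when the
   molecule counts differ).  Route fingerprints
   `f_r = Σ_{t∈r} f_p(t)` (the sum of structural reaction fingerprints
   over the route's templates) feed a t-SNE embedding for diversity
   visualization.

## Why naive route counting fails

The obvious recursion counts routes per node: building blocks get
`mol(X).count = 1`, a molecule sums its reactions
(`mol(1).count = rxn(A).count + rxn(B).count + …`), and a reaction
multiplies its reactants (`rxn(A).count = mol(2).count × mol(3).count`).
This assumes each reactant is synthesized independently.  When one
molecule feeds several reactions (a *joined node*) the recursion
over-counts:

```python
>>> from compret import naive_route_count, count_routes, naive_counts
>>> from compret.fixtures import make_fig3b_network
>>> net = make_fig3b_network()   # shared-intermediate counter-example
>>> naive_route_count(net)
4
>>> naive_counts(net)[net.or_id_for("4")]   # the shared intermediate
2
>>> count_routes(net)
CountResult(count=2, capped=False)
```

The network holds only two routes (the choice of either reaction making
the shared intermediate), but the naive recursion reports four.
`enumerate_routes` fixes this with a *prohibited-list* binary partition:
at each undetermined molecule choice point the route set is split into
"commit this reaction" and "prohibit this reaction" halves, so every
route is emitted exactly once — sound, duplicate-free, and complete, as
verified against a brute-force assignment oracle on hundreds of random
networks.

## Worked example (CLI)

`compret` ships a deterministic toy string-rewrite chemistry so the whole
pipeline can be exercised (and oracle-checked) without reaction data.
Molecules are token strings, a rule `AB>>A.B` cuts a product into two
reactants, and single tokens are building blocks:

```
$ printf 'R1\tsplitAB\tAB>>A.B\t10\nR2\tsplitBA\tBA>>B.A\t5\n' > templates.tsv
$ printf 'A\nB\n' > bb.txt
$ compret build --target ABAB --templates templates.tsv \
      --building-blocks bb.txt --backend toy --max-depth 4 --out net.json
n_or=7 n_and=10 n_edges=30 construction_time=0.00s
$ compret enumerate --network net.json --out routes.jsonl
count=6 capped=false
$ compret rank --routes routes.jsonl --network net.json \
      --method step --backend toy --out scores.csv
ranked 6 routes by step
```

The network of the 4-token target contains 7 molecules, 10 reactions and
exactly 6 distinct routes; the scores CSV lists them shortest-first
(`route_id,step,mscs,ref`).  For real molecules, supply reaction-SMARTS
templates and a building-block SMILES list and drop `--backend toy`; a
textbook single-template run looks like:

```python
>>> from compret import RDKitBackend, RetroTemplate, SearchConfig, \
...     build_network, count_routes
>>> ester = RetroTemplate("ester", "ester hydrolysis",
...     "[C:1](=[O:2])[O:3][C:4]>>[C:1](=[O:2])[OH].[OH:3][C:4]", rank=1)
>>> net = build_network("CCOC(C)=O", [ester], {"CC(=O)O", "CCO"},
...                     SearchConfig(md=2), RDKitBackend())
>>> count_routes(net)
CountResult(count=1, capped=False)
```

`compret fingerprint` and `compret embed` complete the pipeline with
route fingerprints and a seeded 2-D t-SNE embedding.

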