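"""Programmatic test inputs with oracle-known answers.

Three families:

* the two canonical counting networks — one where the naive sum/product
  recursion is exact (three independent first reactions) and one where a
  shared intermediate makes it over-count (naive 4, true route count 2);
* seeded random AND/OR networks, acyclic and target-rooted, with an
  optional bias towards shared ("joined") intermediates;
* seeded toy string-rewrite chemistries whose complete route sets are
  computed at generation time by exhaustive depth-bounded expansion, so
  search + enumeration can be checked end to end.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .enumeration import RouteKey
from .model import Molecule, ReactionNetwork, SearchConfig
from .templates import RetroTemplate, apply_retro
from .toy import ToyBackend, ToyChemistry

__all__ = [
    "FixtureSpec",
    "ToyCase",
    "make_fig3a_network",
    "make_fig3b_network",
    "random_network",
    "toy_chemistry_suite",
    "exhaustive_route_keys",
]


def make_fig3b_network() -> ReactionNetwork:
    """The shared-intermediate counter-example to naive counting.

    Target 1 is made by reaction A from intermediates 2 and 3; each of 2
    and 3 is made from the shared intermediate 4 (reactions F and G); 4 is
    made from building block 5 (reaction D) or building block 6 (reaction
    E).  The naive recursion gives mol(4) = 2 and a target count of 4,
    while the network holds exactly 2 routes (the D-or-E choice at 4).
    """
    net = ReactionNetwork(Molecule("1", mol_weight=1.0))
    for name in ("2", "3", "4"):
        net.add_molecule(Molecule(name, mol_weight=float(name)))
    for name in ("5", "6"):
        net.add_molecule(Molecule(name, is_building_block=True,
                                  mol_weight=float(name)))
    net.add_reaction("A", "1", ["2", "3"])
    net.add_reaction("F", "2", ["4"])
    net.add_reaction("G", "3", ["4"])
    net.add_reaction("D", "4", ["5"])
    net.add_reaction("E", "4", ["6"])
    return net


def make_fig3a_network() -> ReactionNetwork:
    """Independent-alternatives network where naive counting is exact:
    three first reactions, no shared intermediates, three routes."""
    net = ReactionNetwork(Molecule("1", mol_weight=1.0))
    for i, name in enumerate(("a1", "a2", "b1", "c1"), start=2):
        net.add_molecule(Molecule(name, is_building_block=True,
                                  mol_weight=float(i)))
    net.add_reaction("A", "1", ["a1", "a2"])
    net.add_reaction("B", "1", ["b1"])
    net.add_reaction("C", "1", ["c1"])
    return net


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random AND/OR network."""

    name: str = "random"
    seed: int = 0
    n_molecules: int = 8
    n_reactions: int = 2  # max reactions per molecule
    max_reactants: int = 3
    share_probability: float = 0.0
    depth: int = 4

    def __post_init__(self) -> None:
        if self.n_molecules < 2:
            raise ValueError("need at least a target and one building block")
        if not 1 <= self.max_reactants <= 3:
            raise ValueError("max_reactants must be in [1, 3]")
        if self.n_reactions < 1 or self.depth < 1:
            raise ValueError("n_reactions and depth must be >= 1")
        if not 0.0 <= self.share_probability <= 1.0:
            raise ValueError("share_probability must be in [0, 1]")


def random_network(spec: FixtureSpec) -> ReactionNetwork:
    """Seeded random valid network, grown top-down from the target.

    Acyclicity holds by construction: reactions only point from a molecule
    to molecules with a larger creation index.  When sharing is enabled a
    reactant slot may reuse an already-created later molecule, producing
    joined nodes; when it is zero every molecule has at most one reaction
    parent, so the naive count is exact.
    """
    rng = random.Random(spec.seed)
    net = ReactionNetwork(Molecule("M0", mol_weight=0.0))
    index = {"M0": 0}
    expandable = [("M0", 0)]  # (structure, depth)
    n_created = 1

    while expandable:
        structure, depth = expandable.pop(0)
        n_rxn = rng.randint(1, spec.n_reactions)
        for _ in range(n_rxn):
            n_slots = rng.randint(1, spec.max_reactants)
            reactants: list[str] = []
            for _ in range(n_slots):
                candidates = [
                    s for s, i in index.items()
                    if i > index[structure] and s not in reactants
                ]
                if candidates and rng.random() < spec.share_probability:
                    pick = rng.choice(sorted(candidates, key=index.__getitem__))
                    reactants.append(pick)
                    continue
                name = f"M{n_created}"
                is_leaf = (
                    depth + 1 >= spec.depth or n_created >= spec.n_molecules
                )
                net.add_molecule(
                    Molecule(name, is_building_block=is_leaf,
                             mol_weight=float(n_created))
                )
                index[name] = n_created
                n_created += 1
                reactants.append(name)
                if not is_leaf:
                    expandable.append((name, depth + 1))
            if reactants:
                net.add_reaction(
                    f"T{index[structure]}_{len(net.and_nodes)}",
                    structure,
                    reactants,
                )

    if spec.share_probability > 0 and not _has_joined_node(net):
        # force the promised joined node: a second reaction into the target
        # re-using an existing molecule
        reuse = next(s for s, i in sorted(index.items(), key=lambda kv: kv[1])
                     if i > 0)
        net.add_reaction("T_share", "M0", [reuse])
    net.validate()
    return net


def _has_joined_node(net: ReactionNetwork) -> bool:
    parents: dict[str, int] = {}
    for a in net.and_nodes.values():
        for rid in a.reactants:
            parents[rid] = parents.get(rid, 0) + 1
    return any(v >= 2 for v in parents.values())


# -- toy chemistries with exhaustive oracle --------------------------------


def exhaustive_route_keys(
    target: str,
    templates: tuple[RetroTemplate, ...],
    building_blocks: frozenset[str],
    md: int,
    backend: ToyBackend | None = None,
) -> frozenset[RouteKey]:
    """Oracle: every route of height <= *md* by exhaustive expansion.

    A derivation is a consistent mapping molecule -> (template, reactants)
    — a shared molecule must be made the same way in every branch.  Keys
    are frozen sets of (product, template id, sorted reactants) triples,
    the same canonical form the enumerator's route keys use.
    """
    backend = backend or ToyBackend()
    memo: dict[tuple[str, int], frozenset] = {}

    def derivations(s: str, depth_left: int) -> frozenset:
        if s in building_blocks:
            return frozenset({frozenset()})
        if depth_left == 0:
            return frozenset()
        key = (s, depth_left)
        if key in memo:
            return memo[key]
        out: set[frozenset] = set()
        for tpl in templates:
            for prop in apply_retro(tpl, s, backend):
                if s in prop.reactants:
                    continue
                subs = [derivations(r, depth_left - 1) for r in prop.reactants]
                if any(not sub for sub in subs):
                    continue
                own = (tpl.id, tuple(sorted(prop.reactants)))
                for combo in itertools.product(*subs):
                    merged: dict[str, tuple[str, tuple[str, ...]]] = {s: own}
                    ok = True
                    for sub_map in combo:
                        for p, choice in sub_map:
                            if merged.setdefault(p, choice) != choice:
                                ok = False
                                break
                        if not ok:
                            break
                    if ok:
                        out.add(frozenset(merged.items()))
        memo[key] = frozenset(out)
        return memo[key]

    keys = set()
    for derivation in derivations(target, md):
        keys.add(frozenset(
            (p, tid, rs) for p, (tid, rs) in derivation
        ))
    return frozenset(keys)


@dataclass(frozen=True)
class ToyCase:
    """One end-to-end toy problem with its oracle-known route set."""

    name: str
    chemistry: ToyChemistry
    target: str
    config: SearchConfig
    expected_route_keys: frozenset[RouteKey] = field(default=frozenset())

    @property
    def templates(self) -> tuple[RetroTemplate, ...]:
        return self.chemistry.rules

    @property
    def building_blocks(self) -> set[str]:
        return set(self.chemistry.building_blocks)


def _rule(rid: str, transform: str, rank: int) -> RetroTemplate:
    return RetroTemplate(id=rid, name=rid, retro_transform=transform,
                         rank=rank, frequency=100 - rank)


def toy_chemistry_suite(seed: int = 0) -> list[ToyCase]:
    """Deterministic suite of toy problems covering: a unique route, joined
    nodes, a building-block target, an unreachable depth bound, and a
    mixed split/rewrite rule set.  Expected route sets come from the
    exhaustive oracle at generation time; *seed* is recorded in each
    search config."""
    ab = frozenset("AB")
    abc = frozenset("ABC")

    def case(name: str, rules: tuple[RetroTemplate, ...], bbs: frozenset[str],
             alphabet: frozenset[str], target: str, md: int) -> ToyCase:
        chem = ToyChemistry(alphabet=alphabet, rules=rules,
                            building_blocks=bbs)
        cfg = SearchConfig(md=md, node_budget=50_000, seed=seed)
        expected = exhaustive_route_keys(target, rules, bbs, md)
        return ToyCase(name, chem, target, cfg, expected)

    split_ab = _rule("R1", "AB>>A.B", 1)
    split_ba = _rule("R2", "BA>>B.A", 2)
    split_bc = _rule("R3", "BC>>B.C", 3)
    shrink_aa = _rule("R4", "AA>>A", 4)

    return [
        case("unique-route", (split_ab,), ab, ab, "AAB", md=3),
        case("joined-nodes", (split_ab, split_ba), ab, ab, "ABAB", md=4),
        case("bb-target", (split_ab,), ab, ab, "A", md=3),
        case("too-shallow", (split_ab,), ab, ab, "AAB", md=1),
        case("mixed-rules", (split_ab, split_bc, shrink_aa),
             frozenset("ABC"), abc, "AABC", md=4),
    ]
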