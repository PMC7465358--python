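"""Depth-first proof-number search (DFPN) and reaction-network construction.

The retrosynthetic space is an AND/OR graph: a molecule (OR node) is
provable when any one of its candidate reactions is provable; a reaction
(AND node) is provable when all of its reactants are.  Building blocks are
proven terminals; a non-building-block molecule at the maximum depth *md*
is disproven, as is one with no relevance-checked template application.

:func:`find_route` runs DFPN proper — proof/disproof numbers with the
standard min/sum updates and top-two-children thresholds, over a
depth-indexed transposition table — and extracts one proof tree.

:func:`build_network` grows the full merged network: it exhaustively
expands every molecule reachable within *md* (memoising template
application per structure, subject to the node budget), keeps each
decomposition that participates in at least one depth-valid route, and
then prunes until no enumerable route can exceed *md* steps even through
re-used intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import networkx as nx

from .model import Molecule, ReactionNetwork, SearchConfig
from .templates import ChemistryBackend, RetroTemplate, apply_retro

__all__ = [
    "INF",
    "ProofNumbers",
    "TerminalStatus",
    "SearchOutcome",
    "FindRouteResult",
    "BudgetExhausted",
    "evaluate_terminal",
    "update_numbers",
    "find_route",
    "build_network",
]

#: Large finite cap standing in for infinity in saturating arithmetic.
INF = 1 << 32


def _sat_add(values: Sequence[int]) -> int:
    total = 0
    for v in values:
        total += v
        if total >= INF:
            return INF
    return total


@dataclass
class ProofNumbers:
    """Proof number (cost to prove) and disproof number (cost to refute)."""

    pn: int = 1
    dn: int = 1

    @property
    def proven(self) -> bool:
        return self.pn == 0

    @property
    def disproven(self) -> bool:
        return self.dn == 0

    @classmethod
    def proven_leaf(cls) -> "ProofNumbers":
        return cls(pn=0, dn=INF)

    @classmethod
    def disproven_leaf(cls) -> "ProofNumbers":
        return cls(pn=INF, dn=0)


class TerminalStatus(Enum):
    PROVEN = "proven"
    DISPROVEN = "disproven"
    UNKNOWN = "unknown"


def evaluate_terminal(
    molecule: Molecule,
    depth: int,
    config: SearchConfig,
    building_blocks: set[str],
    n_proposals: int | None = None,
) -> TerminalStatus:
    """Terminal evaluation of a molecule OR node at *depth* reaction steps.

    Building blocks are proven at any depth; a non-building block at depth
    ``md`` is disproven; one whose expansion yielded no relevance-checked
    proposal (``n_proposals == 0``) is disproven; otherwise unknown.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if molecule.is_building_block or molecule.structure in building_blocks:
        return TerminalStatus.PROVEN
    if depth >= config.md:
        return TerminalStatus.DISPROVEN
    if n_proposals == 0:
        return TerminalStatus.DISPROVEN
    return TerminalStatus.UNKNOWN


def update_numbers(kind: str, children: Sequence[ProofNumbers]) -> ProofNumbers:
    """Standard DFPN update: OR takes min-pn / sum-dn, AND sum-pn / min-dn.

    An expanded OR node with no children is disproven; an AND node with no
    children is a construction error (a reaction always has reactants).
    """
    if kind not in ("OR", "AND"):
        raise ValueError(f"kind must be 'OR' or 'AND', got {kind!r}")
    if not children:
        if kind == "OR":
            return ProofNumbers.disproven_leaf()
        raise ValueError("an AND node cannot have an empty child list")
    if kind == "OR":
        return ProofNumbers(
            pn=min(c.pn for c in children),
            dn=_sat_add([c.dn for c in children]),
        )
    return ProofNumbers(
        pn=_sat_add([c.pn for c in children]),
        dn=min(c.dn for c in children),
    )


class BudgetExhausted(Exception):
    """The node-expansion budget ran out before the search concluded."""


class SearchOutcome(Enum):
    PROVEN = "proven"
    DISPROVEN = "disproven"
    INCONCLUSIVE = "inconclusive"


@dataclass
class FindRouteResult:
    """Outcome of :func:`find_route`; ``route`` is a route-shaped
    :class:`ReactionNetwork` (a proof tree) when proven."""

    outcome: SearchOutcome
    route: ReactionNetwork | None
    expansions: int


@dataclass
class _OrEntry:
    numbers: ProofNumbers
    expanded: bool = False
    # each child is (template, reactant structures)
    children: list[tuple[RetroTemplate, tuple[str, ...]]] | None = None


class _Searcher:
    """DFPN over (structure, depth) with memoised template application."""

    def __init__(
        self,
        templates: Sequence[RetroTemplate],
        building_blocks: set[str],
        config: SearchConfig,
        backend: ChemistryBackend,
    ):
        self.templates = sorted(templates, key=lambda t: (t.rank, t.id))
        self.building_blocks = building_blocks
        self.config = config
        self.backend = backend
        self.table: dict[tuple[str, int], _OrEntry] = {}
        self.proposal_cache: dict[str, list[tuple[RetroTemplate, tuple[str, ...]]]] = {}
        self.expansions = 0

    # -- expansion --------------------------------------------------------

    def proposals(self, structure: str) -> list[tuple[RetroTemplate, tuple[str, ...]]]:
        cached = self.proposal_cache.get(structure)
        if cached is not None:
            return cached
        if self.expansions >= self.config.node_budget:
            raise BudgetExhausted(structure)
        self.expansions += 1
        out: list[tuple[RetroTemplate, tuple[str, ...]]] = []
        for tpl in self.templates:
            for prop in apply_retro(tpl, structure, self.backend,
                                    check_relevance=True):
                if structure in prop.reactants:
                    continue  # a molecule cannot be its own reactant
                out.append((tpl, prop.reactants))
        self.proposal_cache[structure] = out
        return out

    def entry(self, structure: str, depth: int) -> _OrEntry:
        key = (structure, depth)
        e = self.table.get(key)
        if e is None:
            mol = Molecule(structure,
                           is_building_block=structure in self.building_blocks)
            status = evaluate_terminal(mol, depth, self.config,
                                       self.building_blocks)
            if status is TerminalStatus.PROVEN:
                e = _OrEntry(ProofNumbers.proven_leaf(), expanded=True,
                             children=[])
            elif status is TerminalStatus.DISPROVEN:
                e = _OrEntry(ProofNumbers.disproven_leaf(), expanded=True,
                             children=[])
            else:
                e = _OrEntry(ProofNumbers())
            self.table[key] = e
        return e

    def _and_numbers(self, reactants: tuple[str, ...], depth: int) -> ProofNumbers:
        child_numbers = []
        for r in reactants:
            e = self.table.get((r, depth + 1))
            child_numbers.append(e.numbers if e is not None else ProofNumbers())
        return update_numbers("AND", child_numbers)

    def _refresh(self, e: _OrEntry, depth: int) -> list[ProofNumbers]:
        assert e.children is not None
        and_numbers = [self._and_numbers(rs, depth) for _, rs in e.children]
        e.numbers = update_numbers("OR", and_numbers)
        return and_numbers

    # -- DFPN core --------------------------------------------------------

    def search(self, structure: str, depth: int, th_pn: int, th_dn: int) -> None:
        """Expand below (structure, depth) until its proof or disproof
        number reaches its threshold (classic df-pn recursion)."""
        e = self.entry(structure, depth)
        while e.numbers.pn < th_pn and e.numbers.dn < th_dn:
            if not e.expanded:
                props = self.proposals(structure)
                e.children = list(props)
                e.expanded = True
                if not props:
                    e.numbers = ProofNumbers.disproven_leaf()
                    return
                self._refresh(e, depth)
                continue
            if not e.children:
                return
            and_numbers = self._refresh(e, depth)
            if e.numbers.pn >= th_pn or e.numbers.dn >= th_dn:
                return
            # select the AND child with minimum pn; track the runner-up pn
            best = 0
            best_pn, second_pn = INF, INF
            for i, num in enumerate(and_numbers):
                if num.pn < best_pn:
                    second_pn = best_pn
                    best_pn, best = num.pn, i
                elif num.pn < second_pn:
                    second_pn = num.pn
            tpl, reactants = e.children[best]
            child_th_pn = min(th_pn, _sat_add([second_pn, 1]))
            child_th_dn = min(th_dn - e.numbers.dn + and_numbers[best].dn, INF)
            self._search_and(reactants, depth, child_th_pn, child_th_dn)
            self._refresh(e, depth)

    def _search_and(self, reactants: tuple[str, ...], depth: int,
                    th_pn: int, th_dn: int) -> None:
        while True:
            numbers = self._and_numbers(reactants, depth)
            if numbers.pn >= th_pn or numbers.dn >= th_dn:
                return
            # select the reactant with minimum dn; track runner-up
            entries = [self.entry(r, depth + 1) for r in reactants]
            best = 0
            best_dn, second_dn = INF + 1, INF + 1
            for i, ent in enumerate(entries):
                if ent.numbers.dn < best_dn:
                    second_dn = best_dn
                    best_dn, best = ent.numbers.dn, i
                elif ent.numbers.dn < second_dn:
                    second_dn = ent.numbers.dn
            child_th_dn = min(th_dn, _sat_add([min(second_dn, INF), 1]))
            child_th_pn = min(th_pn - numbers.pn + entries[best].numbers.pn, INF)
            self.search(reactants[best], depth + 1, child_th_pn, child_th_dn)

    # -- proof-tree extraction -------------------------------------------

    def extract_proof(self, target: str) -> ReactionNetwork:
        """Deterministically extract one proof tree of a proven target.

        One reaction is chosen per molecule (first proven child in template
        rank order), validated at the molecule's deepest occurrence in the
        tree so the extracted route respects the *md* bound.
        """
        choice: dict[str, tuple[RetroTemplate, tuple[str, ...]]] = {}
        depths: dict[str, int] = {target: 0}
        work = [target]
        while work:
            s = work.pop()
            if s in self.building_blocks:
                continue
            d = depths[s]
            cur = choice.get(s)
            if cur is None or not self._and_numbers(cur[1], d).proven:
                e = self.table.get((s, d))
                if e is None or e.children is None:
                    raise RuntimeError(f"no expanded entry for proven node {s!r}")
                for tpl, reactants in e.children:
                    if self._and_numbers(reactants, d).proven:
                        choice[s] = (tpl, reactants)
                        break
                else:
                    raise RuntimeError("proven node without a proven child")
            for r in choice[s][1]:
                nd = d + 1
                if r not in depths or nd > depths[r]:
                    depths[r] = nd
                    work.append(r)
        # closure walk over the final per-structure choices
        net = ReactionNetwork(self._molecule(target))
        seen = {target}
        stack = [target]
        while stack:
            s = stack.pop()
            if s in self.building_blocks or s not in choice:
                continue
            tpl, reactants = choice[s]
            for r in reactants:
                net.add_molecule(self._molecule(r))
            net.add_reaction(tpl.id, s, reactants)
            for r in reactants:
                if r not in seen:
                    seen.add(r)
                    stack.append(r)
        return net

    def _molecule(self, structure: str) -> Molecule:
        is_bb = structure in self.building_blocks
        return Molecule(structure, is_building_block=is_bb,
                        mol_weight=self.backend.mol_weight(structure))


def find_route(
    target: str,
    templates: Sequence[RetroTemplate],
    building_blocks: set[str],
    config: SearchConfig,
    backend: ChemistryBackend,
) -> FindRouteResult:
    """Find one synthetic route of at most ``config.md`` steps by DFPN.

    Returns a proven proof tree, a disproven verdict, or an inconclusive
    result when the node budget runs out (distinct from "no route").
    """
    target = backend.canonicalize(target)
    searcher = _Searcher(templates, building_blocks, config, backend)
    if target in building_blocks:
        net = ReactionNetwork(searcher._molecule(target))
        return FindRouteResult(SearchOutcome.PROVEN, net, 0)
    try:
        searcher.search(target, 0, INF, INF)
    except BudgetExhausted:
        return FindRouteResult(SearchOutcome.INCONCLUSIVE, None,
                               searcher.expansions)
    numbers = searcher.entry(target, 0).numbers
    if numbers.proven:
        return FindRouteResult(SearchOutcome.PROVEN,
                               searcher.extract_proof(target),
                               searcher.expansions)
    if numbers.disproven:
        return FindRouteResult(SearchOutcome.DISPROVEN, None,
                               searcher.expansions)
    return FindRouteResult(SearchOutcome.INCONCLUSIVE, None,  # pragma: no cover
                           searcher.expansions)


# -- full network construction ---------------------------------------------


def build_network(
    target: str,
    templates: Sequence[RetroTemplate],
    building_blocks: set[str],
    config: SearchConfig,
    backend: ChemistryBackend,
) -> ReactionNetwork:
    """Construct the merged reaction network of all routes within *md*.

    Procedure: (1) breadth-first expansion from the target of every
    molecule whose minimum depth is below *md* (template application is
    memoised per structure and counted against ``node_budget``; on
    exhaustion the network is flagged ``incomplete``); (2) bottom-up
    minimum synthesis heights; (3) keep each decomposition usable in at
    least one route that fits in *md* from the molecule's shallowest
    occurrence; (4) prune decompositions (deepest occurrence + tallest
    remaining choice must fit in *md*) so that no enumerable route can
    exceed *md*, cascading removals to a fixpoint.
    """
    md = config.md
    target = backend.canonicalize(target)
    bbs = building_blocks
    searcher = _Searcher(templates, bbs, config, backend)
    incomplete = False

    # (1) reachability with minimum depths
    dmin: dict[str, int] = {target: 0}
    decomps: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    frontier = [target]
    while frontier:
        nxt: list[str] = []
        for s in frontier:
            if s in bbs or s in decomps or dmin[s] >= md:
                continue
            try:
                props = searcher.proposals(s)
            except BudgetExhausted:
                incomplete = True
                props = []
            decomps[s] = [(tpl.id, rs) for tpl, rs in props]
            for _, rs in decomps[s]:
                for r in rs:
                    d = dmin[s] + 1
                    if r not in dmin or d < dmin[r]:
                        dmin[r] = d
                        nxt.append(r)
        frontier = nxt

    # (2) minimum synthesis heights (least fixpoint; cycles never help)
    hmin: dict[str, int] = {s: 0 for s in dmin if s in bbs}
    changed = True
    while changed:
        changed = False
        for s, ds in decomps.items():
            best = hmin.get(s, INF)
            for _, rs in ds:
                if all(r in hmin for r in rs):
                    h = 1 + max(hmin[r] for r in rs)
                    if h < best:
                        best = h
            if best < hmin.get(s, INF):
                hmin[s] = best
                changed = True

    # (3) decompositions usable in some depth-valid route
    def choice_height_min(rs: tuple[str, ...]) -> int:
        return 1 + max(hmin.get(r, INF) for r in rs)

    kept: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    for s, ds in decomps.items():
        budget_d = md - dmin[s]
        kept[s] = [
            (tid, rs) for tid, rs in ds
            if choice_height_min(rs) <= budget_d
        ]

    def reachable_closure() -> list[str]:
        seen = [target]
        seen_set = {target}
        i = 0
        while i < len(seen):
            for _, rs in kept.get(seen[i], []):
                for r in rs:
                    if r not in seen_set:
                        seen_set.add(r)
                        seen.append(r)
            i += 1
        return seen

    def drop_dead() -> bool:
        """Remove non-building-block molecules with no decomposition left,
        cascading into the choices that used them."""
        removed = False
        changed_local = True
        while changed_local:
            changed_local = False
            dead = {s for s, ds in kept.items() if not ds and s not in bbs}
            for s in list(kept):
                before = len(kept[s])
                kept[s] = [
                    (tid, rs) for tid, rs in kept[s]
                    if not any(r in dead for r in rs)
                ]
                if len(kept[s]) != before:
                    changed_local = removed = True
            for s in dead:
                if s != target and s in kept:
                    del kept[s]
                    changed_local = removed = True
        return removed

    drop_dead()

    # (4) soundness pruning on the merged graph: for every molecule s and
    # every kept decomposition c, maxdepth(s) + height(c) <= md, where
    # height takes the *tallest* remaining choice below (any enumerable
    # combination).  Remove violators until fixpoint.
    while True:
        nodes = [s for s in reachable_closure()]
        node_set = set(nodes)
        # break any molecule-level cycle conservatively (deterministic DFS)
        state: dict[str, int] = {}
        cycle_removed = False

        def dfs(u: str) -> None:
            nonlocal cycle_removed
            state[u] = 0
            for tid, rs in list(kept.get(u, [])):
                for r in rs:
                    if state.get(r) == 0:  # back edge: drop this reaction
                        kept[u].remove((tid, rs))
                        cycle_removed = True
                        break
                    if r not in state and r in node_set:
                        dfs(r)
            state[u] = 1

        for s in nodes:
            if s not in state:
                dfs(s)
        if cycle_removed:
            drop_dead()
            continue

        # longest-path depth from target over the kept graph (DAG now)
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for s in nodes:
            for _, rs in kept.get(s, []):
                for r in rs:
                    if r in node_set:
                        g.add_edge(s, r)
        dmax = {s: 0 for s in nodes}
        for u in nx.topological_sort(g):
            for v in g.successors(u):
                dmax[v] = max(dmax[v], dmax[u] + 1)
        hmax: dict[str, int] = {}
        for u in reversed(list(nx.topological_sort(g))):
            if u in bbs or not kept.get(u):
                hmax[u] = 0
            else:
                hmax[u] = max(1 + max(hmax[r] for r in rs)
                              for _, rs in kept[u])
        violated = False
        for s in nodes:
            if s in bbs:
                continue
            fit = md - dmax[s]
            before = len(kept.get(s, []))
            kept[s] = [
                (tid, rs) for tid, rs in kept.get(s, [])
                if 1 + max(hmax[r] for r in rs) <= fit
            ]
            if len(kept[s]) != before:
                violated = True
        if violated:
            drop_dead()
            continue
        break

    # assemble the network in deterministic traversal order
    net = ReactionNetwork(searcher._molecule(target))
    net.incomplete = incomplete
    order = reachable_closure()
    for s in order:
        net.add_molecule(searcher._molecule(s))
    for s in order:
        for tid, rs in kept.get(s, []):
            net.add_reaction(tid, s, rs)
    return net
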