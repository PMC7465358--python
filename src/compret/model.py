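"""Core domain model: molecules, AND/OR reaction networks, routes.

A reaction network is a bipartite AND/OR graph rooted at a target molecule.
OR nodes are molecules (any one child reaction suffices to make them); AND
nodes are reactions (every reactant is required).  A synthetic route is a
proof tree of the network: one reaction chosen per included molecule, with
every leaf a building block.

The naive route count recursion (building blocks count 1, molecules sum over
reaction children, reactions multiply over reactant children) over-counts
whenever a molecule is shared as a reactant by several reactions; the exact
count lives in :mod:`compret.enumeration`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

__all__ = [
    "Molecule",
    "OrNode",
    "AndNode",
    "ReactionNetwork",
    "Route",
    "SearchConfig",
    "ValidationResult",
    "NetworkStats",
    "MoleculeParseError",
    "NetworkError",
    "MergeError",
    "CycleError",
    "SchemaError",
    "DanglingNodeError",
    "canonicalize_molecule",
    "merge_route",
    "naive_counts",
    "naive_route_count",
    "is_valid_route",
    "network_stats",
    "to_dot",
    "to_json",
    "from_json",
]

JSON_FORMAT = "compret-network/1"


class MoleculeParseError(ValueError):
    """A structure string could not be parsed by the chemistry toolkit."""


class NetworkError(ValueError):
    """A reaction-network invariant was violated."""


class MergeError(NetworkError):
    """A route fragment is incompatible with the network it is merged into."""


class CycleError(NetworkError):
    """A directed cycle through molecule nodes makes counting ill-defined."""


class SchemaError(ValueError):
    """Serialized network JSON does not match the expected schema."""


class DanglingNodeError(KeyError):
    """A route references a node id absent from the network."""


def canonicalize_molecule(structure: str) -> str:
    """Return the canonical SMILES for *structure* (stereochemistry kept).

    Raises :class:`MoleculeParseError` naming the offending input when the
    string does not parse.
    """
    from rdkit import Chem

    if not structure:
        raise MoleculeParseError("empty structure string")
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise MoleculeParseError(f"unparsable SMILES: {structure!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Molecule:
    """A molecule: canonical structure plus building-block status."""

    structure: str
    is_building_block: bool = False
    mol_weight: float = 0.0

    def __post_init__(self) -> None:
        if not self.structure:
            raise ValueError("Molecule.structure must be non-empty")


@dataclass
class OrNode:
    """Molecule node; ``children`` are AND-node ids in insertion order."""

    node_id: str
    molecule: Molecule
    children: list[str] = field(default_factory=list)


@dataclass
class AndNode:
    """Reaction node: one product OR node, 1-3 reactant OR nodes."""

    node_id: str
    template_id: str
    product: str
    reactants: list[str] = field(default_factory=list)


AndKey = tuple[str, str, tuple[str, ...]]


class ReactionNetwork:
    """Merged AND/OR reaction network rooted at a target molecule.

    OR nodes are unified by canonical structure, AND nodes by
    (product structure, template id, sorted reactant structures).  All
    iteration is in insertion order, so identically-built networks serialize
    byte-for-byte identically.
    """

    def __init__(self, target: Molecule):
        self.or_nodes: dict[str, OrNode] = {}
        self.and_nodes: dict[str, AndNode] = {}
        self._or_by_structure: dict[str, str] = {}
        self._and_by_key: dict[AndKey, str] = {}
        self.incomplete: bool = False
        self.target = self.add_molecule(target)

    # -- construction -----------------------------------------------------

    def add_molecule(self, molecule: Molecule) -> str:
        """Add (or find) the OR node for *molecule*; return its id."""
        existing = self._or_by_structure.get(molecule.structure)
        if existing is not None:
            node = self.or_nodes[existing]
            if node.molecule.is_building_block != molecule.is_building_block:
                raise MergeError(
                    f"conflicting building-block status for {molecule.structure!r}"
                )
            return existing
        node_id = f"m{len(self.or_nodes)}"
        self.or_nodes[node_id] = OrNode(node_id, molecule)
        self._or_by_structure[molecule.structure] = node_id
        return node_id

    def add_reaction(
        self,
        template_id: str,
        product_structure: str,
        reactant_structures: Iterable[str],
    ) -> str:
        """Add (or find) a reaction AND node; return its id.

        Product and reactant molecules must already exist as OR nodes.
        """
        reactants = tuple(reactant_structures)
        if not 1 <= len(reactants) <= 3:
            raise NetworkError("a reaction needs between 1 and 3 reactants")
        if product_structure in reactants:
            raise NetworkError("a reaction's product cannot be its own reactant")
        key: AndKey = (product_structure, template_id, tuple(sorted(reactants)))
        existing = self._and_by_key.get(key)
        if existing is not None:
            return existing
        try:
            product_id = self._or_by_structure[product_structure]
            reactant_ids = [self._or_by_structure[s] for s in reactants]
        except KeyError as exc:
            raise NetworkError(f"unknown molecule in reaction: {exc.args[0]!r}") from exc
        node_id = f"r{len(self.and_nodes)}"
        self.and_nodes[node_id] = AndNode(node_id, template_id, product_id, reactant_ids)
        self._and_by_key[key] = node_id
        self.or_nodes[product_id].children.append(node_id)
        return node_id

    # -- lookups ----------------------------------------------------------

    def or_id_for(self, structure: str) -> str | None:
        return self._or_by_structure.get(structure)

    def structure_of(self, or_id: str) -> str:
        return self.or_nodes[or_id].molecule.structure

    def and_key(self, and_id: str) -> AndKey:
        a = self.and_nodes[and_id]
        rs = tuple(self.structure_of(r) for r in a.reactants)
        return (self.structure_of(a.product), a.template_id, tuple(sorted(rs)))

    def molecule_successors(self, or_id: str) -> Iterator[str]:
        """Reactant OR ids reachable in one reaction step from *or_id*."""
        seen: set[str] = set()
        for and_id in self.or_nodes[or_id].children:
            for rid in self.and_nodes[and_id].reactants:
                if rid not in seen:
                    seen.add(rid)
                    yield rid

    def topological_order(self) -> list[str]:
        """Deterministic topological order of OR ids, target first.

        Raises :class:`CycleError` on a molecule-level directed cycle.
        Unreachable nodes follow the reachable ones, in insertion order.
        """
        order: list[str] = []
        state: dict[str, int] = {}  # 0 = on stack, 1 = done

        def visit(u: str) -> None:
            stack = [(u, iter(self.molecule_successors(u)))]
            state[u] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for v in it:
                    if state.get(v) == 0:
                        raise CycleError(
                            f"directed cycle through molecule {self.structure_of(v)!r}"
                        )
                    if v not in state:
                        state[v] = 0
                        stack.append((v, iter(self.molecule_successors(v))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    order.append(node)
                    stack.pop()

        visit(self.target)
        for or_id in self.or_nodes:
            if or_id not in state:
                visit(or_id)
        order.reverse()
        # reverse-postorder interleaves components; stable-sort reachables first
        reachable = set(self._reachable_from(self.target))
        order.sort(key=lambda u: (u not in reachable,))
        return order

    def _reachable_from(self, or_id: str) -> list[str]:
        seen = [or_id]
        seen_set = {or_id}
        i = 0
        while i < len(seen):
            for v in self.molecule_successors(seen[i]):
                if v not in seen_set:
                    seen_set.add(v)
                    seen.append(v)
            i += 1
        return seen

    def validate(self) -> None:
        """Check all structural invariants; raise :class:`NetworkError`."""
        if self.target not in self.or_nodes:
            raise NetworkError("target OR node missing")
        structures: set[str] = set()
        for oid, node in self.or_nodes.items():
            if node.molecule.structure in structures:
                raise NetworkError(
                    f"duplicate OR node for structure {node.molecule.structure!r}"
                )
            structures.add(node.molecule.structure)
            for cid in node.children:
                if cid not in self.and_nodes:
                    raise NetworkError(f"OR node {oid} has unknown child {cid}")
                if self.and_nodes[cid].product != oid:
                    raise NetworkError(f"AND node {cid} is a child of a non-product")
        for aid, node in self.and_nodes.items():
            if node.product not in self.or_nodes:
                raise NetworkError(f"AND node {aid} has unknown product")
            if not 1 <= len(node.reactants) <= 3:
                raise NetworkError(f"AND node {aid} has {len(node.reactants)} reactants")
            for rid in node.reactants:
                if rid not in self.or_nodes:
                    raise NetworkError(f"AND node {aid} has unknown reactant {rid}")
                if rid == node.product:
                    raise NetworkError(f"AND node {aid} lists its product as reactant")
        self.topological_order()  # raises CycleError on a cycle


class NetworkStats(NamedTuple):
    n_or: int
    n_and: int
    n_edges: int


def network_stats(network: ReactionNetwork) -> NetworkStats:
    """Node/edge counts of the network (one product edge per reaction plus
    one edge per reactant)."""
    n_and = len(network.and_nodes)
    n_edges = n_and + sum(len(a.reactants) for a in network.and_nodes.values())
    return NetworkStats(len(network.or_nodes), n_and, n_edges)


# -- routes ----------------------------------------------------------------


@dataclass(frozen=True)
class Route:
    """A synthetic route: the chosen reaction for each included molecule.

    Stored as a sorted tuple of (or_id, and_id) pairs so routes are hashable
    and order-independent.  Building-block leaves carry no entry.
    """

    items: tuple[tuple[str, str], ...]

    @classmethod
    def from_selection(cls, selection: Mapping[str, str]) -> "Route":
        return cls(tuple(sorted(selection.items())))

    @property
    def selection(self) -> dict[str, str]:
        return dict(self.items)

    def chosen(self, or_id: str) -> str | None:
        return self.selection.get(or_id)


@dataclass(frozen=True)
class SearchConfig:
    """Search parameters: *md* is the maximum route depth in reaction steps
    along the longest target-to-leaf path."""

    md: int = 6
    node_budget: int = 100_000
    route_cap: int = 1_500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.md < 1:
            raise ValueError("md must be >= 1")
        if self.node_budget < 0 or self.route_cap < 0:
            raise ValueError("budgets must be >= 0")


class ValidationResult(NamedTuple):
    ok: bool
    reason: str | None

    def __bool__(self) -> bool:  # truthiness == validity
        return self.ok


def _normalize_selection(selection: Mapping[str, object]) -> tuple[dict[str, str], str | None]:
    """Unwrap list-valued selections; report multiple selections."""
    out: dict[str, str] = {}
    for oid, val in selection.items():
        if isinstance(val, (list, tuple, set)):
            vals = sorted(val)  # type: ignore[arg-type]
            if len(vals) > 1:
                return {}, "multiple selections"
            if not vals:
                continue
            out[oid] = vals[0]
        else:
            out[oid] = str(val)
    return out, None


def route_closure(network: ReactionNetwork, route: Route | Mapping[str, str]) -> tuple[list[str], list[str]]:
    """OR and AND ids included in the route, by closure from the target.

    Raises :class:`DanglingNodeError` on unknown ids; does not validate
    route semantics beyond reference integrity.
    """
    selection = route.selection if isinstance(route, Route) else dict(route)
    for oid, aid in selection.items():
        if oid not in network.or_nodes:
            raise DanglingNodeError(oid)
        if aid not in network.and_nodes:
            raise DanglingNodeError(aid)
    or_ids: list[str] = [network.target]
    and_ids: list[str] = []
    seen = {network.target}
    i = 0
    while i < len(or_ids):
        oid = or_ids[i]
        i += 1
        aid = selection.get(oid)
        if aid is None:
            continue
        and_ids.append(aid)
        for rid in network.and_nodes[aid].reactants:
            if rid not in seen:
                seen.add(rid)
                or_ids.append(rid)
    return or_ids, and_ids


def is_valid_route(
    network: ReactionNetwork, route: Route | Mapping[str, object]
) -> ValidationResult:
    """Check the route invariants; on failure name the first violated one.

    Unknown node references raise :class:`DanglingNodeError` (distinct from
    an invalid-but-well-referenced route).
    """
    raw = route.selection if isinstance(route, Route) else route
    selection, problem = _normalize_selection(raw)
    if problem:
        return ValidationResult(False, problem)
    for oid, aid in selection.items():
        if oid not in network.or_nodes:
            raise DanglingNodeError(oid)
        if aid not in network.and_nodes:
            raise DanglingNodeError(aid)
    included_or, _ = route_closure(network, selection)
    included_set = set(included_or)
    for oid in selection:
        if oid not in included_set:
            return ValidationResult(False, "selection outside route closure")
    for oid in included_or:
        node = network.or_nodes[oid]
        aid = selection.get(oid)
        if aid is None:
            if not node.molecule.is_building_block:
                return ValidationResult(False, "non-building-block leaf")
        else:
            if node.molecule.is_building_block:
                return ValidationResult(False, "selection on building block")
            if aid not in node.children:
                return ValidationResult(False, "selected reaction not a child")
    # no molecule may repeat on a root-to-leaf path
    def has_repeat(oid: str, path: set[str]) -> bool:
        if oid in path:
            return True
        aid = selection.get(oid)
        if aid is None:
            return False
        path = path | {oid}
        return any(has_repeat(r, path) for r in network.and_nodes[aid].reactants)

    if has_repeat(network.target, set()):
        return ValidationResult(False, "molecule repeated on a path")
    return ValidationResult(True, None)


# -- merging ---------------------------------------------------------------


def merge_route(network: ReactionNetwork, fragment: ReactionNetwork) -> ReactionNetwork:
    """Merge a route-shaped fragment (or any network over the same target)
    into *network*, unifying molecules by structure and reactions by
    (product, template, reactant multiset).  Idempotent."""
    if (
        fragment.structure_of(fragment.target)
        != network.structure_of(network.target)
    ):
        raise MergeError("fragment target differs from network target")
    for node in fragment.or_nodes.values():
        network.add_molecule(node.molecule)
    for a in fragment.and_nodes.values():
        network.add_reaction(
            a.template_id,
            fragment.structure_of(a.product),
            [fragment.structure_of(r) for r in a.reactants],
        )
    return network


# -- naive counting (sum/product recursion) --------------------------------


def naive_counts(network: ReactionNetwork) -> dict[str, int]:
    """Per-node naive route counts, arbitrary precision.

    Building blocks count 1; an OR node sums its reaction children; an AND
    node multiplies its reactant children.  Over-counts when a molecule is
    shared as a reactant of several reactions ("joined node").
    """
    network.topological_order()  # cycle check
    counts: dict[str, int] = {}

    def count_or(oid: str) -> int:
        if oid in counts:
            return counts[oid]
        node = network.or_nodes[oid]
        if node.molecule.is_building_block:
            c = 1
        else:
            c = sum(count_and(a) for a in node.children)
        counts[oid] = c
        return c

    def count_and(aid: str) -> int:
        if aid in counts:
            return counts[aid]
        c = 1
        for rid in network.and_nodes[aid].reactants:
            c *= count_or(rid)
        counts[aid] = c
        return c

    for oid in reversed(network.topological_order()):
        count_or(oid)
    for aid in network.and_nodes:
        count_and(aid)
    return counts


def naive_route_count(network: ReactionNetwork) -> int:
    """Naive count at the target (exact only without joined nodes)."""
    return naive_counts(network)[network.target]


# -- serialization ---------------------------------------------------------


def to_json(network: ReactionNetwork, indent: int | None = None) -> str:
    payload: dict[str, object] = {
        "format": JSON_FORMAT,
        "target": network.target,
        "or_nodes": [
            {
                "id": n.node_id,
                "smiles": n.molecule.structure,
                "is_building_block": n.molecule.is_building_block,
                "mol_weight": n.molecule.mol_weight,
            }
            for n in network.or_nodes.values()
        ],
        "and_nodes": [
            {
                "id": a.node_id,
                "template_id": a.template_id,
                "product": a.product,
                "reactants": list(a.reactants),
            }
            for a in network.and_nodes.values()
        ],
    }
    if network.incomplete:
        payload["incomplete"] = True
    return json.dumps(payload, indent=indent)


def _require(obj: Mapping[str, object], key: str, path: str) -> object:
    if key not in obj:
        raise SchemaError(f"missing key {key!r} at {path}")
    return obj[key]


def from_json(text: str) -> ReactionNetwork:
    """Parse network JSON; raises :class:`SchemaError` with the offending
    path, and :class:`CycleError` on a molecule-level cycle."""
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError("top-level value must be an object at $")
    fmt = _require(data, "format", "$")
    if fmt != JSON_FORMAT:
        raise SchemaError(f"unsupported format {fmt!r} at $.format")
    target_id = _require(data, "target", "$")
    or_rows = _require(data, "or_nodes", "$")
    and_rows = _require(data, "and_nodes", "$")
    if not isinstance(or_rows, list) or not isinstance(and_rows, list):
        raise SchemaError("or_nodes / and_nodes must be arrays at $")

    molecules: dict[str, Molecule] = {}
    for i, row in enumerate(or_rows):
        path = f"$.or_nodes[{i}]"
        if not isinstance(row, dict):
            raise SchemaError(f"expected object at {path}")
        oid = str(_require(row, "id", path))
        if oid in molecules:
            raise SchemaError(f"duplicate OR id {oid!r} at {path}")
        molecules[oid] = Molecule(
            structure=str(_require(row, "smiles", path)),
            is_building_block=bool(_require(row, "is_building_block", path)),
            mol_weight=float(row.get("mol_weight", 0.0)),
        )
    if target_id not in molecules:
        raise SchemaError("target id not among or_nodes at $.target")

    network = ReactionNetwork(molecules[target_id])
    for oid, mol in molecules.items():
        if oid != target_id:
            network.add_molecule(mol)
    id_map = {
        oid: network.or_id_for(mol.structure) for oid, mol in molecules.items()
    }
    for i, row in enumerate(and_rows):
        path = f"$.and_nodes[{i}]"
        if not isinstance(row, dict):
            raise SchemaError(f"expected object at {path}")
        product = str(_require(row, "product", path))
        reactants = _require(row, "reactants", path)
        if not isinstance(reactants, list) or not reactants:
            raise SchemaError(f"reactants must be a non-empty array at {path}")
        if product not in molecules:
            raise SchemaError(f"unknown product id {product!r} at {path}")
        for rid in reactants:
            if rid not in molecules:
                raise SchemaError(f"unknown reactant id {rid!r} at {path}")
        try:
            network.add_reaction(
                str(_require(row, "template_id", path)),
                molecules[product].structure,
                [molecules[str(r)].structure for r in reactants],
            )
        except NetworkError as exc:
            raise SchemaError(f"{exc} at {path}") from exc
    network.incomplete = bool(data.get("incomplete", False))
    network.validate()  # raises CycleError on molecule-level cycles
    return network


def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(network: ReactionNetwork) -> str:
    """Graphviz digraph: molecules as circles, reactions as boxes."""
    lines = ["digraph reaction_network {"]
    for n in network.or_nodes.values():
        lines.append(
            f"  {_dot_quote(n.node_id)} [shape=circle, "
            f"label={_dot_quote(n.molecule.structure)}];"
        )
    for a in network.and_nodes.values():
        lines.append(
            f"  {_dot_quote(a.node_id)} [shape=box, "
            f"label={_dot_quote(a.template_id)}];"
        )
    for a in network.and_nodes.values():
        lines.append(f"  {_dot_quote(a.product)} -> {_dot_quote(a.node_id)};")
        for rid in a.reactants:
            lines.append(f"  {_dot_quote(a.node_id)} -> {_dot_quote(rid)};")
    lines.append("}")
    return "\n".join(lines) + "\n"
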