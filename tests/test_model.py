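"""Core model: canonicalization, merging, naive counting, validation,
serialization."""

import itertools
import random

import pytest

from compret import (
    CycleError,
    Molecule,
    MoleculeParseError,
    ReactionNetwork,
    Route,
    SchemaError,
    canonicalize_molecule,
    from_json,
    is_valid_route,
    merge_route,
    naive_counts,
    naive_route_count,
    network_stats,
    to_dot,
    to_json,
)
from compret.model import DanglingNodeError

from .util import fig3b_route, independent_naive_count


def _random_smiles(rng: random.Random) -> str:
    """Small valid SMILES assembled from safe pieces."""
    atoms = ["C", "N", "O", "c1ccccc1", "CC(C)", "C(=O)O", "CCO", "CS"]
    return "".join(rng.choice(atoms) for _ in range(rng.randint(1, 4)))


class TestCanonicalize:
    def test_atom_order_invariance(self):
        assert canonicalize_molecule("OCC") == canonicalize_molecule("CCO")

    def test_idempotent_on_random_smiles(self):
        rng = random.Random(7)
        for _ in range(1000):
            s = canonicalize_molecule(_random_smiles(rng))
            assert canonicalize_molecule(s) == s

    def test_stereochemistry_preserved(self):
        canon = canonicalize_molecule("C/C=C/C")
        assert "/" in canon

    @pytest.mark.parametrize("bad", ["C1CC", "not-a-molecule", ""])
    def test_parse_error_names_input(self, bad):
        with pytest.raises(MoleculeParseError):
            canonicalize_molecule(bad)


def _route_fragment(target: str, steps: list[tuple[str, str, list[str]]],
                    building_blocks: set[str]) -> ReactionNetwork:
    net = ReactionNetwork(Molecule(target))
    for _, product, reactants in steps:
        for s in [product, *reactants]:
            net.add_molecule(Molecule(s, is_building_block=s in building_blocks))
    for tid, product, reactants in steps:
        net.add_reaction(tid, product, reactants)
    return net


class TestMergeRoute:
    def _two_routes_sharing_m(self):
        r1 = _route_fragment("T", [("t1", "T", ["M"]), ("t2", "M", ["B1"])],
                             {"B1"})
        r2 = _route_fragment("T", [("t1", "T", ["M"]), ("t3", "M", ["B2"])],
                             {"B2"})
        return r1, r2

    def test_shared_intermediate_unifies(self):
        r1, r2 = self._two_routes_sharing_m()
        net = ReactionNetwork(Molecule("T"))
        merge_route(net, r1)
        merge_route(net, r2)
        mid = net.or_id_for("M")
        assert len(net.or_nodes[mid].children) == 2

    def test_idempotent(self):
        r1, _ = self._two_routes_sharing_m()
        net = ReactionNetwork(Molecule("T"))
        merge_route(net, r1)
        before = network_stats(net)
        merge_route(net, r1)
        assert network_stats(net) == before

    def test_disjoint_routes_or_count_is_structure_union(self):
        rng = random.Random(3)
        fragments = []
        all_structures = {"T"}
        for i in range(5):
            inter, bb = f"I{i}", f"B{i}"
            fragments.append(_route_fragment(
                "T", [(f"t{i}", "T", [inter]), (f"u{i}", inter, [bb])], {bb}))
            all_structures |= {inter, bb}
        rng.shuffle(fragments)
        net = ReactionNetwork(Molecule("T"))
        for frag in fragments:
            merge_route(net, frag)
        assert network_stats(net).n_or == len(all_structures)

    def test_merge_order_does_not_change_node_sets(self):
        r1, r2 = self._two_routes_sharing_m()
        extra = _route_fragment("T", [("t4", "T", ["B3"])], {"B3"})
        results = []
        for perm in itertools.permutations([r1, r2, extra]):
            net = ReactionNetwork(Molecule("T"))
            for frag in perm:
                merge_route(net, frag)
            results.append((
                frozenset(n.molecule.structure for n in net.or_nodes.values()),
                frozenset(net.and_key(a) for a in net.and_nodes),
            ))
        assert len(set(results)) == 1

    def test_target_mismatch_rejected(self):
        from compret.model import MergeError

        frag = _route_fragment("X", [("t", "X", ["B"])], {"B"})
        net = ReactionNetwork(Molecule("T"))
        with pytest.raises(MergeError):
            merge_route(net, frag)


class TestNaiveCount:
    def test_shared_intermediate_overcounts(self, fig3b):
        assert naive_route_count(fig3b) == 4

    def test_counts_at_shared_node(self, fig3b):
        counts = naive_counts(fig3b)
        assert counts[fig3b.or_id_for("4")] == 2
        d = next(a for a, n in fig3b.and_nodes.items() if n.template_id == "D")
        e = next(a for a, n in fig3b.and_nodes.items() if n.template_id == "E")
        assert counts[d] == 1 and counts[e] == 1

    def test_single_reaction_all_building_blocks(self):
        net = _route_fragment("T", [("t", "T", ["B1", "B2"])], {"B1", "B2"})
        assert naive_route_count(net) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_independent_recursion(self, seed):
        from compret.fixtures import FixtureSpec, random_network

        net = random_network(FixtureSpec(seed=seed, n_molecules=10,
                                         share_probability=0.5, depth=3))
        assert naive_route_count(net) == independent_naive_count(net)

    def test_cycle_is_an_error(self):
        net = _route_fragment(
            "T", [("t1", "T", ["M"]), ("t2", "M", ["N"]), ("t3", "N", ["M2"])],
            set())
        # close a molecule-level cycle M -> N -> M by hand
        net.add_reaction("t4", "N", ["T"])
        with pytest.raises(CycleError):
            naive_route_count(net)


class TestIsValidRoute:
    def test_fig3b_route_via_d(self, fig3b):
        assert is_valid_route(fig3b, fig3b_route(fig3b, "D"))

    def test_non_building_block_leaf(self, fig3b):
        route = fig3b_route(fig3b, "D")
        selection = route.selection
        selection.pop(fig3b.or_id_for("4"))
        verdict = is_valid_route(fig3b, Route.from_selection(selection))
        assert not verdict and verdict.reason == "non-building-block leaf"

    def test_multiple_selections(self, fig3b):
        oid = fig3b.or_id_for("4")
        verdict = is_valid_route(
            fig3b, {oid: list(fig3b.or_nodes[oid].children)})
        assert not verdict and verdict.reason == "multiple selections"

    def test_dangling_reference_is_distinct_error(self, fig3b):
        with pytest.raises(DanglingNodeError):
            is_valid_route(fig3b, {"nope": "r0"})

    def test_selection_on_building_block(self, fig3b):
        route = fig3b_route(fig3b, "D")
        selection = route.selection
        bb = fig3b.or_id_for("5")
        selection[bb] = next(iter(fig3b.and_nodes))
        verdict = is_valid_route(fig3b, selection)
        assert not verdict


class TestStatsAndSerialization:
    def test_fig3b_stats(self, fig3b):
        assert network_stats(fig3b) == (6, 5, 11)

    def test_building_block_only_network(self):
        net = ReactionNetwork(Molecule("B", is_building_block=True))
        assert network_stats(net) == (1, 0, 0)

    def test_json_roundtrip_lossless(self, fig3b, fig3a):
        for net in (fig3b, fig3a):
            again = from_json(to_json(net))
            assert to_json(again) == to_json(net)
            assert network_stats(again) == network_stats(net)

    def test_json_missing_target_is_schema_error(self, fig3b):
        import json

        data = json.loads(to_json(fig3b))
        del data["target"]
        with pytest.raises(SchemaError, match="target"):
            from_json(json.dumps(data))

    def test_json_rejects_cycles(self):
        import json

        net = _route_fragment("T", [("t1", "T", ["M"])], set())
        data = json.loads(to_json(net))
        data["and_nodes"].append({
            "id": "r9", "template_id": "t2",
            "product": net.or_id_for("M"), "reactants": [net.target],
        })
        # M has no reaction, add one so only the cycle is at fault
        with pytest.raises(CycleError):
            from_json(json.dumps(data))

    def test_dot_shapes_match_counts(self, fig3b):
        dot = to_dot(fig3b)
        stats = network_stats(fig3b)
        assert dot.count("shape=circle") == stats.n_or
        assert dot.count("shape=box") == stats.n_and
        assert dot.startswith("digraph")
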