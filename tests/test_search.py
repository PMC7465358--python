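"""DFPN: terminal evaluation, number updates, route finding, network
construction."""

import random

import pytest

from compret import (
    Molecule,
    SearchConfig,
    SearchOutcome,
    TerminalStatus,
    build_network,
    count_routes,
    enumerate_routes,
    evaluate_terminal,
    find_route,
    is_valid_route,
    network_stats,
    route_key,
    step_score,
    to_json,
    update_numbers,
)
from compret.fixtures import toy_chemistry_suite
from compret.search import INF, ProofNumbers
from compret.toy import ToyBackend

from .util import tree_route


class TestEvaluateTerminal:
    CFG = SearchConfig(md=3)

    def test_building_block_proven_at_any_depth(self):
        bb = Molecule("A", is_building_block=True)
        for depth in (0, 3):
            assert evaluate_terminal(bb, depth, self.CFG, {"A"}) \
                is TerminalStatus.PROVEN

    def test_depth_limit_disproves(self):
        mol = Molecule("AAB")
        assert evaluate_terminal(mol, 3, self.CFG, set()) \
            is TerminalStatus.DISPROVEN

    def test_no_applicable_template_disproves(self):
        mol = Molecule("AAB")
        assert evaluate_terminal(mol, 1, self.CFG, set(), n_proposals=0) \
            is TerminalStatus.DISPROVEN

    def test_otherwise_unknown(self):
        mol = Molecule("AAB")
        assert evaluate_terminal(mol, 1, self.CFG, set(), n_proposals=2) \
            is TerminalStatus.UNKNOWN


class TestUpdateNumbers:
    def test_or_min_and_sum(self):
        children = [ProofNumbers(3, 2), ProofNumbers(1, 4),
                    ProofNumbers(INF, 5)]
        result = update_numbers("OR", children)
        assert result.pn == 1
        assert result.dn == 11

    def test_and_saturates_on_disproven_child(self):
        children = [ProofNumbers(2, 3), ProofNumbers(INF, 0)]
        result = update_numbers("AND", children)
        assert result.pn == INF
        assert result.dn == 0

    def test_empty_or_is_disproven(self):
        result = update_numbers("OR", [])
        assert result.disproven

    def test_empty_and_is_an_error(self):
        with pytest.raises(ValueError):
            update_numbers("AND", [])

    @pytest.mark.parametrize("seed", range(20))
    def test_fixpoint_agrees_with_exhaustive_solver(self, seed):
        """Iterating the min/sum updates over a random terminal-labelled
        AND/OR dag marks exactly the nodes an independent boolean solver
        proves."""
        rng = random.Random(seed)
        n = rng.randint(4, 20)
        kinds = {}
        children = {}
        terminal = {}
        for i in range(n):
            kinds[i] = rng.choice(["OR", "AND"])
            later = list(range(i + 1, n))
            if not later or rng.random() < 0.3:
                terminal[i] = rng.random() < 0.5  # leaf: proven or disproven
                children[i] = []
            else:
                children[i] = rng.sample(later,
                                         rng.randint(1, min(3, len(later))))

        def solve(i):  # independent boolean AND/OR evaluation
            if i in terminal:
                return terminal[i]
            values = [solve(c) for c in children[i]]
            return any(values) if kinds[i] == "OR" else all(values)

        numbers = {}
        for i in range(n):
            if i in terminal:
                numbers[i] = (ProofNumbers.proven_leaf() if terminal[i]
                              else ProofNumbers.disproven_leaf())
            else:
                numbers[i] = ProofNumbers()
        changed = True
        while changed:
            changed = False
            for i in range(n):
                if i in terminal:
                    continue
                updated = update_numbers(
                    kinds[i], [numbers[c] for c in children[i]])
                if (updated.pn, updated.dn) != (numbers[i].pn, numbers[i].dn):
                    numbers[i] = updated
                    changed = True
        for i in range(n):
            assert numbers[i].proven == solve(i), f"node {i} (seed {seed})"


class TestFindRoute:
    def test_building_block_target_trivial_route(self, toy_backend):
        res = find_route("A", [], {"A"}, SearchConfig(md=3), toy_backend)
        assert res.outcome is SearchOutcome.PROVEN
        assert network_stats(res.route) == (1, 0, 0)

    def test_unique_two_step_decomposition(self, toy_backend):
        case = next(c for c in toy_chemistry_suite(0)
                    if c.name == "unique-route")
        res = find_route(case.target, case.templates, case.building_blocks,
                         case.config, toy_backend)
        assert res.outcome is SearchOutcome.PROVEN
        route = tree_route(res.route)
        assert is_valid_route(res.route, route)
        assert route_key(res.route, route) in case.expected_route_keys

    def test_empty_template_set_disproves(self, toy_backend):
        res = find_route("AAB", [], {"A", "B"}, SearchConfig(md=3),
                         toy_backend)
        assert res.outcome is SearchOutcome.DISPROVEN

    def test_budget_exhaustion_is_inconclusive(self, toy_backend):
        case = next(c for c in toy_chemistry_suite(0)
                    if c.name == "joined-nodes")
        tiny = SearchConfig(md=case.config.md, node_budget=1)
        res = find_route(case.target, case.templates, case.building_blocks,
                         tiny, toy_backend)
        assert res.outcome is SearchOutcome.INCONCLUSIVE

    def test_route_respects_md(self, toy_backend):
        for case in toy_chemistry_suite(0):
            res = find_route(case.target, case.templates,
                             case.building_blocks, case.config, toy_backend)
            if res.outcome is SearchOutcome.PROVEN:
                route = tree_route(res.route)
                assert step_score(res.route, route) <= case.config.md


class TestBuildNetwork:
    def test_joined_node_pattern_arises(self, toy_backend):
        """A molecule reachable by two rules gets two reaction children."""
        case = next(c for c in toy_chemistry_suite(0)
                    if c.name == "joined-nodes")
        net = build_network(case.target, case.templates, case.building_blocks,
                            case.config, toy_backend)
        joined = [o for o in net.or_nodes.values() if len(o.children) >= 2]
        assert joined, "expected at least one joined-style choice point"

    def test_md_below_minimal_depth_gives_empty_network(self, toy_backend):
        case = next(c for c in toy_chemistry_suite(0)
                    if c.name == "too-shallow")
        net = build_network(case.target, case.templates, case.building_blocks,
                            case.config, toy_backend)
        assert count_routes(net).count == 0

    @pytest.mark.parametrize("case", toy_chemistry_suite(0),
                             ids=lambda c: c.name)
    def test_enumerated_set_matches_exhaustive_oracle(self, toy_backend, case):
        net = build_network(case.target, case.templates, case.building_blocks,
                            case.config, toy_backend)
        got = {route_key(net, r) for r in enumerate_routes(net)}
        assert got == set(case.expected_route_keys)

    @pytest.mark.parametrize("case", toy_chemistry_suite(0),
                             ids=lambda c: c.name)
    def test_soundness_and_depth_bound(self, toy_backend, case):
        net = build_network(case.target, case.templates, case.building_blocks,
                            case.config, toy_backend)
        for route in enumerate_routes(net):
            assert is_valid_route(net, route)
            assert step_score(net, route) <= case.config.md

    def test_deterministic_json(self, toy_backend):
        case = next(c for c in toy_chemistry_suite(0)
                    if c.name == "joined-nodes")
        nets = [
            build_network(case.target, case.templates, case.building_blocks,
                          case.config, ToyBackend())
            for _ in range(2)
        ]
        assert to_json(nets[0]) == to_json(nets[1])

    def test_budget_exhaustion_sets_incomplete_flag(self, toy_backend):
        case = next(c for c in toy_chemistry_suite(0)
                    if c.name == "joined-nodes")
        tiny = SearchConfig(md=case.config.md, node_budget=1)
        net = build_network(case.target, case.templates, case.building_blocks,
                            tiny, toy_backend)
        assert net.incomplete
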