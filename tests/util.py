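"""Shared test helpers and independent oracles."""

from __future__ import annotations

import networkx as nx

from compret import ReactionNetwork, Route


def fig3b_route(net: ReactionNetwork, via: str) -> Route:
    """The Fig-style shared-intermediate route choosing reaction *via*
    (D or E) for the joined molecule."""
    m = {name: net.or_id_for(name) for name in "1234"}
    chosen = {}
    for name, rxn in (("1", "A"), ("2", "F"), ("3", "G"), ("4", via)):
        oid = m[name]
        for aid in net.or_nodes[oid].children:
            if net.and_nodes[aid].template_id == rxn:
                chosen[oid] = aid
    return Route.from_selection(chosen)


def tree_route(net: ReactionNetwork) -> Route:
    """Selection implied by a route-shaped network (<=1 reaction per
    molecule)."""
    selection = {}
    for oid, node in net.or_nodes.items():
        assert len(node.children) <= 1, "network is not route-shaped"
        if node.children:
            selection[oid] = node.children[0]
    return Route.from_selection(selection)


def independent_naive_count(net: ReactionNetwork) -> int:
    """Second implementation of the sum/product recursion, via networkx
    topological order instead of memoized recursion."""
    g = nx.DiGraph()
    for oid, node in net.or_nodes.items():
        g.add_node(oid)
        for aid in node.children:
            g.add_edge(oid, aid)
    for aid, node in net.and_nodes.items():
        for rid in node.reactants:
            g.add_edge(aid, rid)
    counts: dict[str, int] = {}
    for node in reversed(list(nx.topological_sort(g))):
        if node in net.or_nodes:
            mol = net.or_nodes[node].molecule
            if mol.is_building_block:
                counts[node] = 1
            else:
                counts[node] = sum(counts[a] for a in net.or_nodes[node].children)
        else:
            prod = 1
            for rid in net.and_nodes[node].reactants:
                prod *= counts[rid]
            counts[node] = prod
    return counts[net.target]


def route_longest_path(net: ReactionNetwork, route: Route) -> int:
    """Independent longest-path oracle over the route's reaction DAG."""
    selection = route.selection
    g = nx.DiGraph()
    g.add_node(net.target)
    frontier = [net.target]
    while frontier:
        oid = frontier.pop()
        aid = selection.get(oid)
        if aid is None:
            continue
        for rid in net.and_nodes[aid].reactants:
            g.add_edge(oid, rid)
            frontier.append(rid)
    if g.number_of_edges() == 0:
        return 0
    # the target is the only source of the closure DAG, so the globally
    # longest path is a target-to-leaf path
    return nx.dag_longest_path_length(g)
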