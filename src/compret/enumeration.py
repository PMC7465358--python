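"""Exact enumeration of synthetic routes in an AND/OR reaction network.

The naive sum/product count treats each reactant as synthesized
independently and therefore over-counts whenever a molecule is shared as a
reactant of several reactions (a "joined node"): in the canonical
counter-example a network holds only two routes while the recursion counts
four.  This module enumerates the true route set by a binary partition
scheme with a prohibited list: at each step the first undetermined molecule
choice point (in a stable topological order from the target) is either
*committed* to its first viable reaction or that reaction is *prohibited*,
splitting the remaining route set into two disjoint halves.  A branch in
which some included molecule has no viable reaction left is dead and is
pruned.  Every leaf of the recursion is a fully determined route, emitted
exactly once.

:func:`brute_force_routes` is the independent oracle: it materializes every
total reaction assignment, restricts each to the closure from the target,
and keeps the valid ones.
"""

from __future__ import annotations

import itertools
from typing import Iterator, NamedTuple

from .model import ReactionNetwork, Route, is_valid_route, route_closure

__all__ = [
    "RouteKey",
    "route_key",
    "enumerate_routes",
    "count_routes",
    "brute_force_routes",
    "CountResult",
    "RouteError",
]

#: Frozen set of (product structure, template id, sorted reactant structures).
RouteKey = frozenset


class RouteError(ValueError):
    """The route is invalid for the requested operation."""


def route_key(network: ReactionNetwork, route: Route) -> RouteKey:
    """Canonical, traversal-order-independent identity of a route.

    Two routes are the same synthetic plan iff their keys are equal.
    Raises :class:`RouteError` on an invalid route.
    """
    verdict = is_valid_route(network, route)
    if not verdict:
        raise RouteError(f"invalid route: {verdict.reason}")
    _, and_ids = route_closure(network, route)
    return frozenset(network.and_key(a) for a in and_ids)


def _choice_points(network: ReactionNetwork) -> list[str]:
    """Stable topological order of molecule ids, target first."""
    return [
        oid
        for oid in network.topological_order()
        if not network.or_nodes[oid].molecule.is_building_block
    ]


def enumerate_routes(
    network: ReactionNetwork, cap: int | None = None
) -> Iterator[Route]:
    """Lazily emit every distinct synthetic route of the network.

    Complete, duplicate-free and sound: the emitted route set equals the
    brute-force assignment oracle's on any network small enough to compare.
    Emission stops after *cap* routes when given.  Raises
    :class:`~compret.model.CycleError` on a cyclic network.
    """
    order = network.topological_order()  # raises CycleError on cycles
    position = {oid: i for i, oid in enumerate(order)}
    if cap is not None and cap <= 0:
        return

    def included(commit: dict[str, str]) -> list[str]:
        """Molecule ids in the closure under the current commitments."""
        seen = {network.target}
        stack = [network.target]
        out = [network.target]
        while stack:
            oid = stack.pop()
            aid = commit.get(oid)
            if aid is None:
                continue
            for rid in network.and_nodes[aid].reactants:
                if rid not in seen:
                    seen.add(rid)
                    out.append(rid)
                    stack.append(rid)
        return out

    def viable(oid: str, prohibited: dict[str, frozenset[str]]) -> list[str]:
        banned = prohibited.get(oid, frozenset())
        return [a for a in network.or_nodes[oid].children if a not in banned]

    def branch(
        commit: dict[str, str], prohibited: dict[str, frozenset[str]]
    ) -> Iterator[Route]:
        inc = included(commit)
        undetermined: str | None = None
        for oid in sorted(inc, key=position.__getitem__):
            node = network.or_nodes[oid]
            if node.molecule.is_building_block:
                continue
            if oid in commit:
                continue
            if not viable(oid, prohibited):
                return  # dead choice point: no route completes this branch
            if undetermined is None:
                undetermined = oid
        if undetermined is None:
            yield Route.from_selection(commit)
            return
        chosen = viable(undetermined, prohibited)[0]
        # partition: routes choosing `chosen` here vs. routes that do not
        yield from branch({**commit, undetermined: chosen}, prohibited)
        banned = prohibited.get(undetermined, frozenset()) | {chosen}
        yield from branch(commit, {**prohibited, undetermined: banned})

    emitted = 0
    for route in branch({}, {}):
        yield route
        emitted += 1
        if cap is not None and emitted >= cap:
            return


class CountResult(NamedTuple):
    count: int
    capped: bool


def count_routes(network: ReactionNetwork, cap: int = 1_500_000) -> CountResult:
    """Count routes by enumeration, aborting once *cap* routes are found.

    ``capped`` is set only when the network holds more routes than *cap*
    (one extra route is probed to decide).
    """
    if cap == 0:
        any_route = next(enumerate_routes(network, cap=1), None) is not None
        return CountResult(0, any_route)
    count = 0
    for _ in enumerate_routes(network, cap=cap + 1):
        count += 1
    if count > cap:
        return CountResult(cap, True)
    return CountResult(count, False)


def brute_force_routes(
    network: ReactionNetwork, limit: int = 10**6
) -> dict[RouteKey, Route]:
    """Oracle enumeration for small networks.

    Materializes every total assignment of a reaction to each
    non-building-block molecule, restricts it to the closure from the
    target, and keeps valid routes, deduplicated by :func:`route_key`.
    Refuses instances whose raw assignment count exceeds *limit*.
    """
    network.topological_order()  # cycle check up front
    points = [
        oid
        for oid in _choice_points(network)
        if network.or_nodes[oid].children
    ]
    total = 1
    for oid in points:
        total *= len(network.or_nodes[oid].children)
        if total > limit:
            raise ValueError(
                f"instance too large for brute force (> {limit} assignments)"
            )
    out: dict[RouteKey, Route] = {}
    for combo in itertools.product(
        *(network.or_nodes[oid].children for oid in points)
    ):
        assignment = dict(zip(points, combo))
        included, _ = route_closure(network, assignment)
        restricted = {
            oid: assignment[oid] for oid in included if oid in assignment
        }
        route = Route.from_selection(restricted)
        if is_valid_route(network, route):
            out.setdefault(route_key(network, route), route)
    return out
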