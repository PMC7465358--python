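"""Route ranking: STEP, MSCS and REF scores.

STEP is the longest number of synthesis steps on any target-to-leaf path
of the route (smaller is better).  MSCS is the mean synthetic-complexity
score of the route's distinct molecules, bounded in [0, 5] like the SCScore
it averages (smaller is better).  REF compares a route against a reference
route: the distinct molecules of each are sorted by molecular weight, and
if the two lists have equal length REF is the sum of pairwise Tanimoto
fingerprint similarities (larger is better); on a length mismatch REF is 0.

The complexity scorer is a pluggable contract (any callable mapping a
structure to [0, 5]); :func:`default_complexity_scorer` supplies a
structural heuristic stand-in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .model import Molecule, ReactionNetwork, Route, is_valid_route, route_closure

__all__ = [
    "ComplexityScorer",
    "RouteScoreRecord",
    "ScoringError",
    "step_score",
    "mscs",
    "ref_score",
    "rank_routes",
    "default_complexity_scorer",
    "tanimoto",
]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ComplexityScorer:
    """Molecular complexity contract: structure -> float in [0, 5]."""

    name: str
    fn: Callable[[str], float]

    def __call__(self, structure: str) -> float:
        value = float(self.fn(structure))
        if not 0.0 <= value <= 5.0:
            warnings.warn(
                f"complexity scorer {self.name!r} returned {value:.3f} for "
                f"{structure!r}; clamping to [0, 5]",
                stacklevel=2,
            )
            value = min(5.0, max(0.0, value))
        return value


@dataclass(frozen=True)
class RouteScoreRecord:
    route_id: str
    step: int
    mscs: float
    ref: float | None = None


def _checked(network: ReactionNetwork, route: Route) -> None:
    verdict = is_valid_route(network, route)
    if not verdict:
        raise ScoringError(f"invalid route: {verdict.reason}")


def route_molecules(network: ReactionNetwork, route: Route) -> list[Molecule]:
    """Distinct molecules of a route (target, intermediates, leaves), in
    closure order."""
    or_ids, _ = route_closure(network, route)
    return [network.or_nodes[oid].molecule for oid in or_ids]


def step_score(
    network: ReactionNetwork, route: Route, mode: str = "longest_path"
) -> int:
    """Number of synthesis steps of a route.

    ``longest_path`` (default) is the length in reactions of the longest
    target-to-leaf path; ``total`` counts the route's distinct reactions.
    """
    _checked(network, route)
    if mode == "total":
        _, and_ids = route_closure(network, route)
        return len(and_ids)
    if mode != "longest_path":
        raise ValueError(f"unknown step mode {mode!r}")
    selection = route.selection

    depth_cache: dict[str, int] = {}

    def depth(oid: str) -> int:
        if oid in depth_cache:
            return depth_cache[oid]
        aid = selection.get(oid)
        if aid is None:
            d = 0
        else:
            d = 1 + max(depth(r) for r in network.and_nodes[aid].reactants)
        depth_cache[oid] = d
        return d

    return depth(network.target)


def mscs(network: ReactionNetwork, route: Route, scorer: ComplexityScorer) -> float:
    """Mean complexity score over the distinct molecules of the route."""
    _checked(network, route)
    molecules = route_molecules(network, route)
    return sum(scorer(m.structure) for m in molecules) / len(molecules)


def tanimoto(a: frozenset[int], b: frozenset[int]) -> float:
    """Tanimoto similarity of two bit sets (1.0 for two empty sets)."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _sorted_molecules(mols: Iterable[Molecule]) -> list[Molecule]:
    # molecular-weight order; ties broken by structure for determinism
    return sorted(mols, key=lambda m: (m.mol_weight, m.structure))


def ref_score(
    network: ReactionNetwork,
    route: Route,
    reference_network: ReactionNetwork,
    reference: Route,
    fingerprint: Callable[[str], frozenset[int]] | None = None,
) -> float:
    """Similarity of a route to a reference route.

    Both molecule lists are sorted by molecular weight and paired
    positionally; the score is the sum of Tanimoto similarities, or 0 when
    the list lengths differ.
    """
    _checked(network, route)
    _checked(reference_network, reference)
    if fingerprint is None:
        from .templates import RDKitBackend

        fingerprint = RDKitBackend().molecule_fingerprint
    ours = _sorted_molecules(route_molecules(network, route))
    theirs = _sorted_molecules(route_molecules(reference_network, reference))
    if len(ours) != len(theirs):
        return 0.0
    total = 0.0
    for a, b in zip(ours, theirs):
        try:
            fa, fb = fingerprint(a.structure), fingerprint(b.structure)
        except Exception as exc:
            raise ScoringError(
                f"fingerprint failed for molecule {a.structure!r} / "
                f"{b.structure!r}: {exc}"
            ) from exc
        total += tanimoto(fa, fb)
    return total


_DIRECTIONS = {"step": 1, "mscs": 1, "ref": -1}  # +1 ascending, -1 descending


def rank_routes(
    records: Sequence[RouteScoreRecord],
    method: str,
    top_k: int | None = None,
) -> list[str]:
    """Route ids ordered best-first: ascending STEP/MSCS, descending REF.

    Ties are broken by route id, keeping the ranking a stable permutation
    of the input.
    """
    method = method.lower()
    if method not in _DIRECTIONS:
        raise ValueError(f"unknown ranking method {method!r}")
    if method == "ref":
        if any(r.ref is None for r in records):
            raise ScoringError("REF ranking requested without reference scores")
        keyed = sorted(records, key=lambda r: (-r.ref, r.route_id))  # type: ignore[operator]
    elif method == "step":
        keyed = sorted(records, key=lambda r: (r.step, r.route_id))
    else:
        keyed = sorted(records, key=lambda r: (r.mscs, r.route_id))
    ids = [r.route_id for r in keyed]
    return ids[:top_k] if top_k is not None else ids


def default_complexity_scorer() -> ComplexityScorer:
    """Deterministic structural stand-in for a learned complexity model.

    Scores ``5 * (1 - exp(-(heavy_atoms + 2 * rings) / 25))``, which is
    bounded in [0, 5) and strictly increasing in heavy-atom count for
    molecules differing only by chain extension.  Structures that RDKit
    cannot parse (e.g. toy token strings) fall back to string length as
    the size measure.
    """

    def size(structure: str) -> float:
        try:
            from rdkit import Chem, RDLogger

            RDLogger.DisableLog("rdApp.*")
            mol = Chem.MolFromSmiles(structure)
        except Exception:  # pragma: no cover - rdkit always importable here
            mol = None
        if mol is None:
            return float(len(structure))
        return float(mol.GetNumHeavyAtoms()
                     + 2 * mol.GetRingInfo().NumRings())

    def score(structure: str) -> float:
        return 5.0 * (1.0 - math.exp(-size(structure) / 25.0))

    return ComplexityScorer(name="heavy-atom-heuristic", fn=score)
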