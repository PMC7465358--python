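"""Route fingerprints and 2-D embedding for route-diversity visualization.

A route's fingerprint is the elementwise sum of the structural reaction
fingerprints of its reactions, counted with multiplicity: a template used
twice contributes twice.  The fingerprint is therefore invariant to the
order in which reactions appear and additive over disjoint sub-routes.
A t-SNE embedding of sampled route fingerprints gives a 2-D overview of
how diverse the enumerated routes are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import ReactionNetwork, Route, route_closure
from .templates import ChemistryBackend, RetroTemplate

__all__ = [
    "RouteFingerprint",
    "FingerprintError",
    "template_fingerprint",
    "route_fp",
    "embed_2d",
]


class FingerprintError(ValueError):
    pass


@dataclass(frozen=True)
class RouteFingerprint:
    """Sparse non-negative vector indexed by reaction-fingerprint bit."""

    route_id: str
    vector: Mapping[int, float]

    def as_dict(self) -> dict[int, float]:
        return dict(self.vector)


def template_fingerprint(
    template: RetroTemplate, backend: ChemistryBackend
) -> dict[int, int]:
    """Structural reaction fingerprint of a template (sparse counts)."""
    try:
        return backend.reaction_fingerprint(template)
    except Exception as exc:
        raise FingerprintError(
            f"cannot fingerprint template {template.id!r}: {exc}"
        ) from exc


def route_fp(
    network: ReactionNetwork,
    route: Route,
    templates: Mapping[str, RetroTemplate],
    backend: ChemistryBackend,
    route_id: str = "",
) -> RouteFingerprint:
    """Sum of template fingerprints over the route's reaction multiset."""
    _, and_ids = route_closure(network, route)
    vector: dict[int, float] = {}
    for aid in and_ids:
        tid = network.and_nodes[aid].template_id
        template = templates.get(tid)
        if template is None:
            raise FingerprintError(f"missing template {tid!r} for route fingerprint")
        for bit, value in template_fingerprint(template, backend).items():
            vector[bit] = vector.get(bit, 0.0) + value
    return RouteFingerprint(route_id=route_id, vector=vector)


def embed_2d(
    fingerprints: Sequence[RouteFingerprint],
    seed: int,
    sample_size: int | None = None,
) -> tuple[np.ndarray, list[int]]:
    """t-SNE embedding of (a sample of) route fingerprints.

    Returns the (n, 2) coordinate array and the indices of the sampled
    fingerprints.  Deterministic under a fixed seed.  A degenerate input
    (all fingerprints identical) yields a warning, not an error.
    """
    if len(fingerprints) < 2:
        raise ValueError("need at least two fingerprints to embed")
    n = len(fingerprints)
    if sample_size is None or sample_size >= n:
        indices = list(range(n))
    else:
        if sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        rng = np.random.default_rng(seed)
        indices = sorted(rng.choice(n, size=sample_size, replace=False).tolist())
    chosen = [fingerprints[i] for i in indices]
    dims = sorted({bit for fp in chosen for bit in fp.vector})
    dim_index = {b: j for j, b in enumerate(dims)}
    matrix = np.zeros((len(chosen), max(len(dims), 1)))
    for i, fp in enumerate(chosen):
        for bit, value in fp.vector.items():
            matrix[i, dim_index[bit]] = value
    if np.allclose(matrix, matrix[0]):
        warnings.warn("all fingerprints identical; embedding is degenerate",
                      stacklevel=2)

    from sklearn.manifold import TSNE

    perplexity = min(30.0, max(1.0, (len(chosen) - 1) / 3))
    tsne = TSNE(
        n_components=2,
        random_state=seed,
        init="random",
        perplexity=perplexity,
        max_iter=500,
    )
    coords = tsne.fit_transform(matrix)
    if not np.all(np.isfinite(coords)):
        warnings.warn("t-SNE produced non-finite coordinates; returning zeros",
                      stacklevel=2)
        coords = np.zeros_like(coords)
    return coords, indices
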