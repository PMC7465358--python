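"""Deterministic toy string-rewrite chemistry.

Molecules are token strings over a small alphabet and "reactions" are
string rewrites, so every search/enumeration result can be verified by an
exhaustive oracle without a chemistry toolkit.  Rule semantics:

* split rule, k >= 2 reactants, written ``f1f2>>f1.f2`` (the product
  pattern is the concatenation of the fragments): applies to a product
  string by cutting it into k consecutive non-empty parts such that part
  *j* contains fragment *j* as a substring; the parts are the reactants.
  ``AB>>A.B`` on ``AAB`` gives (A, AB) and (AA, B).
* rewrite rule, 1 reactant, ``lhs>>rhs`` with ``len(rhs) < len(lhs)``:
  the reactant is the product with one occurrence of ``lhs`` replaced by
  ``rhs``.

Every rule strictly shortens each reactant relative to the product, so
retrosynthetic expansion terminates in at most ``len(product)`` steps and
the molecule-level graph is acyclic by construction.

Forward application is the inverse: concatenation of the parts for split
rules, back-substitution for rewrite rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .templates import MAX_REACTANTS, RetroTemplate, TemplateError, split_transform

__all__ = ["ToyChemistry", "ToyBackend"]


@dataclass(frozen=True)
class ToyChemistry:
    """A rule set over a token alphabet with a building-block list."""

    alphabet: frozenset[str]
    rules: tuple[RetroTemplate, ...]
    building_blocks: frozenset[str]

    def __post_init__(self) -> None:
        backend = ToyBackend()
        for rule in self.rules:
            backend.validate_template(rule)


def _splits(s: str, k: int) -> Iterator[tuple[str, ...]]:
    """All ways to cut *s* into k consecutive non-empty parts."""
    if k == 1:
        if s:
            yield (s,)
        return
    for i in range(1, len(s) - k + 2):
        for rest in _splits(s[i:], k - 1):
            yield (s[:i], *rest)


class ToyBackend:
    """Chemistry-backend implementation over token strings."""

    name = "toy"

    def canonicalize(self, structure: str) -> str:
        if not structure:
            from .model import MoleculeParseError

            raise MoleculeParseError("empty toy structure")
        return structure

    def mol_weight(self, structure: str) -> float:
        return float(len(structure))

    def validate_template(self, template: RetroTemplate) -> None:
        pattern, fragments = split_transform(template.retro_transform)
        if len(fragments) > MAX_REACTANTS:
            raise TemplateError(
                f"toy rule {template.id} has {len(fragments)} fragments"
            )
        if len(fragments) == 1:
            if len(fragments[0]) >= len(pattern):
                raise TemplateError(
                    f"toy rewrite rule {template.id} must strictly shorten"
                )
        elif "".join(fragments) != pattern:
            raise TemplateError(
                f"toy split rule {template.id}: product pattern must be the "
                "concatenation of its fragments"
            )

    def n_reactant_patterns(self, template: RetroTemplate) -> int:
        return len(split_transform(template.retro_transform)[1])

    def apply_retro(
        self, template: RetroTemplate, product: str
    ) -> list[tuple[str, ...]]:
        pattern, fragments = split_transform(template.retro_transform)
        out: list[tuple[str, ...]] = []
        if len(fragments) == 1:
            rhs = fragments[0]
            start = 0
            while True:
                i = product.find(pattern, start)
                if i < 0:
                    break
                out.append((product[:i] + rhs + product[i + len(pattern):],))
                start = i + 1
        else:
            for parts in _splits(product, len(fragments)):
                if all(f in p for f, p in zip(fragments, parts)):
                    out.append(parts)
        return out

    def forward(
        self, template: RetroTemplate, reactants: Sequence[str]
    ) -> list[str]:
        pattern, fragments = split_transform(template.retro_transform)
        if len(fragments) != len(reactants):
            return []
        if len(fragments) == 1:
            rhs = fragments[0]
            s = reactants[0]
            products = []
            start = 0
            while True:
                i = s.find(rhs, start)
                if i < 0:
                    break
                products.append(s[:i] + pattern + s[i + len(rhs):])
                start = i + 1
            return products
        if all(f in p for f, p in zip(fragments, reactants)):
            return ["".join(reactants)]
        return []

    def molecule_fingerprint(self, structure: str) -> frozenset[int]:
        # one bit per distinct token
        return frozenset(ord(ch) for ch in structure)

    def reaction_fingerprint(self, template: RetroTemplate) -> dict[int, int]:
        # token histogram of the product pattern (the reaction core)
        pattern, _ = split_transform(template.retro_transform)
        hist: dict[int, int] = {}
        for ch in pattern:
            hist[ord(ch)] = hist.get(ord(ch), 0) + 1
        return hist
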