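"""Retrosynthetic templates and the chemistry-backend contract.

A retro template maps one product pattern to 1-3 reactant patterns.  Two
interchangeable backends implement template application:

* :class:`RDKitBackend` — reaction SMARTS on real molecules via RDKit's
  reaction machinery, with a forward relevance check.
* ``compret.toy.ToyBackend`` — a deterministic string-rewrite chemistry for
  dependency-light, oracle-checkable testing.

Template files are TSV: ``id<TAB>name<TAB>retro_smarts<TAB>frequency``.
Building-block files hold one structure per line; ``#`` starts a comment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "RetroTemplate",
    "RetroProposal",
    "TemplateError",
    "ParseReport",
    "ChemistryBackend",
    "RDKitBackend",
    "parse_template_file",
    "parse_building_blocks",
    "apply_retro",
    "relevance_check",
    "split_transform",
]

MAX_REACTANTS = 3


class TemplateError(ValueError):
    """A template is malformed or cannot be applied."""


@dataclass(frozen=True)
class RetroTemplate:
    """A retro transform ``product_pattern>>reactant_patterns`` with a
    frequency-order rank (rank 1 = most frequent)."""

    id: str
    name: str
    retro_transform: str
    rank: int = 0
    frequency: int = 0


@dataclass(frozen=True)
class RetroProposal:
    """One way a template decomposes a product into reactants."""

    template_id: str
    reactants: tuple[str, ...]
    relevance_checked: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= MAX_REACTANTS:
            raise TemplateError("a proposal needs between 1 and 3 reactants")


def split_transform(transform: str) -> tuple[str, list[str]]:
    """Split ``product>>r1.r2`` into the product pattern and reactant
    patterns, respecting parenthesized component groups."""
    if ">>" not in transform:
        raise TemplateError(f"transform lacks '>>': {transform!r}")
    product, _, rhs = transform.partition(">>")
    parts: list[str] = []
    depth = 0
    cur = []
    for ch in rhs:
        if ch == "." and depth == 0:
            parts.append("".join(cur))
            cur = []
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        cur.append(ch)
    parts.append("".join(cur))
    if not product or any(not p for p in parts):
        raise TemplateError(f"empty pattern in transform {transform!r}")
    return product, parts


class ChemistryBackend(Protocol):
    """Contract every chemistry engine must satisfy."""

    name: str

    def canonicalize(self, structure: str) -> str: ...

    def mol_weight(self, structure: str) -> float: ...

    def validate_template(self, template: RetroTemplate) -> None: ...

    def n_reactant_patterns(self, template: RetroTemplate) -> int: ...

    def apply_retro(
        self, template: RetroTemplate, product: str
    ) -> list[tuple[str, ...]]: ...

    def forward(
        self, template: RetroTemplate, reactants: Sequence[str]
    ) -> list[str]: ...

    def molecule_fingerprint(self, structure: str) -> frozenset[int]: ...

    def reaction_fingerprint(self, template: RetroTemplate) -> dict[int, int]: ...


@dataclass
class ParseReport:
    """Outcome of parsing a template TSV."""

    templates: list[RetroTemplate]
    rejected_arity: int = 0
    row_errors: list[tuple[int, str]] = field(default_factory=list)


def parse_template_file(
    text: str, backend: ChemistryBackend | None = None
) -> ParseReport:
    """Parse a template TSV, sort by descending frequency, assign ranks.

    Templates with more than three reactant patterns are rejected (counted
    in ``rejected_arity``); rows whose pattern fails backend validation are
    collected per-row without aborting the parse.  A duplicate id is fatal.
    """
    rows: list[RetroTemplate] = []
    report = ParseReport(templates=rows)
    seen_ids: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            report.row_errors.append((lineno, f"expected 4 columns, got {len(cols)}"))
            continue
        tid, name, transform, freq_s = (c.strip() for c in cols)
        if tid in seen_ids:
            raise TemplateError(f"duplicate template id {tid!r} on line {lineno}")
        seen_ids.add(tid)
        try:
            frequency = int(freq_s)
        except ValueError:
            report.row_errors.append((lineno, f"bad frequency {freq_s!r}"))
            continue
        tpl = RetroTemplate(id=tid, name=name, retro_transform=transform,
                            frequency=frequency)
        try:
            _, reactant_patterns = split_transform(transform)
        except TemplateError as exc:
            report.row_errors.append((lineno, str(exc)))
            continue
        if len(reactant_patterns) > MAX_REACTANTS:
            report.rejected_arity += 1
            logger.warning("template %s rejected: %d reactant patterns",
                           tid, len(reactant_patterns))
            continue
        if backend is not None:
            try:
                backend.validate_template(tpl)
            except TemplateError as exc:
                report.row_errors.append((lineno, str(exc)))
                continue
        rows.append(tpl)
    rows.sort(key=lambda t: (-t.frequency, t.id))
    report.templates = [
        RetroTemplate(t.id, t.name, t.retro_transform, rank=i + 1,
                      frequency=t.frequency)
        for i, t in enumerate(rows)
    ]
    return report


def parse_building_blocks(text: str, backend: ChemistryBackend) -> set[str]:
    """Read a building-block list (one structure per line) to a canonical
    structure set."""
    out: set[str] = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(backend.canonicalize(line))
    return out


def apply_retro(
    template: RetroTemplate,
    product: str,
    backend: ChemistryBackend,
    check_relevance: bool = True,
) -> list[RetroProposal]:
    """Apply a retro template to a (canonical) product structure.

    Returns deterministic, symmetric-duplicate-free proposals; when
    *check_relevance* is set, proposals whose forward application does not
    regenerate the product are discarded (and logged).
    """
    product = backend.canonicalize(product)
    proposals: list[RetroProposal] = []
    seen: set[tuple[str, ...]] = set()
    for reactants in backend.apply_retro(template, product):
        key = tuple(sorted(reactants))
        if key in seen:
            continue
        seen.add(key)
        prop = RetroProposal(template.id, tuple(reactants))
        if check_relevance:
            if not relevance_check(template, prop, product, backend):
                logger.info(
                    "template %s proposal %s failed relevance check on %s",
                    template.id, reactants, product,
                )
                continue
            prop = RetroProposal(template.id, tuple(reactants),
                                 relevance_checked=True)
        proposals.append(prop)
    return proposals


def relevance_check(
    template: RetroTemplate,
    proposal: RetroProposal,
    product: str,
    backend: ChemistryBackend,
) -> bool:
    """True iff forward application of the template to the proposal's
    reactants regenerates the product's canonical structure."""
    target = backend.canonicalize(product)
    try:
        products = backend.forward(template, proposal.reactants)
    except TemplateError:
        logger.info("forward application failed for template %s", template.id)
        return False
    return target in products


class RDKitBackend:
    """Reaction-SMARTS chemistry engine built on RDKit.

    Retro application runs the retro reaction on the product and
    canonicalizes each reactant set; forward application swaps the SMARTS
    sides and tries every reactant ordering (at most 3! = 6).  Match-level
    sanitization failures skip that match only.
    """

    name = "rdkit"

    def __init__(self, fingerprint_bits: int = 2048):
        from rdkit import Chem, RDLogger
        from rdkit.Chem import AllChem, Descriptors, rdChemReactions

        RDLogger.DisableLog("rdApp.*")
        self._Chem = Chem
        self._AllChem = AllChem
        self._Descriptors = Descriptors
        self._rdChemReactions = rdChemReactions
        self._fingerprint_bits = fingerprint_bits
        self._retro_cache: dict[str, object] = {}
        self._forward_cache: dict[str, object] = {}

    # -- molecules --------------------------------------------------------

    def _mol(self, structure: str):
        mol = self._Chem.MolFromSmiles(structure)
        if mol is None:
            from .model import MoleculeParseError

            raise MoleculeParseError(f"unparsable SMILES: {structure!r}")
        return mol

    def canonicalize(self, structure: str) -> str:
        return self._Chem.MolToSmiles(self._mol(structure))

    def mol_weight(self, structure: str) -> float:
        return float(self._Descriptors.MolWt(self._mol(structure)))

    def molecule_fingerprint(self, structure: str) -> frozenset[int]:
        fp = self._Chem.RDKFingerprint(self._mol(structure),
                                       fpSize=self._fingerprint_bits)
        return frozenset(fp.GetOnBits())

    # -- templates --------------------------------------------------------

    def _retro_reaction(self, template: RetroTemplate):
        rxn = self._retro_cache.get(template.id)
        if rxn is None:
            rxn = self._AllChem.ReactionFromSmarts(template.retro_transform)
            if rxn is None:
                raise TemplateError(f"bad reaction SMARTS in {template.id}")
            self._retro_cache[template.id] = rxn
        return rxn

    def _forward_reaction(self, template: RetroTemplate):
        rxn = self._forward_cache.get(template.id)
        if rxn is None:
            product, reactants = split_transform(template.retro_transform)
            fwd = ".".join(reactants) + ">>" + product
            rxn = self._AllChem.ReactionFromSmarts(fwd)
            if rxn is None:
                raise TemplateError(f"bad forward SMARTS in {template.id}")
            self._forward_cache[template.id] = rxn
        return rxn

    def validate_template(self, template: RetroTemplate) -> None:
        product, reactants = split_transform(template.retro_transform)
        if len(reactants) > MAX_REACTANTS:
            raise TemplateError(
                f"template {template.id} has {len(reactants)} reactant patterns"
            )
        try:
            rxn = self._retro_reaction(template)
        except Exception as exc:  # RDKit raises bare ValueError on bad SMARTS
            raise TemplateError(f"bad reaction SMARTS in {template.id}: {exc}") from exc
        if rxn.GetNumReactantTemplates() != 1:
            raise TemplateError(
                f"template {template.id} must have exactly one product pattern"
            )

    def n_reactant_patterns(self, template: RetroTemplate) -> int:
        return len(split_transform(template.retro_transform)[1])

    def apply_retro(
        self, template: RetroTemplate, product: str
    ) -> list[tuple[str, ...]]:
        rxn = self._retro_reaction(template)
        mol = self._mol(product)
        out: list[tuple[str, ...]] = []
        for match in rxn.RunReactants((mol,)):
            try:
                reactants = tuple(
                    self.canonicalize(self._Chem.MolToSmiles(m)) for m in match
                )
            except Exception:
                logger.info("skipping unsanitizable match for template %s",
                            template.id)
                continue
            if len(reactants) > MAX_REACTANTS:
                continue
            out.append(reactants)
        return out

    def forward(
        self, template: RetroTemplate, reactants: Sequence[str]
    ) -> list[str]:
        rxn = self._forward_reaction(template)
        if rxn.GetNumReactantTemplates() != len(reactants):
            return []
        mols = [self._mol(s) for s in reactants]
        products: list[str] = []
        for perm in itertools.permutations(mols):
            for match in rxn.RunReactants(tuple(perm)):
                for m in match:
                    try:
                        products.append(self.canonicalize(self._Chem.MolToSmiles(m)))
                    except Exception:
                        continue
        return products

    def reaction_fingerprint(self, template: RetroTemplate) -> dict[int, int]:
        rxn = self._retro_reaction(template)
        fp = self._rdChemReactions.CreateStructuralFingerprintForReaction(rxn)
        return {int(b): 1 for b in fp.GetOnBits()}
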