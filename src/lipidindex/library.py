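"""The packaged library of functional lipid indices.

Each index is a ratio (or weighted sum) over lipid classes, species or
resolved chains, classified into one of three biochemical roles —
Structural, Signaling or Energy — and linked to the human proteins that
catalyse, regulate or respond to the lipids involved.  The library ships as
a human-editable YAML file; :func:`load_index_library` materialises it into
:class:`IndexDefinition` objects consumed by the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .nomenclature import ALKENYL, ALKYL, ESTER

CATEGORIES = ("Structural", "Signaling", "Energy")
MODES = ("class_fraction", "class_ratio", "chain_ratio", "db_weighted", "chain_matched")

_LINKAGE_SUFFIX = {"O": ALKYL, "P": ALKENYL}


def parse_class_token(token: str) -> tuple[str, str]:
    """Split a selector class token into (class, linkage).

    ``"PC"`` means ester-linked PC; ``"PC O"`` / ``"PC P"`` the alkyl and
    alkenyl (plasmalogen) ether forms.
    """
    parts = token.split()
    if len(parts) == 2 and parts[1] in _LINKAGE_SUFFIX:
        return parts[0], _LINKAGE_SUFFIX[parts[1]]
    return token, ESTER


@dataclass(frozen=True)
class ChainFilter:
    """Predicate on an individual resolved chain."""

    db_min: Optional[int] = None
    db_max: Optional[int] = None
    carbons_min: Optional[int] = None
    carbons_max: Optional[int] = None
    parity: Optional[str] = None  # "odd" | "even"
    keys: tuple[str, ...] = ()

    def matches(self, carbons: int, double_bonds: int) -> bool:
        if self.db_min is not None and double_bonds < self.db_min:
            return False
        if self.db_max is not None and double_bonds > self.db_max:
            return False
        if self.carbons_min is not None and carbons < self.carbons_min:
            return False
        if self.carbons_max is not None and carbons > self.carbons_max:
            return False
        if self.parity == "odd" and carbons % 2 == 0:
            return False
        if self.parity == "even" and carbons % 2 == 1:
            return False
        if self.keys and f"{carbons}:{double_bonds}" not in self.keys:
            return False
        return True


@dataclass(frozen=True)
class SelectorExpression:
    """Which lipids (or chains) contribute to one side of an index."""

    class_set: tuple[tuple[str, str], ...] = ()  # (class, linkage) pairs
    oxidized: Optional[bool] = None
    species_db_min: Optional[int] = None
    species_db_max: Optional[int] = None
    species_chain_keys: tuple[str, ...] = ()
    chain: Optional[ChainFilter] = None
    complement_of_total: bool = False

    def matches_species(self, record) -> bool:
        """Species-level membership test (class modes)."""
        if self.class_set and record.class_key not in self.class_set:
            return False
        if self.oxidized is not None and record.oxidized != self.oxidized:
            return False
        if self.species_db_min is not None and record.sum_db < self.species_db_min:
            return False
        if self.species_db_max is not None and record.sum_db > self.species_db_max:
            return False
        if self.species_chain_keys:
            if not record.chains:
                return False
            if not any(c.key in self.species_chain_keys for c in record.chains):
                return False
        return True

    def chain_weight(self, record) -> int:
        """How many resolved chains of the species match (chain modes)."""
        if self.chain is None:
            return 0
        return sum(
            1 for c in record.chains if self.chain.matches(c.carbons, c.double_bonds)
        )


@dataclass(frozen=True)
class IndexDefinition:
    index_id: str
    display_name: str
    category: str
    mode: str
    numerator: SelectorExpression
    denominator: SelectorExpression
    proteins: tuple[str, ...]
    phrase_high: str
    phrase_low: str
    requires_chains: bool
    reference_tag: str
    require_detected: bool = False
    # chain_matched mode only:
    lyso_classes: tuple[str, ...] = ()
    intact_classes: tuple[str, ...] = ()
    linkage: str = ESTER


def _selector_from_spec(spec: dict) -> SelectorExpression:
    spec = dict(spec or {})
    chain = None
    if "chain" in spec:
        c = dict(spec["chain"])
        if "keys" in c:
            c["keys"] = tuple(str(k) for k in c["keys"])
        chain = ChainFilter(**c)
    return SelectorExpression(
        class_set=tuple(parse_class_token(t) for t in spec.get("classes", ())),
        oxidized=spec.get("oxidized"),
        species_db_min=spec.get("species_db_min"),
        species_db_max=spec.get("species_db_max"),
        species_chain_keys=tuple(str(k) for k in spec.get("species_chain_keys", ())),
        chain=chain,
        complement_of_total=bool(spec.get("complement_of_total", False)),
    )


def load_index_library(path=None) -> tuple[IndexDefinition, ...]:
    """Load the packaged (or a user-supplied) index library.

    Returns exactly the definitions found in the YAML file; the packaged
    file holds the 42 curated indices.
    """
    if path is None:
        text = resources.files("lipidindex.data").joinpath("index_library.yml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, list) or not raw:
        raise RuntimeError("index library file is corrupt: expected a list of index records")
    defs = []
    for rec in raw:
        if rec.get("category") not in CATEGORIES:
            raise RuntimeError(f"index {rec.get('id')!r}: bad category {rec.get('category')!r}")
        if rec.get("mode") not in MODES:
            raise RuntimeError(f"index {rec.get('id')!r}: bad mode {rec.get('mode')!r}")
        defs.append(
            IndexDefinition(
                index_id=rec["id"],
                display_name=rec["name"],
                category=rec["category"],
                mode=rec["mode"],
                numerator=_selector_from_spec(rec.get("numerator")),
                denominator=_selector_from_spec(rec.get("denominator")),
                proteins=tuple(rec["proteins"]),
                phrase_high=rec["phrase_high"],
                phrase_low=rec["phrase_low"],
                requires_chains=bool(rec.get("requires_chains", False)),
                reference_tag=rec.get("reference", ""),
                require_detected=bool(rec.get("require_detected", False)),
                lyso_classes=tuple(rec.get("lyso_classes", ())),
                intact_classes=tuple(rec.get("intact_classes", ())),
                linkage={"ester": ESTER, "alkyl": ALKYL, "alkenyl": ALKENYL}.get(
                    rec.get("linkage", "ester"), ESTER
                ),
            )
        )
    ids = [d.index_id for d in defs]
    if len(set(ids)) != len(ids):
        raise RuntimeError("index library file is corrupt: duplicate index ids")
    return tuple(defs)


def library_index(library=None) -> dict[str, IndexDefinition]:
    """id -> definition lookup."""
    if library is None:
        library = load_index_library()
    return {d.index_id: d for d in library}


def protein_vocabulary(library=None) -> frozenset:
    """Union of all protein symbols across the library."""
    if library is None:
        library = load_index_library()
    return frozenset(p for d in library for p in d.proteins)
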