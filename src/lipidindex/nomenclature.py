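"""Parsing of shorthand lipid nomenclature.

Quantitative lipidomics matrices label their rows with compact shorthand
names.  Two annotation levels are in common use:

* **sum composition** — only the total carbon and double-bond counts of all
  chains are known, e.g. ``PC 34:1``;
* **molecular species** — every constituent chain is resolved, separated by
  ``/`` when the sn-position is known or ``_`` when it is not, e.g.
  ``PE 16:0/22:6`` or ``TG 16:0_18:1_18:2``.

Ether lipids carry an ``O-`` (alkyl) or ``P-`` (alkenyl / plasmalogen)
prefix on the chain field; the class-level spellings ``PC O 34:2`` and
``PC-O 34:2`` are accepted as the same thing.  A trailing ``;O``-style
suffix denotes additional oxygens: on the glycerophospholipid classes
(PC, PE, PG, PI, PS) it is read as oxidation (the species feeds the
oxidized-phospholipid index), while on sphingolipids (SM, Cer, gangliosides)
and sterols it is part of the canonical backbone hydroxylation and is *not*
treated as oxidation.

Free cholesterol is modelled as its own class ``Chol`` (aliases
``Cholesterol`` and the systematic ``ST 27:1;O``); cholesteryl esters are a
distinct class ``CE``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

ESTER = "ester"
ALKYL = "alkyl"
ALKENYL = "alkenyl"

SUM_COMPOSITION = "sum_composition"
MOLECULAR_SPECIES = "molecular_species"

#: classes whose species carry exactly one chain, so a single C:DB token is
#: already a fully resolved molecular species (e.g. "LPC 18:0", "CE 18:2").
SINGLE_CHAIN_CLASSES = frozenset(
    {"LPC", "LPE", "LPA", "LPG", "LPI", "LPS", "FA", "CAR", "CE", "MG"}
)

#: the ";O" suffix counts as oxidation only on these classes (ester-linked
#: glycerophospholipids); elsewhere it is backbone hydroxylation.
OXIDIZABLE_CLASSES = frozenset({"PC", "PE", "PG", "PI", "PS"})

_CANONICAL_CLASS = {
    c.upper(): c
    for c in (
        "PC PE PS PI PG PA LPC LPE LPA LPG LPI LPS SM Cer TG DG MG CE CL "
        "CAR BMP FA GM1 GM2 GM3 ST Chol Hex1Cer Hex2Cer".split()
    )
}

_CHOL_ALIASES = {"CHOL", "CHOLESTEROL", "FC"}

_CLASS_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)")
_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:;O(\d*))?$")


class LipidParseError(ValueError):
    """Structured rejection of an unparseable lipid name."""

    def __init__(self, name: str, token: str, reason: str):
        self.name = name
        self.token = token
        self.reason = reason
        super().__init__(f"cannot parse lipid name {name!r}: {reason} (at {token!r})")


@dataclass(frozen=True)
class ChainDescriptor:
    """One resolved fatty chain: carbon count, double bonds, linkage."""

    carbons: int
    double_bonds: int
    linkage: str = ESTER
    hydroxyls: int = 0

    def __post_init__(self):
        if self.carbons < 1 or self.double_bonds < 0:
            raise ValueError("chain must have carbons >= 1 and double_bonds >= 0")

    @property
    def key(self) -> str:
        """The C:DB key used for chain-level aggregation (e.g. '20:4')."""
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidRecord:
    """A parsed lipid name.

    ``oxidized`` is True only when the ';O'-style suffix sits on one of the
    oxidizable glycerophospholipid classes; ``hydroxyls`` always records the
    raw suffix count regardless of class.
    """

    raw_name: str = field(compare=False)
    lipid_class: str = ""
    linkage: str = ESTER
    chains: tuple[ChainDescriptor, ...] = ()
    sum_carbons: int = 0
    sum_db: int = 0
    hydroxyls: int = 0
    oxidized: bool = False
    annotation_level: str = SUM_COMPOSITION

    @property
    def class_key(self) -> tuple[str, str]:
        return (self.lipid_class, self.linkage)


def annotation_level(record: LipidRecord) -> str:
    """Return the annotation level of a parsed record."""
    return record.annotation_level


def _parse_chain_token(name: str, token: str, linkage: str) -> ChainDescriptor:
    m = _CHAIN_RE.match(token)
    if not m:
        raise LipidParseError(name, token, "malformed chain token")
    carbons, db = int(m.group(1)), int(m.group(2))
    if carbons < 1:
        raise LipidParseError(name, token, "chain must have at least one carbon")
    hydroxyls = 0
    if m.group(3) is not None:
        hydroxyls = int(m.group(3)) if m.group(3) else 1
    return ChainDescriptor(carbons, db, linkage, hydroxyls)


def _chol_record(raw: str) -> LipidRecord:
    return LipidRecord(
        raw_name=raw,
        lipid_class="Chol",
        linkage=ESTER,
        chains=(),
        sum_carbons=27,
        sum_db=1,
        hydroxyls=1,
        oxidized=False,
        annotation_level=MOLECULAR_SPECIES,
    )


def parse_lipid_name(name: str) -> LipidRecord:
    """Parse one shorthand lipid name into a :class:`LipidRecord`.

    Raises :class:`LipidParseError` carrying the offending token when the
    name does not fit the grammar; a name is never silently mis-assigned.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidParseError(str(name), str(name), "empty name")
    raw = name
    # "_dupN" markers appended by the matrix reader to disambiguate duplicate
    # rows are not part of the lipid name
    text = re.sub(r"_dup\d+$", "", name.strip())

    if text.upper() in _CHOL_ALIASES:
        return _chol_record(raw)

    m = _CLASS_RE.match(text)
    if not m:
        raise LipidParseError(raw, text, "no class token")
    cls_token = m.group(1)
    cls = _CANONICAL_CLASS.get(cls_token.upper())
    if cls is None:
        raise LipidParseError(raw, cls_token, "unknown lipid class")
    rest = text[m.end():]

    # class-only name: only free cholesterol is legal without a chain field
    if not rest.strip():
        raise LipidParseError(raw, text, "missing chain field")

    # separator between class and chain field: space, '-' or '('
    paren = False
    sep = rest[0]
    if sep in " -(":
        paren = sep == "("
        rest = rest[1:]
    else:
        raise LipidParseError(raw, rest, "expected separator after class")
    rest = rest.strip()
    if paren:
        if not rest.endswith(")"):
            raise LipidParseError(raw, rest, "unbalanced parenthesis")
        rest = rest[:-1].strip()

    # ether linkage marker: "O-", "P-", "O " or "P " before the chains
    linkage = ESTER
    lk = re.match(r"^([OP])\s*[- ]\s*", rest)
    if lk:
        linkage = ALKYL if lk.group(1) == "O" else ALKENYL
        rest = rest[lk.end():]
    if not rest:
        raise LipidParseError(raw, text, "missing chain field")

    tokens = re.split(r"([/_])", rest)
    chain_tokens = tokens[0::2]
    separators = tokens[1::2]
    if any(not t.strip() for t in chain_tokens):
        raise LipidParseError(raw, rest, "empty chain token")
    chain_tokens = [t.strip() for t in chain_tokens]

    single_chain = cls in SINGLE_CHAIN_CLASSES
    if single_chain and len(chain_tokens) > 1:
        raise LipidParseError(raw, rest, f"{cls} carries a single chain")

    if len(chain_tokens) == 1 and not single_chain:
        # sum composition
        chain = _parse_chain_token(raw, chain_tokens[0], linkage)
        sum_carbons, sum_db, hydroxyls = chain.carbons, chain.double_bonds, chain.hydroxyls
        if cls == "ST" and (sum_carbons, sum_db, hydroxyls) == (27, 1, 1):
            return _chol_record(raw)
        return LipidRecord(
            raw_name=raw,
            lipid_class=cls,
            linkage=linkage,
            chains=(),
            sum_carbons=sum_carbons,
            sum_db=sum_db,
            hydroxyls=hydroxyls,
            oxidized=hydroxyls > 0 and cls in OXIDIZABLE_CLASSES and linkage == ESTER,
            annotation_level=SUM_COMPOSITION,
        )

    chains = []
    for i, tok in enumerate(chain_tokens):
        chains.append(_parse_chain_token(raw, tok, linkage if i == 0 else ESTER))
    del separators  # '/' vs '_' both denote molecular species
    chains = tuple(chains)
    sum_carbons = sum(c.carbons for c in chains)
    sum_db = sum(c.double_bonds for c in chains)
    hydroxyls = sum(c.hydroxyls for c in chains)
    return LipidRecord(
        raw_name=raw,
        lipid_class=cls,
        linkage=linkage,
        chains=chains,
        sum_carbons=sum_carbons,
        sum_db=sum_db,
        hydroxyls=hydroxyls,
        oxidized=hydroxyls > 0 and cls in OXIDIZABLE_CLASSES and linkage == ESTER,
        annotation_level=MOLECULAR_SPECIES,
    )


def render(record: LipidRecord) -> str:
    """Render a record back to canonical shorthand.

    Canonical form uses "CLASS O-..."/"CLASS P-..." for ether species and
    '_' between chains (sn-position information is not stored).
    """
    if record.lipid_class == "Chol":
        return "Chol"
    prefix = {ALKYL: "O-", ALKENYL: "P-"}.get(record.linkage, "")

    def chain_str(c: ChainDescriptor) -> str:
        s = f"{c.carbons}:{c.double_bonds}"
        if c.hydroxyls == 1:
            s += ";O"
        elif c.hydroxyls > 1:
            s += f";O{c.hydroxyls}"
        return s

    if record.chains:
        body = "_".join(chain_str(c) for c in record.chains)
    else:
        body = f"{record.sum_carbons}:{record.sum_db}"
        if record.hydroxyls == 1:
            body += ";O"
        elif record.hydroxyls > 1:
            body += f";O{record.hydroxyls}"
    return f"{record.lipid_class} {prefix}{body}"


class ProfileParseReport(NamedTuple):
    records: dict  # name -> LipidRecord
    skipped: list  # list of (name, reason)


def parse_profile(names: Iterable[str], max_failure_fraction: float = 0.5) -> ProfileParseReport:
    """Parse many names, skipping unparseable ones.

    The run aborts (ValueError) only when more than ``max_failure_fraction``
    of the names fail to parse, which usually indicates a wrong input format
    rather than a few stray identifiers.
    """
    records: dict[str, LipidRecord] = {}
    skipped: list[tuple[str, str]] = []
    names = list(names)
    for n in names:
        try:
            records[n] = parse_lipid_name(n)
        except LipidParseError as e:
            skipped.append((n, e.reason))
    if names and len(skipped) > max_failure_fraction * len(names):
        raise ValueError(
            f"{len(skipped)}/{len(names)} lipid names failed to parse; "
            "check the input nomenclature (first offender: "
            f"{skipped[0][0]!r})"
        )
    return ProfileParseReport(records, skipped)


class TranslationResult(NamedTuple):
    name: str
    translated: bool
    warning: Optional[str]


def load_vendor_table() -> dict[str, str]:
    """Load the packaged vendor-spelling translation table."""
    table: dict[str, str] = {}
    with resources.files("lipidindex.data").joinpath("vendor_translations.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[row["vendor_name"].strip()] = row["shorthand_name"].strip()
    return table


def _normalize_brackets(name: str) -> str:
    # "PC(16:0/18:1)" -> "PC 16:0/18:1"
    m = re.match(r"^([A-Za-z][A-Za-z0-9 -]*?)\((.+)\)\s*$", name.strip())
    if m:
        return f"{m.group(1).strip()} {m.group(2).strip()}"
    return name.strip()


def translate_vendor_name(name: str, mapping: Optional[Mapping[str, str]] = None) -> TranslationResult:
    """Translate a vendor spelling to shorthand via a finite lookup table.

    Exact names are looked up first, then the class token of the
    bracket-normalized form.  Unknown names are returned unchanged with a
    warning so callers can decide whether to skip them.
    """
    if mapping is None:
        mapping = load_vendor_table()
    if name in mapping:
        return TranslationResult(mapping[name], True, None)
    norm = _normalize_brackets(name)
    parts = norm.split(None, 1)
    if parts and parts[0] in mapping:
        rest = f" {parts[1]}" if len(parts) > 1 else ""
        return TranslationResult(f"{mapping[parts[0]]}{rest}", True, None)
    if norm != name.strip():
        return TranslationResult(norm, True, None)
    try:
        parse_lipid_name(name)
        return TranslationResult(name.strip(), False, None)
    except LipidParseError:
        return TranslationResult(name, False, f"no translation found for {name!r}")
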