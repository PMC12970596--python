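"""Evaluation of functional indices over abundance profiles.

Two equivalent evaluation paths are provided:

* reference, dictionary-based operations (:func:`select_abundance`,
  :func:`chain_level_totals`, :func:`double_bond_index`,
  :func:`matched_lyso_ratio`, :func:`evaluate_index`) that spell out the
  membership rules one profile at a time, and
* a compiled, vectorised :class:`IndexEngine` used by
  :func:`compute_index_matrix` for whole studies.

Missing-value semantics: an index value is NA (``numpy.nan``) whenever its
denominator is zero in that sample or the lipids it requires are absent
from the dataset altogether; zeros in the numerator are kept as zeros, no
pseudocounts are added, and NA is a value, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library import IndexDefinition, SelectorExpression, load_index_library
from .nomenclature import (
    MOLECULAR_SPECIES,
    LipidRecord,
    parse_profile,
)

NA = float("nan")


# ---------------------------------------------------------------------------
# reference (dictionary-based) operations
# ---------------------------------------------------------------------------

def select_abundance(
    profile_row: Mapping[str, float],
    records: Mapping[str, LipidRecord],
    selector: SelectorExpression,
) -> float:
    """Sum of abundances of lipids matched by ``selector``.

    For selectors carrying a chain predicate the species contributes its
    full abundance once if ANY of its resolved chains matches (chain-ratio
    mode instead weights by chain multiplicity, see
    :func:`chain_level_totals`).
    """
    total = 0.0
    for name, abundance in profile_row.items():
        rec = records[name]
        if selector.chain is not None:
            if any(
                selector.chain.matches(c.carbons, c.double_bonds) for c in rec.chains
            ) and (not selector.class_set or rec.class_key in selector.class_set):
                total += abundance
        elif selector.matches_species(rec):
            total += abundance
    return total


def chain_level_totals(
    profile_row: Mapping[str, float],
    records: Mapping[str, LipidRecord],
) -> dict[str, float]:
    """Aggregate abundances onto resolved chains.

    Each resolved chain of each molecular species contributes that species'
    abundance to its C:DB key (a TG with three chains contributes three
    entries, duplicated chains count twice); sum-composition species
    contribute nothing.
    """
    totals: dict[str, float] = {}
    for name, abundance in profile_row.items():
        rec = records[name]
        for chain in rec.chains:
            totals[chain.key] = totals.get(chain.key, 0.0) + abundance
    return totals


def double_bond_index(
    profile_row: Mapping[str, float],
    records: Mapping[str, LipidRecord],
) -> float:
    """Abundance-weighted mean number of double bonds per molecule."""
    num = 0.0
    den = 0.0
    for name, abundance in profile_row.items():
        rec = records[name]
        num += abundance * rec.sum_db
        den += abundance
    return num / den if den > 0 else NA


def matched_lyso_ratio(
    profile_row: Mapping[str, float],
    records: Mapping[str, LipidRecord],
    lyso_classes: Sequence[str],
    intact_classes: Sequence[str],
    linkage: str,
) -> float:
    """Chain-matched lyso/intact phospholipid ratio.

    Numerator: lyso species (single chain, given linkage) whose chain occurs
    among the resolved chains of at least one intact species of the paired
    classes.  Denominator: intact species containing at least one chain that
    occurs as a lyso species.  NA when no chain-matched pair exists or when
    no molecular-species data are available.
    """
    lyso = []
    intact = []
    for name in profile_row:
        rec = records[name]
        if rec.annotation_level != MOLECULAR_SPECIES or rec.linkage != linkage:
            continue
        if rec.lipid_class in lyso_classes and len(rec.chains) == 1:
            lyso.append(name)
        elif rec.lipid_class in intact_classes and len(rec.chains) >= 2:
            intact.append(name)
    intact_chain_keys = {c.key for n in intact for c in records[n].chains}
    lyso_chain_keys = {records[n].chains[0].key for n in lyso}
    num = sum(
        profile_row[n] for n in lyso if records[n].chains[0].key in intact_chain_keys
    )
    den = sum(
        profile_row[n]
        for n in intact
        if any(c.key in lyso_chain_keys for c in records[n].chains)
    )
    return num / den if den > 0 else NA


def _species_gate_ok(records_list: Iterable[LipidRecord], definition: IndexDefinition) -> bool:
    """Dataset-level evaluability of the numerator side."""
    num = definition.numerator
    if num.species_chain_keys:
        # the index needs molecular species of the named classes; whether any
        # of them carries the target chains is then a (possibly zero) value
        return any(
            r.annotation_level == MOLECULAR_SPECIES
            and (not num.class_set or r.class_key in num.class_set)
            for r in records_list
        )
    return any(num.matches_species(r) for r in records_list)


def evaluate_index(
    profile_row: Mapping[str, float],
    records: Mapping[str, LipidRecord],
    definition: IndexDefinition,
) -> float:
    """Evaluate one index on one profile (reference implementation)."""
    recs = [records[n] for n in profile_row]
    if definition.mode == "db_weighted":
        return double_bond_index(profile_row, records)
    if definition.mode == "chain_matched":
        return matched_lyso_ratio(
            profile_row,
            records,
            definition.lyso_classes,
            definition.intact_classes,
            definition.linkage,
        )
    if definition.mode == "chain_ratio":
        num = den = 0.0
        for name, abundance in profile_row.items():
            rec = records[name]
            num += abundance * definition.numerator.chain_weight(rec)
            den += abundance * definition.denominator.chain_weight(rec)
        has_num = any(definition.numerator.chain_weight(r) for r in recs)
        has_den = any(definition.denominator.chain_weight(r) for r in recs)
        if not (has_num and has_den) or den == 0:
            return NA
        return num / den
    # class_fraction / class_ratio
    if not _species_gate_ok(recs, definition):
        return NA
    num = select_abundance(profile_row, records, definition.numerator)
    if definition.denominator.complement_of_total:
        den = sum(profile_row.values()) - num
    else:
        if not any(definition.denominator.matches_species(r) for r in recs):
            return NA
        den = select_abundance(profile_row, records, definition.denominator)
    if den == 0:
        return NA
    if definition.require_detected and num == 0:
        return NA
    return num / den


# ---------------------------------------------------------------------------
# compiled, vectorised engine
# ---------------------------------------------------------------------------

@dataclass
class _Compiled:
    mode: str
    num_w: np.ndarray  # per-lipid numerator weights
    den_w: Optional[np.ndarray]  # None => complement of total
    evaluable: bool
    require_detected: bool


class IndexEngine:
    """Pre-compiles the selector algebra of a library against a lipid panel.

    Every selector reduces to a per-lipid weight vector, so evaluating an
    index over all samples is a pair of dot products.
    """

    def __init__(
        self,
        lipid_names: Sequence[str],
        records: Mapping[str, LipidRecord],
        library: Optional[Sequence[IndexDefinition]] = None,
    ):
        self.lipid_names = list(lipid_names)
        self.records = [records[n] for n in self.lipid_names]
        self.library = tuple(library) if library is not None else load_index_library()
        self._compiled = [self._compile(d) for d in self.library]

    def _compile(self, d: IndexDefinition) -> _Compiled:
        recs = self.records
        n = len(recs)
        if d.mode == "db_weighted":
            num_w = np.array([r.sum_db for r in recs], dtype=float)
            den_w = np.ones(n)
            return _Compiled(d.mode, num_w, den_w, n > 0, False)
        if d.mode == "chain_matched":
            lyso_idx, intact_idx = [], []
            for i, r in enumerate(recs):
                if r.annotation_level != MOLECULAR_SPECIES or r.linkage != d.linkage:
                    continue
                if r.lipid_class in d.lyso_classes and len(r.chains) == 1:
                    lyso_idx.append(i)
                elif r.lipid_class in d.intact_classes and len(r.chains) >= 2:
                    intact_idx.append(i)
            intact_keys = {c.key for i in intact_idx for c in recs[i].chains}
            lyso_keys = {recs[i].chains[0].key for i in lyso_idx}
            num_w = np.zeros(n)
            den_w = np.zeros(n)
            for i in lyso_idx:
                if recs[i].chains[0].key in intact_keys:
                    num_w[i] = 1.0
            for i in intact_idx:
                if any(c.key in lyso_keys for c in recs[i].chains):
                    den_w[i] = 1.0
            return _Compiled(d.mode, num_w, den_w, den_w.any(), False)
        if d.mode == "chain_ratio":
            num_w = np.array([d.numerator.chain_weight(r) for r in recs], dtype=float)
            den_w = np.array([d.denominator.chain_weight(r) for r in recs], dtype=float)
            return _Compiled(d.mode, num_w, den_w, bool(num_w.any() and den_w.any()), False)
        # class modes
        num_w = np.array([d.numerator.matches_species(r) for r in recs], dtype=float)
        evaluable = _species_gate_ok(recs, d)
        if d.denominator.complement_of_total:
            den_w = None
        else:
            den_w = np.array(
                [d.denominator.matches_species(r) for r in recs], dtype=float
            )
            evaluable = evaluable and bool(den_w.any())
        return _Compiled(d.mode, num_w, den_w, evaluable, d.require_detected)

    def evaluate(self, abundances: np.ndarray) -> np.ndarray:
        """abundances: (n_lipids, n_samples) -> values (n_indices, n_samples)."""
        A = np.asarray(abundances, dtype=float)
        n_samples = A.shape[1]
        out = np.full((len(self._compiled), n_samples), np.nan)
        total = A.sum(axis=0)
        for k, c in enumerate(self._compiled):
            if not c.evaluable:
                continue
            num = c.num_w @ A
            den = total - num if c.den_w is None else c.den_w @ A
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            if c.require_detected:
                vals = np.where(num > 0, vals, np.nan)
            out[k] = vals
        return out


@dataclass
class IndexMatrix:
    """Samples x indices table of computed functional-index values."""

    values: pd.DataFrame  # samples x indices, NaN = NA
    library: tuple

    @property
    def evaluated_mask(self) -> pd.DataFrame:
        return self.values.notna()

    @property
    def evaluated_counts(self) -> pd.Series:
        return self.values.notna().sum(axis=0)

    @property
    def not_evaluated(self) -> list[str]:
        """Indices that are NA in every sample."""
        counts = self.evaluated_counts
        return list(counts.index[counts == 0])

    def categories(self) -> pd.Series:
        return pd.Series(
            {d.index_id: d.category for d in self.library}, name="category"
        ).reindex(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, na_rep="NA", float_format="%.6g", index_label="sample")


def compute_index_matrix(
    matrix: pd.DataFrame,
    library: Optional[Sequence[IndexDefinition]] = None,
    records: Optional[Mapping[str, LipidRecord]] = None,
) -> IndexMatrix:
    """Evaluate the full index library on a lipids x samples matrix.

    Rows whose names fail to parse are skipped (the parse step logs them);
    an empty matrix is a hard failure.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty abundance matrix")
    if library is None:
        library = load_index_library()
    if records is None:
        records = parse_profile(matrix.index).records
    names = [n for n in matrix.index if n in records]
    if not names:
        raise ValueError("no parseable lipid rows in the abundance matrix")
    engine = IndexEngine(names, records, library)
    vals = engine.evaluate(matrix.loc[names].to_numpy(dtype=float))
    values = pd.DataFrame(
        vals.T, index=matrix.columns, columns=[d.index_id for d in library]
    )
    return IndexMatrix(values=values, library=tuple(library))
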