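"""From significant indices to protein-level hypotheses.

Two complementary layers:

* **protein seeds** — every index carries a curated list of human proteins
  that catalyse, regulate or respond to its lipids; the union over
  significant indices (with provenance) seeds a protein-association
  network query;
* **enzyme direction calls** — for a curated reaction A + B -> C + D the
  product/substrate abundance balance is computed per group from
  group-mean sums; a shift of the balance toward products in the
  experimental group is read as net forward drive through the reaction
  (an activity-oriented hypothesis, not a kinetic measurement).

Network queries against the STRING association database are *built*
(serialisable request payloads), never sent, so the analysis stays fully
offline; an explicit opt-in helper can post them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import IndexMatrix
from .library import SelectorExpression, _selector_from_spec, load_index_library
from .nomenclature import LipidRecord

ANNOTATION_SOURCES = (
    "GO-BP",
    "GO-MF",
    "GO-CC",
    "KEGG",
    "Pfam",
    "InterPro",
    "UniProt keywords",
    "Reactome",
)

FORWARD_INCREASED = "forward-increased"
FORWARD_DECREASED = "forward-decreased"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Reaction:
    enzyme: str
    name: str
    substrates: tuple[SelectorExpression, ...]
    products: tuple[SelectorExpression, ...]
    note: str = ""


@dataclass
class EnzymeCall:
    enzyme: str
    direction: str
    balance_exp: float
    balance_ctrl: float
    supporting_indices: list[str] = field(default_factory=list)
    note: str = ""


def load_reactions(path=None) -> tuple[Reaction, ...]:
    """Load the packaged (or user-supplied) curated reaction table."""
    if path is None:
        text = resources.files("lipidindex.data").joinpath("reactions.yml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = []
    for rec in raw:
        out.append(
            Reaction(
                enzyme=rec["enzyme"],
                name=rec.get("name", rec["enzyme"]),
                substrates=tuple(_selector_from_spec(s) for s in rec["substrates"]),
                products=tuple(_selector_from_spec(s) for s in rec["products"]),
                note=rec.get("note", ""),
            )
        )
    return tuple(out)


def significant_index_proteins(
    table: pd.DataFrame, library=None
) -> dict[str, set[str]]:
    """Union of curated protein lists over significant indices.

    Returns protein -> set of contributing index ids (provenance); empty
    when nothing is significant.
    """
    if library is None:
        library = load_index_library()
    defs = {d.index_id: d for d in library}
    out: dict[str, set[str]] = {}
    if table.empty:
        return out
    for index_id in table.loc[table["significant"], "index_id"]:
        for protein in defs[index_id].proteins:
            out.setdefault(protein, set()).add(index_id)
    return out


def _selector_sum(
    selectors: Sequence[SelectorExpression],
    records: Sequence[LipidRecord],
    A: np.ndarray,
) -> np.ndarray:
    """Per-sample summed abundance over a union of selectors."""
    mask = np.zeros(len(records))
    for sel in selectors:
        for i, r in enumerate(records):
            if sel.matches_species(r):
                mask[i] = 1.0
    return mask @ A


def enzyme_direction_call(
    matrix: pd.DataFrame,
    records: Mapping[str, LipidRecord],
    groups: pd.Series,
    group_exp: str,
    group_ctrl: str,
    reactions: Optional[Sequence[Reaction]] = None,
    comparison_table: Optional[pd.DataFrame] = None,
    library=None,
    tolerance: float = 0.10,
) -> list[EnzymeCall]:
    """Call an activity-oriented direction for each curated reaction.

    Per group the balance is (group-mean product sum)/(group-mean substrate
    sum).  The call is forward-increased (decreased) when the balance ratio
    between groups exceeds the relative ``tolerance`` in log space —
    |log(B_exp/B_ctrl)| > log(1+tolerance) — which makes calls exactly
    antisymmetric under swapping the two groups.  Zero substrate or product
    sums give an indeterminate call; reactions with no measurable lipids are
    skipped.
    """
    if reactions is None:
        reactions = load_reactions()
    names = [n for n in matrix.index if n in records]
    recs = [records[n] for n in names]
    A = matrix.loc[names].to_numpy(dtype=float)
    cols = list(matrix.columns)
    exp_cols = [i for i, c in enumerate(cols) if groups.get(c) == group_exp]
    ctrl_cols = [i for i, c in enumerate(cols) if groups.get(c) == group_ctrl]
    if not exp_cols or not ctrl_cols:
        raise ValueError("both groups must contain at least one sample")
    enzyme_to_sig: dict[str, list[str]] = {}
    if comparison_table is not None:
        for protein, idx in significant_index_proteins(comparison_table, library).items():
            enzyme_to_sig[protein] = sorted(idx)
    calls: list[EnzymeCall] = []
    threshold = math.log(1.0 + tolerance)
    for rxn in reactions:
        sub = _selector_sum(rxn.substrates, recs, A)
        prod = _selector_sum(rxn.products, recs, A)
        if sub.sum() == 0 and prod.sum() == 0:
            continue  # nothing measurable for this reaction
        s_exp, s_ctrl = sub[exp_cols].mean(), sub[ctrl_cols].mean()
        p_exp, p_ctrl = prod[exp_cols].mean(), prod[ctrl_cols].mean()
        if min(s_exp, s_ctrl, p_exp, p_ctrl) <= 0:
            calls.append(
                EnzymeCall(rxn.enzyme, INDETERMINATE, float("nan"), float("nan"),
                           enzyme_to_sig.get(rxn.enzyme, []), rxn.note)
            )
            continue
        b_exp = p_exp / s_exp
        b_ctrl = p_ctrl / s_ctrl
        shift = math.log(b_exp / b_ctrl)
        if shift > threshold:
            direction = FORWARD_INCREASED
        elif shift < -threshold:
            direction = FORWARD_DECREASED
        else:
            direction = INDETERMINATE
        calls.append(
            EnzymeCall(rxn.enzyme, direction, b_exp, b_ctrl,
                       enzyme_to_sig.get(rxn.enzyme, []), rxn.note)
        )
    return calls


def enzyme_calls_frame(calls: Sequence[EnzymeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "enzyme": [c.enzyme for c in calls],
            "direction": [c.direction for c in calls],
            "balance_exp": [c.balance_exp for c in calls],
            "balance_ctrl": [c.balance_ctrl for c in calls],
            "supporting_indices": [";".join(c.supporting_indices) for c in calls],
            "reaction": [c.note for c in calls],
        }
    )


def build_string_request(
    proteins: Sequence[str],
    network_type: str = "full",
    score_threshold: int = 400,
    add_nodes: int = 0,
    annotation_source: str = "GO-BP",
    organism: int = 9606,
) -> dict:
    """Build (but do not send) a STRING network request payload.

    ``network_type`` is "full" or "physical"; ``score_threshold`` the STRING
    confidence score in [0, 1000]; ``add_nodes`` the number of neighbouring
    proteins to pull in; ``annotation_source`` one of the eight supported
    node-colouring annotation systems.  The organism field defaults to human
    (NCBI taxon 9606) and is reserved for future orthology support.
    """
    proteins = [p for p in proteins if p]
    if not proteins:
        raise ValueError("cannot build a network request from an empty protein list")
    if network_type not in ("full", "physical"):
        raise ValueError("network_type must be 'full' or 'physical'")
    if not 0 <= score_threshold <= 1000:
        raise ValueError("score_threshold must be in [0, 1000]")
    if add_nodes < 0:
        raise ValueError("add_nodes must be >= 0")
    if annotation_source not in ANNOTATION_SOURCES:
        raise ValueError(
            f"annotation_source must be one of {ANNOTATION_SOURCES}"
        )
    return {
        "endpoint": "https://string-db.org/api/json/network",
        "method": "POST",
        "params": {
            "identifiers": "\r".join(sorted(set(proteins))),
            "species": organism,
            "required_score": int(score_threshold),
            "network_type": network_type,
            "add_white_nodes": int(add_nodes),
            "caller_identity": "lipidindex",
        },
        "annotation_source": annotation_source,
    }


def write_string_request(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def post_string_request(payload: dict, confirm_network_access: bool = False):
    """Optionally send a previously built request (requires explicit opt-in).

    Never used by the analysis pipeline or the test suite; provided for
    interactive sessions with network access.
    """
    if not confirm_network_access:
        raise RuntimeError(
            "network access is opt-in: call with confirm_network_access=True"
        )
    import urllib.parse
    import urllib.request

    data = urllib.parse.urlencode(payload["params"]).encode()
    with urllib.request.urlopen(payload["endpoint"], data=data, timeout=60) as resp:
        return json.loads(resp.read().decode())
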