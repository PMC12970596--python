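"""Synthetic lipidomics studies with planted, closed-form index effects.

The generator emulates a two-group (or multi-group) quantitative lipidomics
study: species abundances are lognormal around class-typical base levels
spanning roughly three orders of magnitude (the dynamic range ratio indices
must survive in practice), with a configurable coefficient of variation.
A planted :class:`EffectSpec` multiplies the numerator lipids of a chosen
index by ``2**log2fc`` in the experimental group.  Because every affected
index is a ratio whose numerator-selector lipids are disjoint from its
denominator (fraction indices subtract the numerator from the total), the
expected log2 fold change of the index equals the planted value exactly in
the noise-free limit and unbiasedly under noise.

The template species pool covers every lipid class used by the index
library, at both annotation levels (molecular species and sum
compositions), including ether/plasmalogen, oxidized, odd-chain and
hydroxylated sphingolipid species, so all five computation modes are
exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import IndexEngine
from .library import load_index_library
from .nomenclature import parse_profile

#: (shorthand name, base abundance) — class-typical levels spanning ~3 orders
#: of magnitude.
TEMPLATE_POOL: tuple[tuple[str, float], ...] = (
    ("PC 16:0/18:1", 100.0),
    ("PC 16:0/20:4", 50.0),
    ("PC 18:0/22:6", 30.0),
    ("PC 16:0/16:0", 40.0),
    ("PC 17:0/18:1", 3.0),
    ("PC 34:1", 60.0),
    ("PC 16:0/20:4;O", 0.7),
    ("PC O-16:0/18:1", 8.0),
    ("PC P-16:0/20:4", 5.0),
    ("LPC 16:0", 10.0),
    ("LPC 18:1", 6.0),
    ("LPC O-16:0", 1.0),
    ("LPC P-16:0", 0.5),
    ("PE 16:0/20:4", 20.0),
    ("PE 18:0/22:6", 15.0),
    ("PE 16:0/18:1", 25.0),
    ("PE 38:4", 10.0),
    ("PE O-16:0/18:1", 5.0),
    ("PE P-18:0/20:4", 6.0),
    ("PE P-16:0/22:6", 4.0),
    ("LPE 18:1", 3.0),
    ("LPE 16:0", 2.0),
    ("LPE O-16:0", 0.5),
    ("LPE P-18:0", 0.8),
    ("PS 18:0/18:1", 12.0),
    ("PI 18:0/20:4", 14.0),
    ("PG 16:0/18:1", 4.0),
    ("PA 16:0/18:1", 2.0),
    ("SM 18:1;O2/16:0", 25.0),
    ("SM 34:1;O2", 30.0),
    ("SM 18:1;O2/24:1", 12.0),
    ("Cer 18:1;O2/16:0", 5.0),
    ("Cer 18:1;O2/24:1", 4.0),
    ("TG 16:0_18:1_18:2", 80.0),
    ("TG 52:2", 60.0),
    ("TG 16:0_16:0_18:1", 40.0),
    ("TG 18:1_18:1_18:3", 20.0),
    ("DG 16:0_18:1", 10.0),
    ("CE 18:2", 35.0),
    ("CE 16:0", 15.0),
    ("CL 72:8", 6.0),
    ("CAR 16:0", 1.5),
    ("CAR 18:1", 1.0),
    ("CAR 8:0", 0.3),
    ("FA 16:0", 5.0),
    ("FA 18:1", 4.0),
    ("FA 12:0", 1.2),
    ("FA 18:2", 3.0),
    ("BMP 18:1_18:1", 0.8),
    ("GM3 34:1;O2", 0.6),
    ("GM2 34:1;O2", 0.4),
    ("Chol", 90.0),
)


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect on one index's numerator lipids."""

    index_id: str
    log2fc: float


class StudyInput(NamedTuple):
    abundance: pd.DataFrame  # lipids x samples
    groups: pd.Series  # sample -> group label


def _effect_targets(effects: Sequence[EffectSpec], names, records, library) -> dict[str, float]:
    """Map lipid name -> fold multiplier; contradictory overlaps are an error."""
    engine = IndexEngine(names, records, library)
    lib = {d.index_id: d for d in engine.library}
    comp = {d.index_id: c for d, c in zip(engine.library, engine._compiled)}
    multipliers: dict[str, float] = {}
    owner: dict[str, str] = {}
    for eff in effects:
        if eff.index_id not in lib:
            raise ValueError(f"unknown index {eff.index_id!r} in effect spec")
        mask = comp[eff.index_id].num_w > 0
        if not mask.any():
            raise ValueError(
                f"effect on {eff.index_id!r}: no template lipid matches its numerator"
            )
        factor = 2.0**eff.log2fc
        for name, hit in zip(names, mask):
            if not hit:
                continue
            if name in multipliers and not math.isclose(multipliers[name], factor):
                raise ValueError(
                    f"contradictory effects on lipid {name!r} "
                    f"({owner[name]} vs {eff.index_id})"
                )
            multipliers[name] = factor
            owner[name] = eff.index_id
    return multipliers


def generate_study(
    effects: Sequence[EffectSpec] = (),
    n_per_group: int = 10,
    cv: float = 0.2,
    seed: Optional[int] = None,
    groups: Sequence[str] = ("EXP", "CTRL"),
    exp_group: str = "EXP",
    pool: Sequence[tuple[str, float]] = TEMPLATE_POOL,
    library=None,
) -> StudyInput:
    """Simulate a multi-group lipidomics study.

    ``cv`` is the per-species biological coefficient of variation of the
    lognormal abundance model (the lognormal sigma is
    sqrt(ln(1+cv^2)) and the noise has mean exactly 1, so planted fold
    changes are recovered unbiasedly).  Deterministic under ``seed``.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if library is None:
        library = load_index_library()
    rng = np.random.default_rng(seed)
    names = [n for n, _ in pool]
    base = np.array([b for _, b in pool], dtype=float)
    records = parse_profile(names).records
    multipliers = _effect_targets(effects, names, records, library) if effects else {}
    mult_vec = np.array([multipliers.get(n, 1.0) for n in names])

    sample_ids, labels, columns = [], [], []
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0
    for g in groups:
        for i in range(n_per_group):
            sid = f"{g}_{i + 1}"
            sample_ids.append(sid)
            labels.append(g)
            mean = base * (mult_vec if g == exp_group else 1.0)
            if sigma > 0:
                noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(base))
            else:
                noise = 1.0
            columns.append(mean * noise)
    abundance = pd.DataFrame(
        np.column_stack(columns), index=names, columns=sample_ids
    )
    return StudyInput(abundance, pd.Series(labels, index=sample_ids, name="group"))


#: small fixed two-group study used for the worked example and golden files:
#: 3 samples per group, deterministic values (no RNG), exercising the
#: fraction, ratio, chain, matched and double-bond-weighted modes plus the
#: sum-composition NA path, an oxidized PC, ether/plasmalogen lyso pairs and
#: short/medium/long/odd chains.  (name, EXP base, CTRL base):
_TOY_SPECIES = (
    ("PC 16:0/18:1", 100.0, 100.0),
    ("PC 16:0/16:0", 30.0, 30.0),
    ("PC 34:1", 50.0, 50.0),
    ("PC 16:0/20:4;O", 2.2, 1.0),
    ("PC O-16:0/18:1", 8.0, 8.0),
    ("PE P-18:0/20:4", 6.6, 3.0),
    ("PE 16:0/22:6", 12.0, 12.0),
    ("PE 16:0/18:1", 20.0, 20.0),
    ("LPC 16:0", 8.8, 4.0),
    ("LPC O-16:0", 1.0, 1.0),
    ("LPE P-18:0", 0.8, 0.8),
    ("LPE 16:0", 1.5, 1.5),
    ("PS 18:0/18:1", 10.0, 10.0),
    ("PI 18:0/20:4", 12.0, 12.0),
    ("PG 16:0/18:1", 3.0, 3.0),
    ("PA 16:0/18:1", 2.0, 2.0),
    ("SM 18:1;O2/16:0", 20.0, 20.0),
    ("Cer 18:1;O2/16:0", 6.6, 3.0),
    ("TG 16:0_18:1_18:2", 132.0, 60.0),
    ("TG 17:0_18:1_18:1", 11.0, 5.0),
    ("DG 16:0_18:1", 8.0, 8.0),
    ("CE 18:2", 25.0, 25.0),
    ("CL 72:8", 5.0, 5.0),
    ("CAR 8:0", 0.4, 0.4),
    ("FA 18:1", 4.0, 4.0),
    ("FA 12:0", 1.0, 1.0),
    ("BMP 18:1_18:1", 0.6, 0.6),
    ("GM3 34:1;O2", 0.66, 0.3),
    ("GM2 34:1;O2", 0.3, 0.3),
    ("Chol", 70.0, 70.0),
)

#: fixed within-group perturbation factors; species i in within-group sample
#: j gets base * (1 + _TOY_DELTA[(3 i + 7 j) % 11]), so no sample is a scalar
#: multiple of another and every ratio index has within-group variance.
_TOY_DELTA = (0.0, 0.07, -0.05, 0.03, -0.02, 0.06, -0.04, 0.02, -0.07, 0.05, -0.03)


def worked_toy_profile() -> StudyInput:
    """A fixed 30-species, 3+3-sample study used in the docs and tests.

    Planted contrasts (EXP vs CTRL base levels): TG raised 2.2-fold (storage and
    energy axes) along with Cer, LPC 16:0, oxidized PC, plasmalogen PE and GM3
    raised 2.2-fold; all other species share the same base with a deterministic
    species-dependent within-group spread of a few percent.
    """
    names = [n for n, _, _ in _TOY_SPECIES]
    samples = ["EXP_1", "EXP_2", "EXP_3", "CTRL_1", "CTRL_2", "CTRL_3"]
    data = np.zeros((len(names), 6))
    for i, (_, exp_base, ctrl_base) in enumerate(_TOY_SPECIES):
        for s, sid in enumerate(samples):
            j = s % 3
            base = exp_base if s < 3 else ctrl_base
            data[i, s] = base * (1.0 + _TOY_DELTA[(3 * i + 7 * j) % 11])
    abundance = pd.DataFrame(data, index=names, columns=samples)
    groups = pd.Series(
        ["EXP"] * 3 + ["CTRL"] * 3, index=samples, name="group"
    )
    return StudyInput(abundance, groups)
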