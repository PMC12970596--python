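"""Independent brute-force oracle for the 42 functional indices.

Every index formula is spelled out literally below from its biochemical
definition (explicit class lists, per-chain loops), without going through
the package's selector algebra or the packaged YAML library, so agreement
with the engine is a genuine dual-route check.  Only the name parser is
shared (its correctness is established separately against the grammar).
"""

from __future__ import annotations

import math

from lipidindex.nomenclature import ALKENYL, ALKYL, ESTER, MOLECULAR_SPECIES

NA = float("nan")

PL_CLASSES = ("PC", "PE", "PG", "PI", "PS")


def _cls(profile, records, classes, linkage=ESTER, oxidized=None):
    total = 0.0
    for name, a in profile.items():
        r = records[name]
        if r.lipid_class in classes and r.linkage == linkage:
            if oxidized is None or r.oxidized == oxidized:
                total += a
    return total


def _has(profile, records, classes, linkage=ESTER, oxidized=None):
    for name in profile:
        r = records[name]
        if r.lipid_class in classes and r.linkage == linkage:
            if oxidized is None or r.oxidized == oxidized:
                return True
    return False


def _chain_sum(profile, records, pred):
    total = 0.0
    found = False
    for name, a in profile.items():
        r = records[name]
        for c in r.chains:
            if pred(c.carbons, c.double_bonds):
                total += a
                found = True
    return total, found


def _ratio(num, den):
    return num / den if den > 0 else NA


def _class_ratio(profile, records, num_classes, den_classes):
    if not _has(profile, records, num_classes) or not _has(profile, records, den_classes):
        return NA
    return _ratio(
        _cls(profile, records, num_classes), _cls(profile, records, den_classes)
    )


def _fraction(profile, records, classes):
    if not _has(profile, records, classes):
        return NA
    num = _cls(profile, records, classes)
    total = sum(profile.values())
    return _ratio(num, total - num)


def _chain_ratio(profile, records, num_pred, den_pred):
    num, num_found = _chain_sum(profile, records, num_pred)
    den, den_found = _chain_sum(profile, records, den_pred)
    if not (num_found and den_found):
        return NA
    return _ratio(num, den)


def _matched(profile, records, linkage):
    lyso, intact = [], []
    for name in profile:
        r = records[name]
        if r.annotation_level != MOLECULAR_SPECIES or r.linkage != linkage:
            continue
        if r.lipid_class in ("LPC", "LPE") and len(r.chains) == 1:
            lyso.append(name)
        elif r.lipid_class in ("PC", "PE") and len(r.chains) >= 2:
            intact.append(name)
    intact_keys = {(c.carbons, c.double_bonds) for n in intact for c in records[n].chains}
    lyso_keys = {
        (records[n].chains[0].carbons, records[n].chains[0].double_bonds) for n in lyso
    }
    num = sum(
        profile[n]
        for n in lyso
        if (records[n].chains[0].carbons, records[n].chains[0].double_bonds) in intact_keys
    )
    den = sum(
        profile[n]
        for n in intact
        if any((c.carbons, c.double_bonds) in lyso_keys for c in records[n].chains)
    )
    return _ratio(num, den)


def oracle_indices(profile, records) -> dict[str, float]:
    """All 42 index values for one profile (NA encoded as nan)."""
    out = {}
    total = sum(profile.values())

    # --- Structural -------------------------------------------------------
    out["cardiolipin_fraction"] = _fraction(profile, records, ("CL",))
    out["ce_total"] = _fraction(profile, records, ("CE",))
    out["chol_plmem"] = _class_ratio(
        profile, records, ("Chol",), ("PC", "PE", "PS", "PI", "SM")
    )
    out["chol_sm"] = _class_ratio(profile, records, ("Chol",), ("SM",))
    out["double_bond_index"] = (
        sum(a * records[n].sum_db for n, a in profile.items()) / total
        if total > 0
        else NA
    )
    out["mono_poly"] = _chain_ratio(
        profile, records, lambda c, d: d == 1, lambda c, d: d >= 2
    )
    out["odd_even_chain"] = _chain_ratio(
        profile, records, lambda c, d: c % 2 == 1, lambda c, d: c % 2 == 0
    )
    # oxidized vs non-oxidized ester glycerophospholipids
    if _has(profile, records, PL_CLASSES, oxidized=True) and _has(
        profile, records, PL_CLASSES, oxidized=False
    ):
        out["oxpl_pl"] = _ratio(
            _cls(profile, records, PL_CLASSES, oxidized=True),
            _cls(profile, records, PL_CLASSES, oxidized=False),
        )
    else:
        out["oxpl_pl"] = NA
    # species-level unsaturated vs saturated PC
    pc_unsat = sum(
        a for n, a in profile.items()
        if records[n].lipid_class == "PC" and records[n].linkage == ESTER
        and records[n].sum_db >= 1
    )
    pc_sat_rows = [
        n for n in profile
        if records[n].lipid_class == "PC" and records[n].linkage == ESTER
        and records[n].sum_db == 0
    ]
    pc_unsat_rows = [
        n for n in profile
        if records[n].lipid_class == "PC" and records[n].linkage == ESTER
        and records[n].sum_db >= 1
    ]
    if pc_unsat_rows and pc_sat_rows:
        out["pc_unsat_sat"] = _ratio(pc_unsat, sum(profile[n] for n in pc_sat_rows))
    else:
        out["pc_unsat_sat"] = NA
    out["pe_pc"] = _class_ratio(profile, records, ("PE",), ("PC",))
    out["membrane_fluidity"] = _class_ratio(profile, records, ("PC",), ("PE", "SM"))
    out["pl_sm"] = _class_ratio(profile, records, PL_CLASSES, ("SM",))
    out["saturation_index"] = _chain_ratio(
        profile, records, lambda c, d: d == 0, lambda c, d: d >= 1
    )
    out["sm_pc"] = _class_ratio(profile, records, ("SM",), ("PC",))
    out["structural_energetic"] = _class_ratio(
        profile, records, ("PC", "PE", "SM"), ("TG", "DG")
    )

    # --- Signaling --------------------------------------------------------
    out["lysopl_pl"] = _class_ratio(profile, records, ("LPC", "LPE"), PL_CLASSES)
    out["aa_dha"] = _chain_ratio(
        profile, records, lambda c, d: (c, d) == (20, 4), lambda c, d: (c, d) == (22, 6)
    )
    out["bmp_fraction"] = _fraction(profile, records, ("BMP",))
    out["cer_sm"] = _class_ratio(profile, records, ("Cer",), ("SM",))
    out["ceramide_fraction"] = _fraction(profile, records, ("Cer",))
    out["dg_pl"] = _class_ratio(profile, records, ("DG",), PL_CLASSES)
    # ether lipids: alkyl or alkenyl PC/PE/LPC/LPE
    ether = sum(
        a for n, a in profile.items()
        if records[n].lipid_class in ("PC", "PE", "LPC", "LPE")
        and records[n].linkage in (ALKYL, ALKENYL)
    )
    has_ether = any(
        records[n].lipid_class in ("PC", "PE", "LPC", "LPE")
        and records[n].linkage in (ALKYL, ALKENYL)
        for n in profile
    )
    out["ether_fraction"] = _ratio(ether, total - ether) if has_ether else NA
    # ferroptosis: PE (ester) and PE P (alkenyl) molecular species with a
    # 20:4, 22:4 or 22:6 chain, over total minus those
    gate = any(
        records[n].lipid_class == "PE"
        and records[n].linkage in (ESTER, ALKENYL)
        and records[n].annotation_level == MOLECULAR_SPECIES
        for n in profile
    )
    if gate:
        ferr = sum(
            a for n, a in profile.items()
            if records[n].lipid_class == "PE"
            and records[n].linkage in (ESTER, ALKENYL)
            and any((c.carbons, c.double_bonds) in ((20, 4), (22, 4), (22, 6))
                    for c in records[n].chains)
        )
        out["ferroptosis_index"] = _ratio(ferr, total - ferr)
    else:
        out["ferroptosis_index"] = NA
    gm3 = _cls(profile, records, ("GM3",))
    gm2 = _cls(profile, records, ("GM2",))
    if _has(profile, records, ("GM3",)) and _has(profile, records, ("GM2",)) and gm3 > 0 and gm2 > 0:
        out["gm3_gm2"] = gm3 / gm2
    else:
        out["gm3_gm2"] = NA
    out["lpc_pc"] = _class_ratio(profile, records, ("LPC",), ("PC",))
    out["lpe_pe"] = _class_ratio(profile, records, ("LPE",), ("PE",))
    out["lyso_o_pl_o"] = _matched(profile, records, ALKYL)
    out["lyso_p_pl_p"] = _matched(profile, records, ALKENYL)
    out["lyso_pl_matched"] = _matched(profile, records, ESTER)
    out["pa_pl"] = _class_ratio(profile, records, ("PA",), PL_CLASSES)
    # PI + PI O over PC+PE+PG+PS
    pi = _cls(profile, records, ("PI",)) + _cls(profile, records, ("PI",), linkage=ALKYL)
    has_pi = _has(profile, records, ("PI",)) or _has(profile, records, ("PI",), linkage=ALKYL)
    den = _cls(profile, records, ("PC", "PE", "PG", "PS"))
    if has_pi and _has(profile, records, ("PC", "PE", "PG", "PS")):
        out["pi_pl"] = _ratio(pi, den)
    else:
        out["pi_pl"] = NA
    out["omega6_omega3"] = _chain_ratio(
        profile, records,
        lambda c, d: (c, d) in ((18, 2), (20, 4)),
        lambda c, d: (c, d) in ((18, 3), (22, 6)),
    )

    # --- Energy -----------------------------------------------------------
    out["acylcarnitine_fraction"] = _fraction(profile, records, ("CAR",))
    out["dg_tg"] = _class_ratio(profile, records, ("DG",), ("TG",))
    out["energy_load"] = _fraction(profile, records, ("TG", "DG", "CE"))
    out["long_medium_chain"] = _chain_ratio(
        profile, records, lambda c, d: 16 <= c <= 25, lambda c, d: 10 <= c <= 15
    )
    out["neutral_polar"] = (
        _ratio(
            _cls(profile, records, ("TG", "CE")),
            _cls(profile, records, ("PC", "PE", "PG", "PI", "PS", "SM", "LPC", "LPE"))
            + _cls(profile, records, ("PE",), linkage=ALKYL),
        )
        if _has(profile, records, ("TG", "CE"))
        and (
            _has(profile, records, ("PC", "PE", "PG", "PI", "PS", "SM", "LPC", "LPE"))
            or _has(profile, records, ("PE",), linkage=ALKYL)
        )
        else NA
    )
    out["short_long_chain"] = _chain_ratio(
        profile, records, lambda c, d: 2 <= c <= 9, lambda c, d: 16 <= c <= 25
    )
    out["storage_index"] = _fraction(profile, records, ("TG",))
    out["tg_ce"] = _class_ratio(profile, records, ("TG",), ("CE",))
    out["tg_fa"] = _class_ratio(profile, records, ("TG",), ("FA",))
    out["tg_pl"] = _class_ratio(profile, records, ("TG",), PL_CLASSES)
    return out
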