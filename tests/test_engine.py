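"""Index evaluation: membership rules, NA semantics, oracle equivalence."""

import math

import numpy as np
import pandas as pd
import pytest

from lipidindex import (
    chain_level_totals,
    compute_index_matrix,
    double_bond_index,
    evaluate_index,
    matched_lyso_ratio,
    parse_profile,
    select_abundance,
)
from lipidindex.engine import IndexEngine
from lipidindex.library import library_index
from lipidindex.simulate import EffectSpec, generate_study

from conftest import random_profile
from oracle import oracle_indices


def _records(profile):
    return parse_profile(profile).records


def _defs():
    return library_index()


def test_select_abundance_class():
    profile = {"TG 52:2": 10.0, "PC 34:1": 5.0}
    sel = _defs()["storage_index"].numerator
    assert select_abundance(profile, _records(profile), sel) == 10.0


def test_select_abundance_ferroptosis_numerator():
    """Only PE species carrying a 20:4/22:4/22:6 chain contribute."""
    profile = {"PE 16:0/20:4": 3.0, "PE 16:0/18:1": 7.0}
    sel = _defs()["ferroptosis_index"].numerator
    assert select_abundance(profile, _records(profile), sel) == 3.0


def test_select_abundance_empty_match():
    profile = {"PC 34:1": 5.0}
    sel = _defs()["storage_index"].numerator
    assert select_abundance(profile, _records(profile), sel) == 0.0


def test_chain_level_totals_basic():
    profile = {"PC 16:0/18:1": 4.0}
    totals = chain_level_totals(profile, _records(profile))
    assert totals == {"16:0": 4.0, "18:1": 4.0}


def test_chain_level_totals_positional_multiplicity():
    profile = {"TG 16:0_16:0_18:1": 2.0}
    totals = chain_level_totals(profile, _records(profile))
    assert totals == {"16:0": 4.0, "18:1": 2.0}


def test_chain_level_totals_sum_composition_contributes_nothing():
    profile = {"PC 34:1": 9.0}
    assert chain_level_totals(profile, _records(profile)) == {}


@pytest.mark.parametrize(
    "profile,expected",
    [
        ({"FA 16:0": 1.0, "FA 18:2": 1.0}, 1.0),
        ({"PC 34:3": 7.0}, 3.0),
        ({"FA 16:0": 3.0, "FA 20:4": 1.0}, 1.0),
    ],
)
def test_double_bond_index(profile, expected):
    assert double_bond_index(profile, _records(profile)) == pytest.approx(expected)


def test_double_bond_index_zero_abundance_is_na():
    profile = {"PC 34:1": 0.0}
    assert math.isnan(double_bond_index(profile, _records(profile)))


def test_matched_lyso_ratio_derived():
    # brute force: LPC 16:0 matches the 16:0 chain of PC 16:0/18:1 -> 2/8
    profile = {"LPC 16:0": 2.0, "PC 16:0/18:1": 8.0}
    r = matched_lyso_ratio(profile, _records(profile), ("LPC", "LPE"), ("PC", "PE"), "ester")
    assert r == pytest.approx(0.25)


def test_matched_lyso_ratio_no_match_is_na():
    profile = {"LPC 20:0": 2.0, "PC 16:0/18:1": 8.0}
    r = matched_lyso_ratio(profile, _records(profile), ("LPC", "LPE"), ("PC", "PE"), "ester")
    assert math.isnan(r)


def test_matched_lyso_ratio_sum_composition_is_na():
    profile = {"LPC 16:0": 2.0, "PC 34:1": 8.0}
    r = matched_lyso_ratio(profile, _records(profile), ("LPC", "LPE"), ("PC", "PE"), "ester")
    assert math.isnan(r)


def test_storage_index_value_and_na():
    defs = _defs()
    profile = {"TG 52:2": 20.0, "PC 34:1": 80.0}
    assert evaluate_index(profile, _records(profile), defs["storage_index"]) == pytest.approx(0.25)
    alone = {"TG 52:2": 20.0}
    assert math.isnan(evaluate_index(alone, _records(alone), defs["storage_index"]))


def test_omega_ratio_from_chain_totals():
    defs = _defs()
    profile = {"FA 18:2": 5.0, "FA 20:4": 3.0, "FA 18:3": 2.0, "FA 22:6": 2.0}
    assert evaluate_index(profile, _records(profile), defs["omega6_omega3"]) == pytest.approx(2.0)


def test_tg_pc_only_dataset_evaluates_exactly_the_reachable_indices():
    matrix = pd.DataFrame(
        {"S1": [20.0, 80.0], "S2": [10.0, 90.0]},
        index=["TG 52:2", "PC 34:1"],
    )
    im = compute_index_matrix(matrix)
    evaluated = set(im.values.columns) - set(im.not_evaluated)
    # pc_unsat_sat stays NA: no fully saturated PC species present
    assert evaluated == {
        "storage_index", "energy_load", "neutral_polar", "tg_pl",
        "structural_energetic", "double_bond_index",
    }
    # spot value: storage = 20/(100-20)
    assert im.values.loc["S1", "storage_index"] == pytest.approx(0.25)


def test_sum_composition_dataset_disables_chain_indices(library):
    """Chain-resolved indices are NA everywhere on sum-composition data;
    species-level double-bond and PC unsaturation stay computable."""
    matrix = pd.DataFrame(
        {"S1": [50.0, 10.0, 20.0, 30.0, 5.0, 4.0]},
        index=["PC 34:1", "PC 32:0", "PE 38:4", "TG 52:2", "SM 34:1;O2", "CL 72:8"],
    )
    im = compute_index_matrix(matrix)
    chain_modes = {d.index_id for d in library if d.mode in ("chain_ratio", "chain_matched")}
    chain_modes.add("ferroptosis_index")  # needs molecular-species PE
    for idx in chain_modes:
        assert math.isnan(im.values.loc["S1", idx]), idx
    assert im.values.loc["S1", "double_bond_index"] == pytest.approx(
        (50 * 1 + 20 * 4 + 30 * 2 + 5 * 1 + 4 * 8) / 119.0
    )
    assert im.values.loc["S1", "pc_unsat_sat"] == pytest.approx(5.0)


def test_na_deleting_denominator_species_never_raises(library, template_records):
    """For every index, removing all denominator contributors yields NA."""
    names, records = template_records
    engine = IndexEngine(names, records, library)
    for d, compiled in zip(library, engine._compiled):
        A = np.ones((len(names), 1))
        if compiled.den_w is None:
            # complement denominator (total minus numerator): zero everything
            # that is not in the numerator
            A[~(compiled.num_w > 0), 0] = 0.0
        else:
            A[compiled.den_w > 0, 0] = 0.0
        im = compute_index_matrix(
            pd.DataFrame(A, index=names, columns=["S1"]), library, records
        )
        assert math.isnan(im.values.loc["S1", d.index_id]), d.index_id


def test_engine_matches_bruteforce_oracle(template_records):
    names, records = template_records
    rng = np.random.default_rng(7)
    for _ in range(60):
        profile = random_profile(rng, names)
        matrix = pd.DataFrame({"S1": pd.Series(profile, dtype=float)})
        im = compute_index_matrix(matrix, records=records)
        expected = oracle_indices(profile, records)
        for idx, exp in expected.items():
            got = im.values.loc["S1", idx]
            if math.isnan(exp):
                assert math.isnan(got), idx
            else:
                assert got == pytest.approx(exp, rel=1e-12), idx


def test_scale_invariance(template_records, library):
    names, records = template_records
    matrix = pd.DataFrame(
        {"S1": np.linspace(1, 5, len(names)), "S2": np.linspace(5, 1, len(names))},
        index=names,
    )
    im1 = compute_index_matrix(matrix, library, records)
    im2 = compute_index_matrix(matrix * 37.5, library, records)
    pd.testing.assert_frame_equal(im1.values, im2.values)


def test_numerator_monotonicity(template_records, library):
    """Raising a numerator-only species strictly raises non-complement ratios."""
    names, records = template_records
    engine = IndexEngine(names, records, library)
    base = pd.DataFrame({"S1": np.ones(len(names))}, index=names)
    im0 = compute_index_matrix(base, library, records)
    for d, c in zip(library, engine._compiled):
        if d.mode not in ("class_ratio", "chain_ratio") or c.den_w is None:
            continue
        only_num = (c.num_w > 0) & (c.den_w == 0)
        if not only_num.any():
            continue
        bumped = base.copy()
        bumped.iloc[np.argmax(only_num), 0] += 10.0
        im1 = compute_index_matrix(bumped, library, records)
        v0, v1 = im0.values.loc["S1", d.index_id], im1.values.loc["S1", d.index_id]
        if not (math.isnan(v0) or math.isnan(v1)):
            assert v1 > v0, d.index_id


def test_double_bond_index_bounds(template_records):
    names, records = template_records
    rng = np.random.default_rng(3)
    for _ in range(20):
        profile = {k: v for k, v in random_profile(rng, names).items() if v > 0}
        if not profile:
            continue
        dbs = [records[n].sum_db for n in profile]
        val = double_bond_index(profile, records)
        assert min(dbs) - 1e-12 <= val <= max(dbs) + 1e-12


def test_planted_storage_effect_recovered():
    study = generate_study(
        [EffectSpec("storage_index", 1.0)], n_per_group=5, cv=0.02, seed=11
    )
    im = compute_index_matrix(study.abundance)
    col = im.values["storage_index"]
    ratio = col[study.groups == "EXP"].mean() / col[study.groups == "CTRL"].mean()
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_empty_matrix_hard_failure():
    with pytest.raises(ValueError, match="empty"):
        compute_index_matrix(pd.DataFrame())


def test_index_matrix_reporting(toy_model):
    im = toy_model.index_matrix
    assert im.not_evaluated == []
    assert (im.evaluated_counts == 6).all()
    assert im.evaluated_mask.values.all()
    assert ((im.values >= 0) | im.values.isna()).values.all()
    assert np.isfinite(im.values.to_numpy()[~np.isnan(im.values.to_numpy())]).all()
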