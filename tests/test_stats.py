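"""Welch comparison, delta-method SE, dominance, biomarker metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special

from lipidindex.stats import (
    anova_all_indices,
    bh_adjust,
    biomarker_rank,
    cohens_d,
    compare_all_indices,
    correlation_matrix,
    functional_dominance,
    log2fc_with_se,
    rank_auc,
    ttest_power,
    welch_anova,
    welch_compare,
)


def _welch_oracle(x, y):
    """Textbook Welch formulas with the p-value from numerical integration
    of the t density (independent of scipy's t.sf)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))

    def pdf(u):
        return (
            special.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * special.gamma(df / 2))
            * (1 + u**2 / df) ** (-(df + 1) / 2)
        )

    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return t, df, 2 * tail


def test_welch_identical_groups():
    t, df, p = welch_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0
    assert p == 1.0


def test_welch_separation_limit():
    t, df, p = welch_compare([1.0, 2.0, 3.0], [11.0001, 12.0, 12.9999])
    assert p < 0.01


def test_welch_matches_density_integration_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.normal(0.3, 1.2, rng.integers(3, 12))
        y = rng.normal(0.0, 0.7, rng.integers(3, 12))
        t, df, p = welch_compare(x, y)
        t0, df0, p0 = _welch_oracle(x, y)
        assert t == pytest.approx(t0, rel=1e-12)
        assert df == pytest.approx(df0, rel=1e-12)
        assert p == pytest.approx(p0, abs=1e-9)


def test_welch_needs_two_values():
    with pytest.raises(ValueError):
        welch_compare([1.0], [1.0, 2.0])


def test_log2fc_exact_cases():
    lfc, se = log2fc_with_se([4.0, 4.0, 4.0], [2.0, 2.0, 2.0])
    assert lfc == pytest.approx(1.0)
    assert se == 0.0
    lfc, _ = log2fc_with_se([3.0, 5.0], [4.0, 4.0])
    assert lfc == pytest.approx(0.0)
    with pytest.raises(ValueError):
        log2fc_with_se([0.0, 0.0], [1.0, 1.0])


def test_delta_se_matches_bootstrap_sd():
    """Delta-method SE tracks the bootstrap SD of log2FC on lognormal groups."""
    rng = np.random.default_rng(42)
    x = rng.lognormal(0.0, 0.4, 40)
    y = rng.lognormal(0.3, 0.5, 40)
    _, se = log2fc_with_se(x, y)
    reps = 10_000
    bx = x[rng.integers(0, len(x), (reps, len(x)))].mean(axis=1)
    by = y[rng.integers(0, len(y), (reps, len(y)))].mean(axis=1)
    boot_sd = np.log2(bx / by).std(ddof=1)
    assert se == pytest.approx(boot_sd, rel=0.15)


def test_label_swap_symmetry():
    rng = np.random.default_rng(1)
    x = rng.lognormal(0.5, 0.3, 8)
    y = rng.lognormal(0.0, 0.4, 6)
    t1, _, p1 = welch_compare(x, y)
    t2, _, p2 = welch_compare(y, x)
    assert p1 == pytest.approx(p2, rel=1e-12)
    assert t1 == pytest.approx(-t2, rel=1e-12)
    l1, s1 = log2fc_with_se(x, y)
    l2, s2 = log2fc_with_se(y, x)
    assert l1 == pytest.approx(-l2, rel=1e-12)
    assert s1 == pytest.approx(s2, rel=1e-12)


def test_rank_auc_polarity():
    assert rank_auc([5, 6, 7], [1, 2, 3]) == 1.0
    assert rank_auc([1, 2, 3], [5, 6, 7]) == 1.0  # anti-separated, corrected
    # raw AUC 0.3 -> reported 0.7: 3 of 10 concordant pairs wins
    x = [1.0, 2.0]
    y = [1.5, 2.5]  # pairs: (1<1.5),(1<2.5),(2>1.5),(2<2.5) -> U=1 -> auc 0.25
    assert rank_auc(x, y) == pytest.approx(0.75)


def test_cohens_d_pooled():
    x = [2.0, 4.0]
    y = [1.0, 3.0]
    # pooled sd = sqrt(2), diff = 1
    assert cohens_d(x, y) == pytest.approx(1 / math.sqrt(2))
    assert cohens_d([1.0, 1.0], [1.0, 1.0]) == 0.0


def test_power_matches_statsmodels():
    from statsmodels.stats.power import TTestIndPower

    oracle = TTestIndPower()
    for d, n1, n2 in [(0.5, 10, 10), (1.2, 6, 9), (0.2, 30, 25)]:
        expected = oracle.power(effect_size=d, nobs1=n1, ratio=n2 / n1, alpha=0.05)
        assert ttest_power(d, n1, n2) == pytest.approx(expected, rel=1e-6)
    assert ttest_power(0.0, 10, 10) == pytest.approx(0.05, abs=0.01)
    assert ttest_power(math.inf, 5, 5) == 1.0


def test_welch_anova_matches_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(2)
    values = np.concatenate(
        [rng.normal(0, 1, 8), rng.normal(0.5, 2, 10), rng.normal(1, 0.5, 7)]
    )
    labels = ["a"] * 8 + ["b"] * 10 + ["c"] * 7
    df = pd.DataFrame({"y": values, "g": labels})
    expected = pg.welch_anova(data=df, dv="y", between="g")
    f, df1, df2, p = welch_anova(
        [values[:8], values[8:18], values[18:]]
    )
    assert f == pytest.approx(expected["F"].iloc[0], rel=1e-9)
    assert df2 == pytest.approx(expected["ddof2"].iloc[0], rel=1e-9)
    assert p == pytest.approx(expected["p_unc"].iloc[0], rel=1e-9)


def test_bh_adjust_known_values():
    p = np.array([0.01, 0.04, 0.03, np.nan])
    adj = bh_adjust(p)
    assert adj[0] == pytest.approx(0.03)
    assert adj[1] == pytest.approx(0.04)
    assert adj[2] == pytest.approx(0.04)
    assert math.isnan(adj[3])


# --- comparison table -------------------------------------------------------

def test_compare_table_shape_and_interpretation(toy_model, toy_results, library):
    t = toy_results.comparison
    assert len(t) <= 42
    assert t["comparable"].all()
    sig = t[t["significant"]]
    assert len(sig) > 0
    defs = {d.index_id: d for d in library}
    for _, row in sig.iterrows():
        expected = (
            defs[row["index_id"]].phrase_high
            if row["log2fc"] > 0
            else defs[row["index_id"]].phrase_low
        )
        assert row["interpretation"] == expected
    assert (t.loc[~t["significant"], "interpretation"] == "").all()


def test_compare_flags_group_with_all_na_not_comparable(toy_model):
    im = toy_model.index_matrix
    values = im.values.copy()
    values.loc[["EXP_1", "EXP_2", "EXP_3"], "storage_index"] = np.nan
    from lipidindex.engine import IndexMatrix

    im2 = IndexMatrix(values=values, library=im.library)
    t = compare_all_indices(im2, toy_model.groups, "EXP", "CTRL")
    row = t[t["index_id"] == "storage_index"].iloc[0]
    assert not row["comparable"]
    assert not row["significant"]
    assert "storage_index" not in set(
        t.loc[t["comparable"], "index_id"]
    )


def test_anova_path(toy_model):
    rng = np.random.default_rng(0)
    im = toy_model.index_matrix
    groups = pd.Series(
        ["A", "A", "B", "B", "C", "C"], index=im.values.index, name="group"
    )
    t = anova_all_indices(im, groups)
    assert {"F", "df1", "df2", "p_value"} <= set(t.columns)
    assert "log2fc" not in t.columns
    assert t["comparable"].any()
    ok = t[t["comparable"]]
    assert ((ok["p_value"] >= 0) & (ok["p_value"] <= 1)).all()


# --- dominance ---------------------------------------------------------------

def _mini_table(rows):
    return pd.DataFrame(rows)


def test_dominance_single_category_example():
    t = _mini_table(
        [
            {"category": "Energy", "comparable": True, "significant": True, "log2fc": 2.0},
            {"category": "Energy", "comparable": True, "significant": False, "log2fc": 0.2},
        ]
    )
    d = functional_dominance(t)
    energy = d[d["category"] == "Energy"].iloc[0]
    assert energy["dominance"] == pytest.approx(1.0)
    assert energy["n_evaluated"] == 2
    structural = d[d["category"] == "Structural"].iloc[0]
    assert math.isnan(structural["dominance"])  # nothing evaluated


def test_dominance_zero_when_nothing_significant(toy_model):
    res = toy_model.fit("EXP", "CTRL", p_threshold=1e-12, fc_threshold=50.0)
    d = res.dominance()
    assert (d["dominance"].fillna(0) == 0).all()


def test_dominance_monotone_in_fc_threshold(toy_model):
    d1 = toy_model.fit("EXP", "CTRL", fc_threshold=1.0).dominance()
    d2 = toy_model.fit("EXP", "CTRL", fc_threshold=2.0).dominance()
    merged = d1.merge(d2, on="category", suffixes=("_1", "_2"))
    assert (merged["dominance_2"].fillna(0) <= merged["dominance_1"].fillna(0) + 1e-12).all()


def test_dominance_invariant_to_order_and_all_na_indices(toy_results):
    t = toy_results.comparison
    shuffled = t.sample(frac=1.0, random_state=4)
    pd.testing.assert_frame_equal(
        functional_dominance(t), functional_dominance(shuffled)
    )


# --- biomarker ranking -------------------------------------------------------

def test_biomarker_table_shape_and_order(toy_model):
    bm = biomarker_rank(toy_model.index_matrix, toy_model.groups, "EXP", "CTRL")
    assert len(bm) <= 20
    assert (bm["p_value"].diff().dropna() >= -1e-15).all()
    assert list(bm["rank"]) == list(range(1, len(bm) + 1))
    assert (bm["auc"] >= 0.5).all()


def test_biomarker_constant_index_ranks_last(toy_model):
    im = toy_model.index_matrix
    values = im.values.copy()
    values["storage_index"] = 1.0  # constant
    from lipidindex.engine import IndexMatrix

    bm = biomarker_rank(
        IndexMatrix(values=values, library=im.library), toy_model.groups, "EXP", "CTRL"
    )
    tail = bm.iloc[-1]
    full = compare_all_indices(
        IndexMatrix(values=values, library=im.library), toy_model.groups, "EXP", "CTRL"
    )
    const_row = full[full["index_id"] == "storage_index"].iloc[0]
    assert const_row["auc"] == 0.5
    assert const_row["cohens_d"] == 0.0
    assert const_row["p_value"] == 1.0


def test_sign_flip_leaves_ranking_invariant(toy_model):
    from lipidindex.engine import IndexMatrix

    im = toy_model.index_matrix
    flipped = im.values.copy()
    flipped["storage_index"] = -flipped["storage_index"] + 2 * flipped["storage_index"].max()
    bm1 = biomarker_rank(im, toy_model.groups, "EXP", "CTRL")
    bm2 = biomarker_rank(
        IndexMatrix(values=flipped, library=im.library), toy_model.groups, "EXP", "CTRL"
    )
    r1 = bm1[bm1["index_id"] == "storage_index"]["auc"].iloc[0]
    r2 = bm2[bm2["index_id"] == "storage_index"]["auc"].iloc[0]
    assert r1 == pytest.approx(r2)


# --- correlations ------------------------------------------------------------

def test_correlation_matrix_properties(toy_model):
    corr = correlation_matrix(toy_model.index_matrix)
    assert ((corr.round(12) >= -1) & (corr.round(12) <= 1) | corr.isna()).all().all()
    np.testing.assert_allclose(np.diag(corr), 1.0)
    np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)


def test_correlation_self_and_negation():
    from lipidindex.engine import IndexMatrix
    from lipidindex import load_index_library

    lib = load_index_library()
    rng = np.random.default_rng(9)
    a = rng.normal(size=30)
    values = pd.DataFrame({"storage_index": a, "cer_sm": -a, "tg_ce": rng.normal(size=30)})
    im = IndexMatrix(values=values, library=lib)
    corr = correlation_matrix(im)
    assert corr.loc["storage_index", "storage_index"] == pytest.approx(1.0)
    assert corr.loc["storage_index", "cer_sm"] == pytest.approx(-1.0)


def test_correlation_independent_indices_near_zero():
    from lipidindex.engine import IndexMatrix
    from lipidindex import load_index_library

    rng = np.random.default_rng(12)
    values = pd.DataFrame(
        rng.normal(size=(1000, 5)),
        columns=["storage_index", "cer_sm", "tg_ce", "pe_pc", "sm_pc"],
    )
    corr = correlation_matrix(IndexMatrix(values=values, library=load_index_library()))
    off = corr.to_numpy()[~np.eye(5, dtype=bool)]
    assert np.abs(off).max() < 0.12


def test_correlation_zero_variance_is_na():
    from lipidindex.engine import IndexMatrix
    from lipidindex import load_index_library

    values = pd.DataFrame(
        {"storage_index": [1.0, 1.0, 1.0, 1.0], "cer_sm": [1.0, 2.0, 3.0, 4.0]}
    )
    corr = correlation_matrix(IndexMatrix(values=values, library=load_index_library()))
    assert math.isnan(corr.loc["storage_index", "cer_sm"])
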