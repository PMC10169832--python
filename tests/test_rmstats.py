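"""Repeated-measures statistics: oracles, properties and an independent
cross-check against pingouin (used only as a test oracle)."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from octacov.rmstats import (
    CATEGORIES,
    gg_epsilon,
    huynh_feldt_epsilon,
    load_subject_category_table,
    mauchly_test,
    pairwise_p_matrix,
    pool_categories,
    posthoc_pairwise,
    rm_anova,
    shapiro_wilk,
)


def random_table(rng, n=12, k=5, scale=1.0):
    subj = rng.normal(0, 2, (n, 1))
    cond = rng.normal(0, 1.5, (1, k))
    x = subj + cond + rng.normal(0, scale, (n, k))
    return pd.DataFrame(x, columns=[f"c{i}" for i in range(k)])


def compound_symmetric_table(rng, n=30, k=5):
    """Subject random effect + iid noise: exactly spherical covariance."""
    x = rng.normal(0, 1.5, (n, 1)) + rng.normal(0, 1.0, (n, k))
    return pd.DataFrame(x, columns=[f"c{i}" for i in range(k)])


def to_long(table):
    long = table.reset_index(names="subject").melt(
        id_vars="subject", var_name="cond", value_name="y"
    )
    return long


# ---------------------------------------------------------------- pooling


def test_pool_categories_oracle():
    seg = pd.DataFrame(
        {
            "category": ["Arteriole"] * 4 + ["Venule"] * 2,
            "mean_cov": [10.0, 20.0, 30.0, 40.0, 5.0, 15.0],
        }
    )
    med = pool_categories({"s1": seg}, measure="median",
                          categories=("Arteriole", "Venule"))
    assert med.loc["s1", "Arteriole"] == 25.0
    assert med.loc["s1", "Venule"] == 10.0
    iqr = pool_categories({"s1": seg}, measure="iqr",
                          categories=("Arteriole", "Venule"))
    assert iqr.loc["s1", "Arteriole"] == pytest.approx(15.0)


def test_pool_categories_missing_category_raises():
    seg = pd.DataFrame({"category": ["Arteriole"], "mean_cov": [1.0]})
    with pytest.raises(ValueError, match="no segments"):
        pool_categories({"s1": seg}, categories=("Arteriole", "Venule"))
    with pytest.raises(ValueError):
        pool_categories({"s1": seg}, measure="mean")


def test_load_subject_category_table(tmp_path):
    df = pd.DataFrame(
        np.arange(14, dtype=float).reshape(2, 7),
        columns=list(CATEGORIES),
        index=pd.Index(["s1", "s2"], name="subject"),
    )
    path = tmp_path / "table.csv"
    df.to_csv(path)
    back = load_subject_category_table(path)
    assert np.allclose(back.to_numpy(), df.to_numpy())
    df.drop(columns=["Quadrant"]).to_csv(path)
    with pytest.raises(ValueError, match="missing"):
        load_subject_category_table(path)


# ---------------------------------------------------------------- shapiro


def test_shapiro_wilk_behaviour():
    rng = np.random.default_rng(0)
    w, p = shapiro_wilk(rng.normal(0, 1, 30))
    assert 0.9 < w <= 1.0 and p > 0.01
    _, p_bimodal = shapiro_wilk(np.r_[np.full(10, -10.0), np.full(10, 10.0)]
                                + rng.normal(0, 0.1, 20))
    assert p_bimodal < 0.05
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_wilk(np.ones(10))


# ---------------------------------------------------------------- mauchly


def test_mauchly_compound_symmetric_accepts():
    table = compound_symmetric_table(np.random.default_rng(42))
    w, p = mauchly_test(table)
    assert 0.0 < w <= 1.0
    assert p > 0.05


def test_mauchly_two_conditions_trivial():
    table = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 2)))
    assert mauchly_test(table) == (1.0, 1.0)


def test_mauchly_needs_enough_subjects():
    table = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 5)))
    with pytest.raises(ValueError):
        mauchly_test(table)


def test_mauchly_matches_pingouin():
    rng = np.random.default_rng(7)
    for _ in range(5):
        table = random_table(rng, n=14, k=5)
        w, p = mauchly_test(table)
        res = pg.sphericity(table)
        assert w == pytest.approx(res.W, rel=1e-9)
        assert p == pytest.approx(res.pval, rel=1e-6, abs=1e-12)


# --------------------------------------------------------------- epsilons


def test_epsilon_bounds_property():
    rng = np.random.default_rng(11)
    for _ in range(200):
        k = int(rng.integers(3, 8))
        n = int(rng.integers(k + 1, 25))
        table = random_table(rng, n=n, k=k, scale=float(rng.uniform(0.2, 3)))
        gg = gg_epsilon(table)
        hf = huynh_feldt_epsilon(table)
        assert 1.0 / (k - 1) - 1e-9 <= gg <= 1.0 + 1e-9
        assert gg <= hf + 1e-9
        assert hf <= 1.0


def test_epsilon_spherical_data_near_one():
    table = compound_symmetric_table(np.random.default_rng(5), n=60, k=4)
    gg = gg_epsilon(table)
    hf = huynh_feldt_epsilon(table)
    assert gg > 0.8
    assert gg <= hf <= 1.0
    assert hf > 0.9


def test_epsilon_matches_pingouin():
    rng = np.random.default_rng(13)
    table = random_table(rng, n=12, k=6)
    assert gg_epsilon(table) == pytest.approx(
        pg.epsilon(table, correction="gg"), rel=1e-9
    )
    assert huynh_feldt_epsilon(table) == pytest.approx(
        min(1.0, pg.epsilon(table, correction="hf")), rel=1e-9
    )


# --------------------------------------------------------------- rm_anova


def test_rm_anova_identical_conditions():
    col = np.random.default_rng(3).normal(10, 2, 8)
    table = pd.DataFrame({"a": col, "b": col, "c": col})
    res = rm_anova(table)
    assert res.f == 0.0
    assert res.p == 1.0
    assert res.ges == 0.0


def test_rm_anova_ss_brute_force():
    rng = np.random.default_rng(17)
    table = random_table(rng, n=9, k=4)
    res = rm_anova(table)
    x = table.to_numpy()
    n, k = x.shape
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_effect = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    assert res.ss["total"] == pytest.approx(ss_total)
    assert res.ss["effect"] == pytest.approx(ss_effect)
    assert res.ss["subjects"] == pytest.approx(ss_subj)
    # SS conservation
    assert res.ss["effect"] + res.ss["subjects"] + res.ss["error"] == (
        pytest.approx(res.ss["total"])
    )
    assert res.ges == pytest.approx(
        ss_effect / (ss_effect + ss_subj + res.ss["error"])
    )


def test_rm_anova_translation_invariance():
    rng = np.random.default_rng(19)
    table = random_table(rng, n=10, k=5)
    a = rm_anova(table)
    b = rm_anova(table + 123.4)
    assert a.f == pytest.approx(b.f)
    assert a.p_uncorrected == pytest.approx(b.p_uncorrected)


def test_rm_anova_matches_pingouin():
    rng = np.random.default_rng(23)
    for _ in range(3):
        table = random_table(rng, n=10, k=7)
        res = rm_anova(table)
        aov = pg.rm_anova(data=to_long(table), dv="y", within="cond",
                          subject="subject", correction=True, detailed=False)
        assert res.f == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p_uncorrected == pytest.approx(
            float(aov["p_unc"].iloc[0]), rel=1e-6, abs=1e-12
        )
        assert res.ges == pytest.approx(float(aov["ng2"].iloc[0]), rel=1e-9)
        sph = pg.sphericity(table)
        assert res.mauchly_p == pytest.approx(sph.pval, rel=1e-6, abs=1e-12)


def test_rm_anova_correction_gate():
    # strongly non-spherical data: corrected p is the headline value
    rng = np.random.default_rng(29)
    base = rng.normal(0, 0.05, (12, 1))
    table = pd.DataFrame(
        np.c_[base + rng.normal(0, 0.05, (12, 1)),
              base + rng.normal(0, 0.05, (12, 1)),
              base + rng.normal(5, 4.0, (12, 1)),
              base + rng.normal(6, 4.0, (12, 1))],
        columns=list("abcd"),
    )
    res = rm_anova(table)
    if res.sphericity_violated:
        assert res.p == res.p_corrected
        assert res.df_effect_corrected < res.df_effect
    else:
        assert res.p == res.p_uncorrected


def test_rm_anova_input_validation():
    with pytest.raises(ValueError):
        rm_anova(pd.DataFrame({"a": [1.0, 2.0]}))
    with pytest.raises(ValueError):
        rm_anova(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))


# ---------------------------------------------------------------- posthoc


def test_posthoc_bonferroni_rule():
    rng = np.random.default_rng(31)
    table = random_table(rng, n=10, k=7)
    out = posthoc_pairwise(table)
    assert len(out) == 21
    for _, row in out.iterrows():
        assert row["p_adj"] == pytest.approx(min(1.0, 21 * row["p_raw"]))
        assert row["ci_low"] <= row["mean_diff"] <= row["ci_high"]


def test_posthoc_identical_pair_degenerate():
    col = np.random.default_rng(2).normal(size=8)
    table = pd.DataFrame({"a": col, "b": col, "c": col + 5})
    out = posthoc_pairwise(table)
    ab = out[(out["a"] == "a") & (out["b"] == "b")].iloc[0]
    assert ab["degenerate"]
    assert ab["p_adj"] == 1.0 and ab["mean_diff"] == 0.0
    ac = out[(out["a"] == "a") & (out["b"] == "c")].iloc[0]
    assert ac["degenerate"] and ac["p_adj"] == 0.0


def test_posthoc_matches_pingouin():
    rng = np.random.default_rng(37)
    table = random_table(rng, n=10, k=5)
    ours = posthoc_pairwise(table)
    theirs = pg.pairwise_tests(
        data=to_long(table), dv="y", within="cond", subject="subject",
        padjust="bonf",
    )
    merged = ours.merge(theirs, left_on=["a", "b"], right_on=["A", "B"])
    assert len(merged) == 10
    assert np.allclose(merged["p_raw"], merged["p_unc"], rtol=1e-6)
    assert np.allclose(merged["p_adj"], merged["p_corr"], rtol=1e-6)


def test_pairwise_p_matrix_layout():
    table = pd.DataFrame(
        np.random.default_rng(41).normal(size=(8, 3)), columns=list("abc")
    )
    mat = pairwise_p_matrix(posthoc_pairwise(table), columns=list("abc"))
    assert list(mat.index) == ["b", "c"]
    assert list(mat.columns) == ["a", "b"]
    assert np.isnan(mat.loc["b", "b"])
    assert np.isfinite(mat.loc["c", "a"])
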