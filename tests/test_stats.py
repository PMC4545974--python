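"""Levene, mixed-design ANOVA, Tukey-Kramer, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from speechkin.errors import InputError
from speechkin.stats import (
    correlate_measures,
    levene_test,
    mixed_anova,
    therapy_ttest,
    tukey_kramer,
)


def _long_df(cell_values, within=None):
    """Build a long-format frame; cell_values: {(group, sex): array}."""
    rows, i = [], 0
    for (g, s), vals in cell_values.items():
        for v in np.atleast_1d(vals):
            if within is None:
                rows.append({"s": f"s{i}", "group": g, "sex": s, "dv": v})
            else:
                for w, dv in zip(within, v):
                    rows.append({"s": f"s{i}", "group": g, "sex": s, "w": w, "dv": dv})
            i += 1
    return pd.DataFrame(rows)


# --- Levene ----------------------------------------------------------------


def test_levene_identical_groups():
    stat, p = levene_test(np.r_[np.ones(5), np.ones(5) * 2], np.r_[["a"] * 5, ["b"] * 5])
    assert stat == 0.0 and p == 1.0


def test_levene_matches_scipy():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 30), rng.normal(0, 3, 25)
    stat, p = levene_test(np.r_[a, b], np.r_[["a"] * 30, ["b"] * 25])
    ref = st.levene(a, b, center="mean")
    assert stat == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
    assert p < 0.01  # variance ratio 9:1 is detected


def test_levene_degenerate_groups_rejected():
    with pytest.raises(InputError):
        levene_test(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))


# --- mixed ANOVA ------------------------------------------------------------


def test_all_identical_observations_give_zero_f():
    df = _long_df(
        {k: np.full(4, 5.0) for k in [("a", "m"), ("a", "f"), ("b", "m"), ("b", "f")]}
    )
    res = mixed_anova(df, "dv", "s", ["group", "sex"])
    assert (res.table["F"] == 0.0).all()
    assert (res.table["p"] == 1.0).all()


def test_two_group_f_equals_squared_t():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 18), rng.normal(0.7, 1, 11)
    df = pd.DataFrame(
        {
            "s": [f"s{i}" for i in range(29)],
            "group": ["a"] * 18 + ["b"] * 11,
            "dv": np.r_[a, b],
        }
    )
    res = mixed_anova(df, "dv", "s", ["group"])
    t, p = st.ttest_ind(a, b)
    assert res.effect("group").F == pytest.approx(t**2, abs=1e-9)
    assert res.effect("group").p == pytest.approx(p, abs=1e-12)


def test_balanced_mixed_design_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    rows = []
    for i in range(30):
        g = "a" if i < 15 else "b"
        base = rng.normal(0.3 if g == "a" else 0.0, 1.0)
        for w in ("w1", "w2"):
            rows.append(
                {
                    "s": f"s{i}",
                    "g": g,
                    "w": w,
                    "dv": base + (0.4 if w == "w1" else 0) + rng.normal(0, 0.5),
                }
            )
    df = pd.DataFrame(rows)
    mine = mixed_anova(df, "dv", "s", ["g"], ["w"])
    ref = pg.mixed_anova(df, dv="dv", within="w", subject="s", between="g")
    ref_f = dict(zip(ref["Source"], ref["F"]))
    assert mine.effect("g").F == pytest.approx(ref_f["g"], abs=1e-9)
    assert mine.effect("w").F == pytest.approx(ref_f["w"], abs=1e-9)
    assert mine.effect("g:w").F == pytest.approx(ref_f["Interaction"], abs=1e-9)


def test_two_within_factors_and_interaction_effects_present():
    rng = np.random.default_rng(2)
    rows = []
    ns = {("a", "m"): 8, ("a", "f"): 5, ("b", "m"): 6, ("b", "f"): 4}
    i = 0
    for (g, s), n in ns.items():
        for _ in range(n):
            base = rng.normal(0, 1)
            for d in ("open", "close"):
                for syl in ("Bob", "pup"):
                    rows.append(
                        {
                            "s": f"s{i}",
                            "group": g,
                            "sex": s,
                            "direction": d,
                            "syllable": syl,
                            "dv": base
                            + (0.5 if d == "open" else 0)
                            + (0.8 if syl == "Bob" else 0)
                            + rng.normal(0, 0.3),
                        }
                    )
            i += 1
    df = pd.DataFrame(rows)
    res = mixed_anova(df, "dv", "s", ["group", "sex"], ["direction", "syllable"])
    effects = set(res.table["effect"])
    # between, within mains, and all crossings are reported
    assert {"group", "sex", "group:sex", "direction", "syllable"} <= effects
    assert {"direction:syllable", "group:direction", "group:sex:syllable"} <= effects
    # the two strong programmed within effects dominate
    assert res.effect("direction").p < 0.001
    assert res.effect("syllable").p < 0.001
    assert res.effect("group").p > 0.05


def test_anova_invariant_to_affine_dv_rescaling():
    rng = np.random.default_rng(3)
    df = _long_df(
        {
            ("a", "m"): rng.normal(0, 1, 10),
            ("a", "f"): rng.normal(0.4, 1, 7),
            ("b", "m"): rng.normal(0.2, 1, 9),
            ("b", "f"): rng.normal(0, 1, 6),
        }
    )
    res1 = mixed_anova(df, "dv", "s", ["group", "sex"])
    df2 = df.assign(dv=5.5 * df["dv"] - 12.0)
    res2 = mixed_anova(df2, "dv", "s", ["group", "sex"])
    assert np.allclose(res1.table["F"], res2.table["F"], atol=1e-9)
    assert np.allclose(res1.table["p"], res2.table["p"], atol=1e-12)


def test_incomplete_within_cells_dropped_listwise():
    rng = np.random.default_rng(4)
    rows = []
    for i in range(12):
        g = "a" if i < 6 else "b"
        for w in ("w1", "w2"):
            if i == 0 and w == "w2":
                continue  # subject 0 misses a cell
            rows.append({"s": f"s{i}", "group": g, "w": w, "dv": rng.normal()})
    res = mixed_anova(pd.DataFrame(rows), "dv", "s", ["group"], ["w"])
    assert res.dropped_subjects == ["s0"]
    assert res.n_subjects == 11


# --- Tukey-Kramer -----------------------------------------------------------


def test_tukey_two_equal_groups_equals_ttest():
    rng = np.random.default_rng(6)
    a, b = rng.normal(0, 1, 20), rng.normal(0.6, 1, 20)
    res = tukey_kramer(np.r_[a, b], np.r_[["a"] * 20, ["b"] * 20])
    _, p_t = st.ttest_ind(a, b)
    assert res.pair("a", "b").p_adj == pytest.approx(p_t, abs=1e-6)


def test_tukey_identical_groups_p_one():
    vals = np.r_[np.ones(5), np.ones(5), np.ones(5), np.ones(5)]
    groups = np.repeat(["a", "b", "c", "d"], 5)
    res = tukey_kramer(vals, groups)
    assert np.allclose(res.table["p_adj"], 1.0, atol=1e-9)


def test_tukey_matches_scipy_unequal_n():
    rng = np.random.default_rng(7)
    a, b, c = rng.normal(0, 1, 20), rng.normal(0.5, 1, 14), rng.normal(1.0, 1, 9)
    res = tukey_kramer(np.r_[a, b, c], np.r_[["a"] * 20, ["b"] * 14, ["c"] * 9])
    ref = st.tukey_hsd(a, b, c)
    assert res.pair("a", "b").p_adj == pytest.approx(ref.pvalue[0, 1], abs=1e-9)
    assert res.pair("a", "c").p_adj == pytest.approx(ref.pvalue[0, 2], abs=1e-9)
    assert res.pair("b", "c").p_adj == pytest.approx(ref.pvalue[1, 2], abs=1e-9)


def test_tukey_excludes_singleton_groups():
    vals = np.r_[np.random.default_rng(8).normal(0, 1, 21), [5.0]]
    groups = np.r_[np.repeat(["a", "b", "c"], 7), ["lonely"]]
    with pytest.warns(UserWarning):
        res = tukey_kramer(vals, groups)
    assert "lonely" not in set(res.table["group1"]) | set(res.table["group2"])


# --- correlations & t-test --------------------------------------------------


def test_correlations_perfect_and_missing():
    df = pd.DataFrame(
        {
            "x": [1.0, 2, 3, 4, 5],
            "y": [2.0, 4, 6, 8, 10],  # perfectly linear
            "z": [5.0, 4, 3, 2, 1],  # anti-linear with x
            "c": [7.0] * 5,  # constant: undefined r
        }
    )
    res = correlate_measures(df)
    get = lambda a, b: res[(res.var1 == a) & (res.var2 == b)].iloc[0]
    assert get("x", "y").r == pytest.approx(1.0)
    assert get("x", "z").r == pytest.approx(-1.0)
    assert np.isnan(get("x", "c").r)


def test_correlations_pairwise_deletion():
    df = pd.DataFrame(
        {"x": [1.0, 2, 3, 4, np.nan, 6], "y": [2.0, 1, 4, 3, 6, np.nan]}
    )
    res = correlate_measures(df)
    assert res.iloc[0]["n"] == 4


def test_therapy_ttest_matches_scipy():
    rng = np.random.default_rng(9)
    vals = rng.normal(0, 1, 30)
    flags = np.r_[np.ones(12, bool), np.zeros(18, bool)]
    t, p = therapy_ttest(vals, flags)
    ref = st.ttest_ind(vals[flags], vals[~flags])
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
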