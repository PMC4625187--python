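"""Statistical-battery tests against hand computations, exact enumeration
and independent library implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from thetamaze import stats as st
from thetamaze.errors import DegenerateDataError, DesignError


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        m = np.tile([1.0, 2.0, 3.0], (3, 1)).T  # each row constant across days
        res = st.friedman_test(np.tile([[5.0, 5.0, 5.0]], (4, 1)))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_strictly_increasing_rows_hand_value(self):
        # every subject ranks the days 1 < 2 < 3: rank sums 3, 6, 9 -> Xr2 = 6
        m = np.array([[1.0, 2.0, 3.0], [0.5, 1.5, 2.5], [2.0, 4.0, 9.0]])
        res = st.friedman_test(m)
        assert res.statistic == pytest.approx(6.0, abs=1e-12)
        assert res.df == (2.0,)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(6, 4))
        base = st.friedman_test(m).statistic
        perm = st.friedman_test(m[:, [2, 0, 3, 1]]).statistic
        assert perm == pytest.approx(base, rel=1e-12)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            m = rng.normal(size=(7, 5))
            mine = st.friedman_test(m)
            ref = sstats.friedmanchisquare(*(m[:, j] for j in range(5)))
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(DesignError):
            st.friedman_test(m)


class TestWilcoxonMannWhitney:
    def test_mann_whitney_exact_enumeration(self):
        # all 6 arrangements of ranks over groups {1,2} vs {3,4}: U=0 occurs
        # once per tail -> two-sided p = 2/6
        res = st.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0 / 3.0, rel=1e-12)
        assert res.method == "exact"

    def test_mann_whitney_u_identity(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(size=5)
        ua = st.mann_whitney(a, b)
        ub = st.mann_whitney(b, a)
        assert ua.statistic + ub.statistic == pytest.approx(len(a) * len(b))
        assert ua.p == pytest.approx(ub.p, rel=1e-12)

    def test_wilcoxon_identical_pairs_degenerate(self):
        with pytest.raises(DegenerateDataError):
            st.wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_wilcoxon_matches_scipy_exact(self):
        a = np.array([10.0, 12.0, 9.0, 15.0, 11.0, 13.5])
        b = np.array([8.0, 13.0, 7.75, 12.0, 10.5, 9.0])
        mine = st.wilcoxon_paired(a, b)
        ref = sstats.wilcoxon(a, b, method="exact")
        assert mine.statistic == ref.statistic
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)


def _brute_force_block_anova(m):
    """Sums-of-squares decomposition written out longhand."""
    b, k = m.shape
    grand = m.mean()
    ss_total = sum((m[i, j] - grand) ** 2 for i in range(b) for j in range(k))
    ss_treat = b * sum((m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_block = k * sum((m[i, :].mean() - grand) ** 2 for i in range(b))
    ss_err = ss_total - ss_treat - ss_block
    f = (ss_treat / (k - 1)) / (ss_err / ((k - 1) * (b - 1)))
    return f


class TestBlockedAnova:
    def test_all_equal_values_give_zero_f(self):
        res = st.blocked_anova_tukey(np.full((4, 3), 2.5))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_brute_force_sums_of_squares(self):
        m = np.array([[3.0, 5.0, 4.0], [6.0, 9.0, 8.0]])
        res = st.blocked_anova_tukey(m)
        assert res.statistic == pytest.approx(_brute_force_block_anova(m), rel=1e-9)
        assert res.df == (2.0, 2.0)

    def test_block_shift_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(5, 4))
        shifted = m + rng.normal(size=(5, 1)) * 10.0
        f0 = st.blocked_anova_tukey(m).statistic
        f1 = st.blocked_anova_tukey(shifted).statistic
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_tukey_table_is_complete_and_bounded(self):
        rng = np.random.default_rng(4)
        res = st.blocked_anova_tukey(rng.normal(size=(6, 4)), labels=[1, 2, 3, 4])
        tk = res.extras["tukey"]
        assert len(tk) == 6  # C(4, 2) pairs
        assert ((tk.p >= 0) & (tk.p <= 1)).all()


class TestPairedT:
    def test_hand_computed_toy_pairs(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 3.0])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        (res,) = st.paired_t_bonferroni([("toy", a, b)])
        assert res.statistic == pytest.approx(t_hand, rel=1e-9)

    def test_constant_shift_is_degenerate(self):
        a = np.arange(5.0)
        (res,) = st.paired_t_bonferroni([("shift", a, a + 1.0)])
        assert res.extras["degenerate"]

    def test_m_equal_one_reduces_to_plain_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6), rng.normal(size=6)
        (res,) = st.paired_t_bonferroni([("x", a, b)], m=1)
        ref = sstats.ttest_rel(a, b)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.extras["p_adjusted"] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(6)
        comps = [(f"c{i}", rng.normal(size=5), rng.normal(size=5)) for i in range(4)]
        out = st.paired_t_bonferroni(comps)
        for r in out:
            assert r.extras["p_adjusted"] == pytest.approx(min(1.0, 4 * r.p), rel=1e-12)


def _long_df(y, subjects=None, groups=None):
    n, a, b = y.shape
    rows = []
    for i in range(n):
        for j in range(a):
            for k in range(b):
                rows.append(
                    {
                        "subject": subjects[i] if subjects else f"s{i}",
                        "group": groups[i] if groups else "g",
                        "day": j,
                        "freq": k,
                        "value": y[i, j, k],
                    }
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_way_within_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        y = rng.normal(size=(8, 4, 3)) + np.arange(4)[None, :, None] * 0.4
        df = _long_df(y)
        mine = st.rm_anova(df, "value", "subject", within=("day", "freq"))
        ref = pg.rm_anova(data=df, dv="value", within=["day", "freq"],
                          subject="subject", detailed=True)
        ref_map = {"day": 0, "freq": 1, "day:freq": 2}
        for key, row in ref_map.items():
            assert mine[key].statistic == pytest.approx(ref.loc[row, "F"], rel=1e-9)
            assert mine[key].p == pytest.approx(ref.loc[row, "p_unc"], rel=1e-9)

    def test_mixed_design_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n1, n2, a = 7, 6, 5
        y = rng.normal(size=(n1 + n2, a, 1))
        y[:n1] += np.arange(a)[None, :, None] * 0.5
        groups = ["g1"] * n1 + ["g2"] * n2
        df = _long_df(y, groups=groups).drop(columns="freq").drop_duplicates()
        mine = st.rm_anova(df, "value", "subject", within=("day",), between="group")
        ref = pg.mixed_anova(data=df, dv="value", within="day", subject="subject",
                             between="group")
        ref = ref.set_index("Source")
        assert mine["group"].statistic == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert mine["day"].statistic == pytest.approx(ref.loc["day", "F"], rel=1e-9)
        assert mine["group:day"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )

    def test_gg_epsilon_matches_pingouin_one_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        y = rng.normal(size=(9, 5, 1)) * np.array([1, 1, 2, 3, 5])[None, :, None]
        df = _long_df(y).drop(columns="freq").drop_duplicates()
        mine = st.rm_anova(df, "value", "subject", within=("day",), gg=True)
        ref = pg.rm_anova(data=df, dv="value", within="day", subject="subject",
                          correction=True)
        assert mine["day"].p == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_single_level_factor_collapses_to_one_way(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(6, 4, 1))
        df2 = _long_df(y)
        two = st.rm_anova(df2, "value", "subject", within=("day", "freq"))
        one = st.rm_anova(df2, "value", "subject", within=("day",))
        assert two["day"].statistic == pytest.approx(one["day"].statistic, rel=1e-9)
        assert set(two) == {"day"}

    def test_missing_cell_raises_design_error(self):
        y = np.random.default_rng(11).normal(size=(4, 3, 2))
        df = _long_df(y)
        df = df[~((df.subject == "s0") & (df.day == 2) & (df.freq == 1))]
        with pytest.raises(DesignError, match="missing"):
            st.rm_anova(df, "value", "subject", within=("day", "freq"))

    def test_subject_relabeling_invariance(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(6, 3, 2))
        df = _long_df(y)
        base = st.rm_anova(df, "value", "subject", within=("day", "freq"))
        relab = df.copy()
        relab["subject"] = relab["subject"].map(
            {f"s{i}": f"rat{chr(90 - i)}" for i in range(6)}
        )
        new = st.rm_anova(relab, "value", "subject", within=("day", "freq"))
        for k in base:
            assert new[k].statistic == pytest.approx(base[k].statistic, rel=1e-12)

    def test_pure_noise_interaction_p_is_roughly_uniform(self):
        # cheap calibration check: p should not pile up near 0
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(40):
            y = rng.normal(size=(6, 3, 4))
            res = st.rm_anova(_long_df(y), "value", "subject", within=("day", "freq"))
            ps.append(res["day:freq"].p)
        assert 0.01 < np.mean(np.asarray(ps) < 0.5) < 0.99
        assert np.mean(np.asarray(ps) < 0.05) < 0.25


class TestMonotonicity:
    def test_group_shift_never_decreases_separation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.5, 2.5, 3.5, 4.5])
        p_prev = np.inf
        for shift in (0.0, 1.0, 2.0, 4.0):
            res = st.mann_whitney(a, b + shift)
            assert res.p <= p_prev + 1e-12
            p_prev = res.p
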