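"""Statistical battery: hand-checked values, exact enumeration oracles,
algebraic identities, calibration, gating, outliers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from eiphys import stats_battery as sb


def enumerated_mw_p(x, y):
    """Independent oracle: full enumeration of rank assignments."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = sst.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([ranks[list(c)].sum() - n1 * (n1 + 1) / 2
                   for c in itertools.combinations(range(n), n1)])
    return min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))


class TestTTest:
    def test_hand_worked_example(self):
        # pooled-variance formula by hand: sp2 = 1, se = sqrt(2/3)
        r = sb.t_test_unpaired([1, 2, 3], [4, 5, 6])
        assert abs(r.statistic_value) == pytest.approx(3.674, abs=1e-3)
        assert r.df == (4,)

    def test_identical_groups(self):
        r = sb.t_test_unpaired([2.0, 2.0], [2.0, 2.0])
        assert r.statistic_value == 0.0 and r.p_value == 1.0

    def test_swap_negates_t_keeps_p(self):
        a = sb.t_test_unpaired([1, 2, 3], [4, 5, 7])
        b = sb.t_test_unpaired([4, 5, 7], [1, 2, 3])
        assert a.statistic_value == pytest.approx(-b.statistic_value)
        assert a.p_value == pytest.approx(b.p_value)


class TestMannWhitney:
    def test_separated_groups_exact(self):
        r = sb.mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic_value == 0.0
        assert r.p_value == pytest.approx(0.1)

    def test_tied_singletons(self):
        r = sb.mann_whitney([1.0], [1.0])
        assert r.statistic_value == 0.5
        assert r.p_value == 1.0

    def test_u1_plus_u2_identity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(size=5)
        pooled = np.concatenate([x, y])
        ranks = sst.rankdata(pooled)
        u1 = ranks[:6].sum() - 6 * 7 / 2
        u2 = ranks[6:].sum() - 5 * 6 / 2
        assert u1 + u2 == pytest.approx(30)
        assert sb.mann_whitney(x, y).statistic_value == min(u1, u2)

    def test_exact_p_matches_enumeration_small_samples(self):
        # property over random tie-free datasets with n1 + n2 <= 8
        rng = np.random.default_rng(42)
        for _ in range(60):
            n1 = int(rng.integers(1, 5))
            n2 = int(rng.integers(1, 9 - n1))
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            assert sb.mann_whitney(x, y).p_value == \
                pytest.approx(enumerated_mw_p(x, y), abs=1e-12)

    def test_group_order_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=7), rng.normal(size=9)
        a, b = sb.mann_whitney(x, y), sb.mann_whitney(y, x)
        assert a.statistic_value == b.statistic_value
        assert a.p_value == pytest.approx(b.p_value)


class TestKruskalWallis:
    def test_identical_groups(self):
        r = sb.kruskal_wallis({"a": [1, 1, 1], "b": [1, 1, 1]})
        assert r.statistic_value == 0.0

    def test_equals_squared_mw_deviate_for_two_groups(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=8)
            y = np.round(rng.normal(0.4, 1, size=9), 1)  # induces ties
            pooled = np.concatenate([x, y])
            u1 = sst.rankdata(pooled)[:8].sum() - 8 * 9 / 2
            z = sb._mw_z(u1, 8, 9, pooled)
            h = sb.kruskal_wallis({"x": x, "y": y}).statistic_value
            assert h == pytest.approx(z ** 2, abs=1e-9)


class TestAnova:
    def test_f_equals_t_squared_when_one_factor_constant(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
        df = pd.DataFrame({
            "y": np.concatenate([x, y]),
            "g": ["A"] * 8 + ["B"] * 8,
            "c": ["k"] * 16})
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        model = smf.ols("y ~ C(g, Sum)", data=df).fit()
        f = anova_lm(model, typ=3).loc["C(g, Sum)", "F"]
        t = sb.t_test_unpaired(x, y).statistic_value
        assert f == pytest.approx(t ** 2, abs=1e-9)

    def test_location_shift_leaves_f_unchanged(self):
        rng = np.random.default_rng(4)
        rows = [{"a": a, "b": b, "y": rng.normal()}
                for a in "AB" for b in "CD" for _ in range(6)]
        df = pd.DataFrame(rows)
        r1 = sb.anova_two_way(df, "y", "a", "b")
        df2 = df.assign(y=df["y"] + 100.0)
        r2 = sb.anova_two_way(df2, "y", "a", "b")
        assert r1.statistic_value == pytest.approx(r2.statistic_value)

    def test_empty_cell_named_in_error(self):
        df = pd.DataFrame({"a": ["A", "A", "B"], "b": ["C", "D", "C"],
                           "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="a=B, b=D"):
            sb.anova_two_way(df, "y", "a", "b")

    def test_repeated_measures_interaction_reported(self):
        rng = np.random.default_rng(5)
        rows = []
        for g in ("WT", "KO"):
            for s in range(6):
                base = rng.normal()
                for t in ("T0", "T1"):
                    eff = 1.0 if (g == "KO" and t == "T1") else 0.0
                    rows.append({"g": g, "subj": f"{g}{s}", "t": t,
                                 "y": base + eff + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        r = sb.anova_two_way(df, "y", "g", "t", repeated="t", subject="subj")
        assert r.test_name == "anova_two_way_rm"
        assert r.p_value < 0.05  # injected interaction detected

    def test_incomplete_subject_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        rows = [{"g": g, "subj": f"{g}{s}", "t": t,
                 "y": float(rng.normal())}
                for g in "AB" for s in range(5) for t in ("T0", "T1")]
        rows = rows[:-1]  # subject B4 loses T1
        df = pd.DataFrame(rows)
        with pytest.warns(UserWarning, match="incomplete subjects"):
            sb.anova_two_way(df, "y", "g", "t", repeated="t", subject="subj")


class TestHolmSidak:
    def test_hand_worked_step_down(self):
        adj = sb.holm_sidak([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.029701, 0.059119, 0.059119],
                                   atol=1e-4)

    def test_single_p_nearly_unchanged(self):
        assert sb.holm_sidak([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(sb.holm_sidak([1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=10)
        assert (sb.holm_sidak(p) >= p - 1e-12).all()


class TestDunn:
    def test_identical_groups_adjusted_p_one(self):
        d = sb.dunn_posthoc({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert d["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(8)
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10),
                  "c": rng.normal(10, 1, 10)}
        d = sb.dunn_posthoc(groups)
        hit = d[d["contrast"].str.contains("c")]
        assert (hit["p_adj"] < 0.05).all()

    def test_adjustment_monotone_in_raw_p(self):
        rng = np.random.default_rng(9)
        groups = {k: rng.normal(i * 0.5, 1, 8)
                  for i, k in enumerate("abcd")}
        d = sb.dunn_posthoc(groups).sort_values("p_raw")
        assert (np.diff(d["p_adj"]) >= -1e-12).all()


class TestNormalityGating:
    def test_normal_samples_pass(self):
        rng = np.random.default_rng(10)
        ok, p = sb.ks_normality(rng.normal(size=50))
        assert ok

    def test_exponential_samples_rejected_with_power(self):
        rng = np.random.default_rng(11)
        rejections = sum(not sb.ks_normality(rng.exponential(size=50))[0]
                         for _ in range(100))
        assert rejections > 90

    def test_constant_data_fail_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            ok, p = sb.ks_normality([3.0] * 10)
        assert not ok

    def test_select_test_branches(self):
        rng = np.random.default_rng(12)
        normal = {"a": rng.normal(size=30), "b": rng.normal(size=30)}
        branch, log = sb.select_test(normal)
        assert branch == "parametric"
        assert any("selected branch: parametric" in line for line in log)
        skewed = {"a": rng.normal(size=30), "b": rng.exponential(size=30)}
        branch, log = sb.select_test(skewed)
        assert branch == "nonparametric"


class TestRout:
    def test_gross_outlier_flagged(self):
        kept, flagged = sb.rout_outliers([1.0, 2.0, 3.0, 100.0])
        assert list(flagged) == [100.0]
        assert sorted(kept) == [1.0, 2.0, 3.0]

    def test_null_false_flag_rate_low(self):
        rng = np.random.default_rng(13)
        flags = sum(sb.rout_outliers(rng.normal(size=50))[1].size
                    for _ in range(200))
        assert flags / (200 * 50) <= 0.01

    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 50.0])
        _, f1 = sb.rout_outliers(x)
        _, f2 = sb.rout_outliers(7.0 * x - 3.0)
        np.testing.assert_allclose(f2, 7.0 * f1 - 3.0)

    def test_small_sample_kept_with_warning(self):
        with pytest.warns(UserWarning, match="n < 4"):
            kept, flagged = sb.rout_outliers([1.0, 2.0, 100.0])
        assert flagged.size == 0 and kept.size == 3


class TestPropertyBased:
    """Derandomized hypothesis property checks of the battery's invariants."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_holm_sidak_dominates_raw_and_stays_in_unit_interval(self, p):
        adj = sb.holm_sidak(p)
        assert ((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0)).all()

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10,
                    unique=True),
           st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10,
                    unique=True))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_mw_u_in_range_and_order_invariant(self, x, y):
        a = sb.mann_whitney(x, y)
        b = sb.mann_whitney(y, x)
        assert 0.0 <= a.statistic_value <= len(x) * len(y) / 2.0
        assert a.statistic_value == b.statistic_value
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
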