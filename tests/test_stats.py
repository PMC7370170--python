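"""Gated comparison machinery: gate calibration, identities, invariances."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from flyspace.stats import (
    ComparisonResult,
    DegenerateDataWarning,
    Design,
    compare,
    factorial_anova,
    kruskal_dunn,
    normality_gate,
    welch_t,
)
from flyspace.synthetic import simulate_design


class TestNormalityGate:
    def test_gaussian_group_passes_at_calibrated_rate(self):
        rng = np.random.default_rng(0)
        hits = sum(
            normality_gate([rng.normal(size=30)]) == "anova" for _ in range(1000)
        )
        assert abs(hits / 1000 - 0.95) < 0.025

    def test_skewed_group_routed_to_rank(self):
        rng = np.random.default_rng(1)
        hits = sum(
            normality_gate([rng.exponential(size=30)]) == "rank" for _ in range(500)
        )
        assert hits / 500 > 0.9

    def test_constant_group_rank_with_warning(self):
        with pytest.warns(DegenerateDataWarning, match="constant"):
            assert normality_gate([np.full(10, 3.0)]) == "rank"

    def test_tiny_group_rank_with_warning(self):
        with pytest.warns(DegenerateDataWarning, match="< 3"):
            assert normality_gate([np.array([1.0, 2.0])]) == "rank"

    def test_any_rejection_flips_choice(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=40), np.exp(rng.normal(size=40) * 2)]
        assert normality_gate(groups) == "rank"


class TestFactorialAnova:
    def test_one_factor_f_equals_squared_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        table = pd.DataFrame(
            {"y": np.r_[a, b], "grp": ["a"] * 12 + ["b"] * 15}
        )
        res = factorial_anova(table, Design(response="y", factors=("grp",)))
        t, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert res.terms.loc[0, "statistic"] == pytest.approx(t**2)
        assert res.terms.loc[0, "p"] == pytest.approx(p_t)

    def test_unbalanced_two_way_runs(self):
        df = simulate_design({"g": ["a", "b"], "t": ["x", "y"]}, reps=6, seed=3)
        df = df.drop(index=[0, 1, 7]).reset_index(drop=True)  # unbalance
        res = factorial_anova(df, Design(response="response", factors=("g", "t")))
        assert list(res.terms["term"]) == ["g", "t", "g:t"]
        assert (res.terms["df_resid"] > 0).all()

    def test_three_way_terms(self):
        df = simulate_design(
            {"g": ["a", "b"], "t": ["x", "y"], "s": ["m", "f"]}, reps=3, seed=4
        )
        res = factorial_anova(df, Design(response="response", factors=("g", "t", "s")))
        assert "g:t:s" in set(res.terms["term"])
        assert len(res.terms) == 7  # 3 mains + 3 two-way + 1 three-way

    def test_row_order_invariance(self):
        df = simulate_design({"g": ["a", "b"], "t": ["x", "y"]}, reps=5, seed=5)
        design = Design(response="response", factors=("g", "t"))
        base = factorial_anova(df, design).terms
        shuffled = factorial_anova(
            df.sample(frac=1.0, random_state=9).reset_index(drop=True), design
        ).terms
        np.testing.assert_allclose(base["statistic"], shuffled["statistic"])

    def test_empty_cell_inestimable(self):
        df = simulate_design({"g": ["a", "b"], "t": ["x", "y"]}, reps=4, seed=6)
        df = df[~((df.g == "b") & (df.t == "y"))]
        with pytest.raises(ValueError, match="g:t"):
            factorial_anova(df, Design(response="response", factors=("g", "t")))


class TestKruskalDunn:
    def test_identical_values_h_zero_p_one(self):
        res = kruskal_dunn({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert res.terms.loc[0, "statistic"] == 0.0
        assert res.terms.loc[0, "p"] == 1.0

    def test_two_groups_match_mann_whitney(self, rng):
        a = rng.normal(size=12).round(1)  # rounding induces ties
        b = rng.normal(0.8, 1, size=14).round(1)
        res = kruskal_dunn({"a": a, "b": b})
        _, p_mwu = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert res.terms.loc[0, "p"] == pytest.approx(p_mwu, rel=1e-10)

    def test_dunn_adjusted_p_monotone_and_geq_raw(self, rng):
        groups = {k: rng.normal(loc, 1, size=10) for k, loc in
                  [("a", 0.0), ("b", 0.5), ("c", 2.0), ("d", 0.1)]}
        ph = kruskal_dunn(groups).posthoc
        assert (ph["p_adj"] >= ph["p"] - 1e-15).all()
        ordered = ph.sort_values("p")
        assert ordered["p_adj"].is_monotonic_increasing

    def test_validation(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1.0], "b": [1.0, 2.0]})


class TestWelchT:
    def test_equal_variance_equal_n_matches_pooled(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        res = welch_t(a, b)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.terms.loc[0, "statistic"] == pytest.approx(t)
        assert res.terms.loc[0, "p"] == pytest.approx(p, abs=0.002)

    def test_satterthwaite_df(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 25)
        df = welch_t(a, b).terms.loc[0, "df"]
        assert 9 <= df <= 33
        _, p_scipy = sps.ttest_ind(a, b, equal_var=False)
        assert welch_t(a, b).terms.loc[0, "p"] == pytest.approx(p_scipy)


class TestGatedCompare:
    def _table(self, rng, skew=False):
        vals = rng.exponential(size=30) if skew else rng.normal(size=30)
        return pd.DataFrame({"y": vals, "g": ["a", "b", "c"] * 10})

    def test_auto_routes_gaussian_to_anova(self, rng):
        res = compare(self._table(rng), Design(response="y", factors=("g",)))
        assert res.test in ("anova", "kruskal")
        assert res.normality is not None

    def test_auto_routes_skewed_to_rank(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {"y": np.exp(rng.normal(size=90) * 3), "g": ["a", "b", "c"] * 30}
        )
        res = compare(table, Design(response="y", factors=("g",)))
        assert res.test == "kruskal"
        assert res.posthoc is not None

    def test_forced_gate(self, rng):
        table = self._table(rng)
        assert compare(table, Design(response="y", factors=("g",)), gate="rank").test == "kruskal"
        assert compare(table, Design(response="y", factors=("g",)), gate="anova").test == "anova"

    def test_invalid_gate(self, rng):
        with pytest.raises(ValueError):
            compare(self._table(rng), Design(response="y", factors=("g",)), gate="bogus")

    def test_design_validation(self):
        with pytest.raises(ValueError):
            Design(response="y", factors=())
        with pytest.raises(ValueError):
            Design(response="y", factors=("a", "b", "c", "d"))
        with pytest.raises(ValueError):
            Design(response="y", factors=("a",), alpha=1.5)
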