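"""Robust group comparisons, variance tests, correlations."""

import numpy as np
import pytest

from vocalscales.stats import (
    correlate,
    describe,
    games_howell,
    robust_pairwise,
    trimmed_welch_pairwise,
    variance_tests,
)


class TestDescribe:
    def test_basic_moments(self):
        out = describe({"a": [1.0, 2.0, 3.0]})
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)  # n-1 denominator

    def test_constant_group_has_zero_sd_and_skew(self):
        row = describe({"a": [5.0] * 10}).iloc[0]
        assert row["sd"] == 0.0 and row["skew"] == 0.0

    def test_large_sample_recovers_parameters(self, rng):
        v = rng.normal(155.0, 62.2, 10_000)
        row = describe({"g": v}).iloc[0]
        assert row["mean"] == pytest.approx(155.0, abs=2.0)
        assert row["sd"] == pytest.approx(62.2, abs=2.0)


class TestGamesHowell:
    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        vals = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(1, 2, 40), rng.normal(0.5, 0.5, 25)]
        )
        grp = ["a"] * 30 + ["b"] * 40 + ["c"] * 25
        ours = games_howell({k: vals[np.array(grp) == k] for k in "abc"})
        ref = pingouin.pairwise_gameshowell(
            data=pd.DataFrame({"v": vals, "g": grp}), dv="v", between="g"
        )
        for (_, mine), (_, theirs) in zip(ours.iterrows(), ref.iterrows()):
            assert mine["t"] == pytest.approx(abs(theirs["T"]), rel=1e-6)
            assert mine["df"] == pytest.approx(theirs["df"], rel=1e-6)
            assert mine["p_adj"] == pytest.approx(theirs["pval"], abs=1e-6)

    def test_identical_groups_not_significant(self):
        v = np.arange(20, dtype=float)
        out = games_howell({"a": v, "b": v})
        assert out["p_adj"].iloc[0] > 0.99
        assert not out["significant"].any()

    def test_separated_groups_detected(self, rng):
        hits = 0
        for _ in range(20):
            out = games_howell(
                {"a": rng.normal(0, 1, 50), "b": rng.normal(3, 1, 50)}, alpha=0.001
            )
            hits += bool((out["p_adj"] < 0.001).all())
        assert hits == 20

    def test_label_permutation_and_shift_invariance(self, rng):
        g = {"a": rng.normal(0, 1, 30), "b": rng.normal(1, 2, 30), "c": rng.normal(2, 1, 30)}
        base = games_howell(g)
        shifted = games_howell({k: v + 100.0 for k, v in g.items()})
        assert np.allclose(base["p_adj"], shifted["p_adj"])
        renamed = games_howell({"z" + k: v for k, v in g.items()})
        assert np.allclose(base["p_adj"], renamed["p_adj"])

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="n < 3"):
            games_howell({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestRobustPairwise:
    def test_reports_diagnostics_and_method(self, rng):
        g = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 3, 40)}
        res = robust_pairwise(g, variable="imprecision")
        assert res.method == "games-howell"
        assert 0 <= res.shapiro_p <= 1
        assert res.levene_df == (1, 78)
        assert len(res.pairwise) == 1
        assert "Shapiro" in res.summary()

    def test_trimmed_alternative_runs(self, rng):
        g = {"a": rng.normal(0, 1, 40), "b": rng.normal(2, 3, 40)}
        res = robust_pairwise(g, method="trimmed")
        assert res.pairwise["p_adj"].iloc[0] < 0.05

    def test_trimmed_null_calibration(self, rng):
        v = np.arange(30, dtype=float)
        out = trimmed_welch_pairwise({"a": v, "b": v})
        assert out["p_adj"].iloc[0] > 0.99


class TestVarianceTests:
    def test_identical_groups_give_zero_f(self):
        v = np.arange(30, dtype=float)
        out = variance_tests({"a": v, "b": v})
        assert out["overall"]["f"] == pytest.approx(0.0)

    def test_unequal_spread_detected(self, rng):
        hits = 0
        for _ in range(20):
            out = variance_tests({"a": rng.normal(0, 3, 60), "b": rng.normal(0, 1, 60)})
            hits += out["overall"]["p"] < 0.01
        assert hits >= 19

    def test_bonferroni_applied_over_pairs(self, rng):
        g = {k: rng.normal(0, 1, 30) for k in "abcd"}
        out = variance_tests(g)
        pw = out["pairwise"]
        assert len(pw) == 6
        assert np.allclose(pw["p_bonferroni"], np.minimum(1.0, pw["p_raw"] * 6))


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        res = correlate(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_null_pairs_have_small_r(self, rng):
        res = correlate(rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000))
        assert abs(res.r) < 0.03

    def test_analytic_r_for_linear_model(self, rng):
        # y = 0.5 x + e, x,e ~ N(0,1) -> r = 0.5 / sqrt(1.25) = 0.447
        x = rng.normal(0, 1, 5000)
        y = 0.5 * x + rng.normal(0, 1, 5000)
        res = correlate(x, y)
        assert res.r == pytest.approx(0.4472, abs=0.03)

    def test_t_statistic_consistent_with_p(self, rng):
        from scipy import stats as sps

        x = rng.normal(0, 1, 50)
        y = 0.3 * x + rng.normal(0, 1, 50)
        res = correlate(x, y)
        assert res.t == pytest.approx(
            res.r * np.sqrt(res.df / (1 - res.r**2)), abs=1e-9
        )
        assert res.p == pytest.approx(2 * sps.t.sf(abs(res.t), res.df), abs=1e-9)

    def test_adjusted_r2_formula(self, rng):
        x = rng.normal(0, 1, 100)
        y = x + rng.normal(0, 1, 100)
        res = correlate(x, y)
        n = res.n
        assert res.adj_r2 == pytest.approx(1 - (1 - res.r2) * (n - 1) / (n - 2), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
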