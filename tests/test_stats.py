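"""Experiment statistics against closed-form and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import thermvar as tv
from thermvar.errors import DataError, DesignError, DomainError
from thermvar.stats import GroupSample


def _census(rows):
    return pd.DataFrame(rows, columns=["treatment", "container", "week", "n_alive", "n_carcasses"])


class TestCannibalismCounts:
    def test_simple_container(self):
        census = _census([
            ("a", 0, 0, 10, 0),
            ("a", 0, 8, 3, 0),
        ])
        books = tv.cannibalism_counts(census)
        assert books.loc[0, "cannibalized"] == 7
        assert books.loc[0, "intrinsic"] == 0

    def test_carcasses_count_as_intrinsic(self):
        census = _census([
            ("a", 0, 0, 10, 0),
            ("a", 0, 4, 6, 2),
            ("a", 0, 8, 5, 1),
        ])
        books = tv.cannibalism_counts(census)
        assert books.loc[0, "intrinsic"] == 3
        assert books.loc[0, "cannibalized"] == 10 - 5 - 3

    def test_impossible_books_rejected(self):
        census = _census([
            ("a", 0, 0, 10, 0),
            ("a", 0, 8, 8, 3),
        ])
        with pytest.raises(DataError, match="a/0"):
            tv.cannibalism_counts(census)


class TestAnovaOneway:
    def test_published_mortality_reconstruction(self):
        """Binary mortality, 4/20 vs 5/20 deaths, gives the printed F(1,38)."""
        constant = GroupSample("constant", tuple([1] * 4 + [0] * 16))
        variation = GroupSample("high", tuple([1] * 5 + [0] * 15))
        res = tv.anova_oneway([constant, variation])
        assert res.df == (1, 38)
        assert round(res.statistic, 2) == 0.14
        assert round(res.p_value, 3) == 0.714

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        groups = [GroupSample(str(i), tuple(rng.normal(i * 0.3, 1.0, 12))) for i in range(4)]
        res = tv.anova_oneway(groups)
        f_ref, p_ref = sps.f_oneway(*[np.array(g.values) for g in groups])
        assert res.statistic == pytest.approx(f_ref, rel=1e-10)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_hand_sums_of_squares(self):
        groups = [
            GroupSample("g1", (1.0, 2.0, 3.0)),
            GroupSample("g2", (2.0, 3.0, 4.0)),
            GroupSample("g3", (3.0, 4.0, 5.0)),
        ]
        # grand mean 3; between SS = 3*(1+0+1) = 6 on 2 df; within SS = 6 on 6 df
        res = tv.anova_oneway(groups)
        assert res.statistic == pytest.approx((6 / 2) / (6 / 6), rel=1e-12)
        assert res.df == (2, 6)

    def test_identical_groups_degenerate_convention(self):
        groups = [GroupSample("a", (2.0, 2.0, 2.0)), GroupSample("b", (2.0, 2.0))]
        res = tv.anova_oneway(groups)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(DesignError):
            tv.anova_oneway([GroupSample("a", (1.0, 2.0))])


def _irls_logistic(y, X, tol=1e-12, maxiter=200):
    """Independent IRLS oracle for a logit GLM (textbook Newton scoring)."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        W = np.clip(W, 1e-12, None)
        z = eta + (y - mu) / W
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _binomial_deviance(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(2.0 * np.sum(y * np.log(y / p + (y == 0)) + (1 - y) * np.log((1 - y) / (1 - p) + (y == 1))))


class TestBinomialGlmLrt:
    def test_fitted_probs_equal_group_proportions(self):
        y = [1, 1, 0, 1, 0, 0, 0, 1, 1, 1]
        lab = ["a"] * 5 + ["b"] * 5
        res, fitted = tv.binomial_glm_lrt(y, lab)
        np.testing.assert_allclose(fitted[:5], 3 / 5, rtol=1e-8)
        np.testing.assert_allclose(fitted[5:], 3 / 5, rtol=1e-8)

    def test_equal_proportions_null_result(self):
        y = [1, 0, 1, 0, 1, 0, 1, 0]
        lab = ["a"] * 4 + ["b"] * 4
        res, _ = tv.binomial_glm_lrt(y, lab)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_two_by_two_closed_form_oracle(self):
        # group a: 7/10 survive; group b: 2/10
        y = np.array([1] * 7 + [0] * 3 + [1] * 2 + [0] * 8, dtype=float)
        lab = np.array(["a"] * 10 + ["b"] * 10)
        res, fitted = tv.binomial_glm_lrt(y, lab)

        def ll(k, n, p):
            return k * math.log(p) + (n - k) * math.log(1 - p)

        ll_sat = ll(7, 10, 0.7) + ll(2, 10, 0.2)
        ll_null = ll(9, 20, 0.45)
        assert res.statistic == pytest.approx(2.0 * (ll_sat - ll_null), rel=1e-8)
        assert res.df == (1,)

    def test_matches_independent_irls_on_synthetic_census(self, seeded_interaction):
        census, _, _ = seeded_interaction
        books = tv.cannibalism_counts(census)
        y, lab = [], []
        for _, row in books.iterrows():
            y += [1] * row["final_alive"] + [0] * row["cannibalized"]
            lab += [row["treatment"]] * (row["final_alive"] + row["cannibalized"])
        y = np.array(y, dtype=float)
        lab = np.array(lab)
        res, fitted = tv.binomial_glm_lrt(y, lab)

        levels = sorted(set(lab))
        X = np.column_stack(
            [np.ones(len(y))] + [(lab == lv).astype(float) for lv in levels[1:]]
        )
        beta = _irls_logistic(y, X)
        p_full = 1.0 / (1.0 + np.exp(-(X @ beta)))
        p_null = np.full_like(y, y.mean())
        stat_oracle = _binomial_deviance(y, p_null) - _binomial_deviance(y, p_full)
        assert res.statistic == pytest.approx(stat_oracle, abs=1e-6)
        np.testing.assert_allclose(fitted, p_full, atol=1e-6)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60).astype(float)
        lab = np.repeat(["a", "b", "c"], 20)
        res1, _ = tv.binomial_glm_lrt(y, lab)
        swap = {"a": "c", "b": "a", "c": "b"}
        res2, _ = tv.binomial_glm_lrt(y, [swap[l] for l in lab])
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-8)

    def test_separation_warns_but_reports(self):
        y = [1, 1, 1, 0, 0, 1]
        lab = ["a", "a", "a", "b", "b", "b"]
        with pytest.warns(UserWarning, match="separation"):
            res, fitted = tv.binomial_glm_lrt(y, lab)
        assert math.isfinite(res.statistic)
        assert 0 <= res.p_value <= 1


class TestTjurR2:
    def test_perfect_prediction(self):
        assert tv.tjur_r2([1.0, 1.0, 0.0], [1, 1, 0]) == pytest.approx(1.0)

    def test_constant_prediction(self):
        assert tv.tjur_r2([0.4, 0.4, 0.4, 0.4], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert tv.tjur_r2([0.8, 0.6, 0.3, 0.1], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1  # ensure both classes
        base = tv.tjur_r2(p, y)
        idx = rng.permutation(40)
        assert tv.tjur_r2(p[idx], y[idx]) == pytest.approx(base, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            tv.tjur_r2([0.5, 0.5], [1, 1])


class TestSizeVarianceRegression:
    def test_normal_equation_oracle(self):
        counts = np.array([0.0, 2.0, 3.0, 7.0, 9.0])
        variances = np.array([0.01, 0.04, 0.02, 0.09, 0.16])
        res = tv.size_variance_regression(counts, variances)
        yv = np.log(counts + 1.0)
        xv = np.sqrt(variances)
        X = np.column_stack([np.ones_like(xv), xv])
        beta = np.linalg.solve(X.T @ X, X.T @ yv)
        assert res.effect["intercept"] == pytest.approx(beta[0], rel=1e-9)
        assert res.effect["slope"] == pytest.approx(beta[1], rel=1e-9)
        resid = yv - X @ beta
        r2 = 1.0 - resid @ resid / ((yv - yv.mean()) @ (yv - yv.mean()))
        assert res.effect["r2"] == pytest.approx(r2, rel=1e-9)
        assert res.df == (1, 3)

    def test_collinear_data_r2_one(self):
        variances = np.array([0.01, 0.04, 0.09, 0.16])
        counts = np.exp(2.0 * np.sqrt(variances) + 0.5) - 1.0
        res = tv.size_variance_regression(counts, variances)
        assert res.effect["r2"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_counts_r2_zero(self):
        res = tv.size_variance_regression([3.0] * 5, [0.01, 0.02, 0.05, 0.08, 0.1])
        assert res.effect["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_predictor_variance_rejected(self):
        with pytest.raises(DesignError):
            tv.size_variance_regression([1.0, 2.0, 3.0], [0.04, 0.04, 0.04])


class TestGroupGrowth:
    def test_identical_means_zero(self):
        assert tv.group_growth([1.0, 2.0], [2.0, 1.0], 10.0) == 0.0

    def test_mean_based_value(self):
        # means 1.2 -> 1.5 over 56 days
        assert tv.group_growth([1.0, 1.4], [1.4, 1.6], 56.0) == pytest.approx(
            math.log(1.25) / 56.0, rel=1e-12
        )

    def test_single_larva_consistency(self):
        assert tv.group_growth([1.1], [1.3], 20.0) == pytest.approx(
            tv.growth_rate(1.1, 1.3, 20.0), rel=1e-12
        )


class TestPipelineReports:
    def test_interaction_report_smoke(self, seeded_interaction):
        census, measurements, _ = seeded_interaction
        report = tv.analyze_interaction(census, measurements, duration_days=56.0)
        totals = report["totals"]
        assert (
            totals["final_alive"] + totals["cannibalized"] + totals["intrinsic"]
            == totals["initial"] == 400
        )
        for key in (
            "cannibalism_glm", "growth_anova", "initial_size_anova",
            "final_size_anova", "intrinsic_mortality_anova",
            "size_variance_regression",
        ):
            assert 0.0 <= report[key]["p_value"] <= 1.0
        assert -1.0 <= report["tjur_r2"] <= 1.0

    def test_single_experiment_report(self, reference_tpc):
        # two single-larva arms: everyone survives, so the mortality ANOVA
        # is the degenerate all-identical case
        rows = []
        for trt, temps_seed in (("constant", 0), ("high", 1)):
            obs = tv.simulate_single_growth(
                20, [23.0], reference_tpc, noise_sd=0.005, duration_days=42.0,
                seed=temps_seed,
            )
            for i, o in enumerate(obs):
                lid = f"{trt}-{i}"
                rows.append((trt, i, lid, "start", o.initial_hw))
                rows.append((trt, i, lid, "end", o.final_hw))
        meas = pd.DataFrame(
            rows, columns=["treatment", "container", "larva_id", "phase", "head_width_mm"]
        )
        report = tv.analyze_single(meas, duration_days=42.0)
        assert report["growth_anova"]["df"] == [1, 38]
        assert report["mortality_anova"]["statistic"] == 0.0
        assert report["mortality_anova"]["p_value"] == 1.0
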