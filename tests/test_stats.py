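"""Rank statistics, splines, influence diagnostics and group comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from calcimorph.errors import (
    CollinearityError,
    DegenerateDataError,
    GroupSizeError,
)
from calcimorph.stats import (
    bh_fdr,
    bootstrap_percentile_ci,
    compare_fragmentation,
    correlation_matrix,
    fit_rcs_model,
    influence_filter,
    kruskal_wallis,
    mann_whitney_u,
    partial_spearman,
    rcs_basis,
    spearman,
    summarize_median_iqr,
)

from _oracles import (
    bh_stepup_by_hand,
    loo_refit_diagnostics,
    mwu_enumeration,
    partial_from_precision,
)


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.arange(1.0, 20.0)
        rho, p = spearman(x, np.exp(x))
        assert rho == 1.0 and p == 0.0

    def test_reversal(self):
        x = np.arange(10.0)
        assert spearman(x, -x)[0] == -1.0

    def test_ties_equal_pearson_on_average_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([10.0, 20.0, 20.0, 40.0])
        # average ranks by hand: x -> 1, 2.5, 2.5, 4 ; y -> 1, 2.5, 2.5, 4
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        expected = np.corrcoef(rx, rx)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariance_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman(x, y)[0]
        assert spearman(np.exp(x), y**3)[0] == pytest.approx(base, abs=1e-12)


class TestBH:
    def test_worked_four_value_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_hand_stepup_and_is_monotone(self, ps):
        q = bh_fdr(ps)
        assert np.allclose(q, bh_stepup_by_hand(ps), atol=1e-12)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestBootstrap:
    def test_constant_statistic(self):
        lo, hi = bootstrap_percentile_ci(lambda rows: 3.14, np.zeros((10, 2)),
                                         n_boot=50, seed=0)
        assert lo == hi == 3.14

    def test_same_seed_same_bounds(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(40, 2))
        stat = lambda t: sps.spearmanr(t[:, 0], t[:, 1])[0]  # noqa: E731
        a = bootstrap_percentile_ci(stat, data, n_boot=200, seed=11)
        b = bootstrap_percentile_ci(stat, data, n_boot=200, seed=11)
        assert a == b

    def test_spearman_ci_coverage_under_known_copula(self):
        """Nominal 95% percentile CI covers the true Spearman at a rate
        in [0.90, 0.985] (population ρs = 0.5 via Gaussian copula)."""
        r = 2 * np.sin(np.pi * 0.5 / 6)
        cov = np.array([[1.0, r], [r, 1.0]])
        chol = np.linalg.cholesky(cov)
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 200
        for _ in range(reps):
            z = rng.standard_normal((200, 2)) @ chol.T
            lo, hi = bootstrap_percentile_ci(
                lambda t: sps.spearmanr(t[:, 0], t[:, 1])[0], z,
                n_boot=1000, seed=rng,
            )
            hits += lo <= 0.5 <= hi
        assert 0.90 <= hits / reps <= 0.985


class TestPartialSpearman:
    def test_empty_covariates_equals_plain_spearman(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 50))
        res = partial_spearman(x, y, None, n_boot=0)
        assert res.rho == pytest.approx(sps.spearmanr(x, y)[0], abs=1e-12)
        assert not res.partial

    def test_agrees_with_precision_matrix_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            z = rng.standard_normal((80, 2))
            x = z @ [0.5, -0.3] + rng.standard_normal(80)
            y = z @ [0.2, 0.6] + rng.standard_normal(80)
            table = np.column_stack([x, y, z])
            res = partial_spearman(x, y, z, n_boot=0)
            assert res.rho == pytest.approx(
                partial_from_precision(table, 0, 1), abs=1e-10
            )

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        z = rng.standard_normal(120)
        x = z + rng.standard_normal(120)
        y = z + rng.standard_normal(120)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        res = partial_spearman(x, y, df[["z"]], n_boot=0)
        ref = pg.partial_corr(df, x="x", y="y", covar=["z"], method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 30))
        z = rng.normal(size=30)
        covs = pd.DataFrame({"z1": z, "z2": 2 * z})
        with pytest.raises(CollinearityError, match="z"):
            partial_spearman(x, y, covs, n_boot=0)


class TestRCSBasis:
    KNOTS = (1.0, 3.0, 7.0)

    def test_zero_below_first_knot(self):
        x = np.linspace(-5, 1.0, 40)
        assert np.allclose(rcs_basis(x, self.KNOTS)[:, 1], 0.0)

    def test_linear_beyond_last_knot(self):
        x = np.linspace(7.5, 30, 400)
        nl = rcs_basis(x, self.KNOTS)[:, 1]
        assert np.abs(np.diff(nl, n=2)).max() < 1e-8

    def test_value_and_derivative_continuous_at_knots(self):
        # continuity: the jump across a shrinking bracket vanishes at O(eps)
        for t in self.KNOTS:
            for eps in (1e-5, 1e-7):
                left, right = rcs_basis(np.array([t - eps, t + eps]), self.KNOTS)[:, 1]
                assert abs(right - left) < 10 * eps
        # first derivative via central differences across each knot
        for t in self.KNOTS:
            h = 1e-5
            grid = np.array([t - 2 * h, t - h, t + h, t + 2 * h])
            nl = rcs_basis(grid, self.KNOTS)[:, 1]
            d_left = (nl[1] - nl[0]) / h
            d_right = (nl[3] - nl[2]) / h
            assert d_left == pytest.approx(d_right, abs=1e-3)

    def test_unordered_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.arange(5.0), (3.0, 3.0, 7.0))


class TestFitRCS:
    def test_exact_linear_truth(self):
        x = np.linspace(0, 10, 150)
        fit = fit_rcs_model(2 * x, x)
        assert abs(fit.coefficients["rcs_nonlinear"]) < 1e-8
        assert fit.p_nonlinear == pytest.approx(1.0)

    def test_quadratic_alternative_detected(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 3, 150)
        y = x**2 + rng.normal(0, 0.5, 150)
        fit = fit_rcs_model(y, x)
        assert fit.p_nonlinear < 0.01
        assert fit.wald_chi2 > 0

    def test_row_accounting(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        y = x + rng.normal(size=120)
        fit = fit_rcs_model(y, x)
        assert fit.n_used + len(fit.excluded_indices) == 120
        assert all(t1 < t2 for t1, t2 in zip(fit.knots, fit.knots[1:]))

    def test_too_few_distinct_x_rejected(self):
        x = np.repeat(np.arange(5.0), 10)
        with pytest.raises(ValueError, match="distinct"):
            fit_rcs_model(x + 1, x)

    def test_prediction_runs_on_grid(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, 100)
        y = np.sin(x) + rng.normal(0, 0.1, 100)
        fit = fit_rcs_model(y, x)
        fitted, lo, hi = fit.predict(np.linspace(0, 5, 20))
        assert fitted.shape == (20,)
        assert (lo <= fitted).all() and (fitted <= hi).all()


class TestInfluence:
    def test_exact_linear_no_cooks_flags(self):
        x = np.linspace(-1, 1, 40)
        X = np.column_stack([np.ones(40), x])
        rep = influence_filter(X, 3 * x + 1)
        assert np.allclose(rep.cooks_d, 0.0)
        assert np.allclose(rep.max_abs_dfbetas, 0.0)

    def test_closed_forms_match_literal_leave_one_out(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
        y = X @ [1.0, 2.0, -1.0] + rng.normal(size=50)
        rep = influence_filter(X, y)
        cooks, hat, dfbetas = loo_refit_diagnostics(X, y)
        assert np.allclose(rep.cooks_d, cooks, atol=1e-8)
        assert np.allclose(rep.leverage, hat, atol=1e-10)
        assert np.allclose(rep.max_abs_dfbetas, np.max(np.abs(dfbetas), axis=1),
                           atol=1e-8)

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        y = 2 * x + rng.normal(size=100)
        x[0] = 10.0
        y[0] = -20.0
        X = np.column_stack([np.ones(100), x])
        rep = influence_filter(X, y)
        assert 0 in rep.flagged

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(CollinearityError):
            influence_filter(X, np.arange(20.0))

    def test_flagged_is_union_of_criteria(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = X[:, 1] + rng.normal(size=60)
        rep = influence_filter(X, y)
        union = set(np.flatnonzero(rep.cooks_d > rep.thresholds["cooks_d"])) \
            | set(np.flatnonzero(rep.leverage > rep.thresholds["leverage"])) \
            | set(np.flatnonzero(rep.max_abs_dfbetas > rep.thresholds["dfbetas"]))
        assert set(rep.flagged) == union


class TestMannWhitney:
    def test_worked_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_u_half(self):
        a = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(a, a)
        assert u == len(a) ** 2 / 2

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 7), (7, 7)])
    def test_small_samples_match_exhaustive_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for trial in range(3):
            a = rng.integers(0, 6, n1).astype(float)  # integers force ties
            b = rng.integers(0, 6, n2).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            u_ref, p_ref = mwu_enumeration(a, b)
            u, p = mann_whitney_u(a, b)
            assert u == u_ref
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_no_ties_exact_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        u, p = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_agrees_with_kruskal(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=25)
        b = rng.normal(0.5, 1, size=30)
        _, p_mwu = mann_whitney_u(a, b)
        _, p_kw = kruskal_wallis([a, b])
        assert p_mwu == pytest.approx(p_kw, abs=0.02)


class TestKruskalWallis:
    def test_label_permutation_invariant(self):
        groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 6.0], [0.5, 7.0, 8.0]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis(groups[::-1])
        assert h1 == pytest.approx(h2)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(size=15) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])


class TestMedianIQR:
    def test_hand_example(self):
        assert summarize_median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        assert summarize_median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=31)
        base = np.array(summarize_median_iqr(v))
        shifted = np.array(summarize_median_iqr(v + 10.0))
        assert np.allclose(shifted, base + 10.0)


def _plaque_table(rng, n_single, n_multi, multi_volume_scale=1.0):
    rows = []
    for i in range(n_single + n_multi):
        multi = i >= n_single
        scale = multi_volume_scale if multi else 1.0
        rows.append(
            {
                "plaque_id": f"P{i:03d}",
                "n_clusters": int(rng.integers(2, 5)) if multi else 1,
                "total_volume_mm3": rng.lognormal(5, 1),
                "mean_cluster_volume_mm3": scale * rng.lognormal(5, 1),
                "mean_eccentricity": rng.uniform(0.2, 2.5),
                "mean_compactness": rng.uniform(1.0, 4.0),
                "mean_mu_hu": rng.uniform(250, 700),
                "mean_sigma_hu": rng.uniform(50, 350),
                "is_multi": multi,
            }
        )
    return pd.DataFrame(rows)


class TestFragmentation:
    def test_all_single_cluster_refused(self):
        rng = np.random.default_rng(0)
        with pytest.raises(GroupSizeError, match="multi"):
            compare_fragmentation(_plaque_table(rng, 10, 0))

    def test_planted_volume_effect_detected(self):
        rng = np.random.default_rng(1)
        plaques = _plaque_table(rng, 80, 20, multi_volume_scale=0.25)
        results = compare_fragmentation(plaques)
        primary = {r.feature: r for r in results if r.grouping == "single_vs_multi"}
        assert primary["mean_cluster_volume_mm3"].p_value < 0.01

    def test_null_rejection_rates_calibrated(self):
        rng = np.random.default_rng(2)
        reps = 400
        rejections = {f: 0 for f in ("mean_cluster_volume_mm3", "mean_mu_hu")}
        for _ in range(reps):
            plaques = _plaque_table(rng, 40, 15)
            results = compare_fragmentation(plaques)
            for r in results:
                if r.grouping == "single_vs_multi" and r.feature in rejections:
                    rejections[r.feature] += r.p_value < 0.05
        for feat, count in rejections.items():
            assert 0.02 <= count / reps <= 0.08, feat

    def test_pairwise_only_when_kw_significant(self):
        rng = np.random.default_rng(3)
        plaques = _plaque_table(rng, 60, 30, multi_volume_scale=0.2)
        results = compare_fragmentation(plaques)
        for r in results:
            if r.grouping == "by_cluster_count":
                if r.p_value >= 0.05:
                    assert r.pairwise is None
                else:
                    assert {"group_a", "group_b", "U", "p", "q"} <= set(r.pairwise)

    def test_undersized_stratum_raises_in_strict_mode(self):
        rng = np.random.default_rng(4)
        plaques = _plaque_table(rng, 10, 3)
        plaques.loc[plaques.index[-1], "n_clusters"] = 9  # singleton stratum
        with pytest.raises(GroupSizeError, match="9"):
            compare_fragmentation(plaques, strict=True)
        compare_fragmentation(plaques)  # default drops the stratum


class TestCorrelationMatrix:
    def test_all_pairs_with_q_and_ci(self, small_cohort_features):
        feats = small_cohort_features
        out = correlation_matrix(feats, n_boot=100, seed=0)
        n_features = 6
        assert len(out) == n_features * (n_features - 1) // 2
        assert ((out.ci_lo <= out.rho) & (out.rho <= out.ci_hi)).all()
        assert out.q_value.between(0, 1).all()

    def test_partial_mode_adjusts_for_remaining_features(self, small_cohort_features):
        out = correlation_matrix(small_cohort_features, partial=True, n_boot=0, seed=0)
        row = out[(out.feature_x == "volume_mm3") & (out.feature_y == "mu_hu")].iloc[0]
        assert row.partial
        assert set(row.adjusted_for.split("|")) == {
            "aspect_ratio", "eccentricity", "compactness", "sigma_hu"
        }
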