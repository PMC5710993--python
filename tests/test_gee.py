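import numpy as np
import pandas as pd
import pytest

from twincrp import (
    FamilyGEE,
    ModelDesign,
    build_model_design,
    fit_gee,
    linear_trend_oracle,
    sex_interaction_test,
)
from twincrp.preprocess import EXPOSURE_CATEGORIES


def _ols(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


def _clustered_data(n_clusters, rho, beta, seed, cluster_size=2):
    """Exchangeable Gaussian clusters with known correlation and effects."""
    rng = np.random.default_rng(seed)
    n = n_clusters * cluster_size
    clusters = np.repeat(np.arange(n_clusters), cluster_size)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    shared = np.repeat(rng.normal(size=n_clusters), cluster_size)
    eps = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=n)
    y = X @ np.asarray(beta) + eps
    return y, X, clusters


class TestFamilyGEE:
    def test_singleton_clusters_reduce_to_ols(self):
        rng = np.random.default_rng(2)
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ np.array([1.0, 0.4, -0.2]) + rng.normal(size=n)
        fit = FamilyGEE(y, X, np.arange(n), ["const", "a", "b"]).fit()
        beta_ols, se_ols = _ols(y, X)
        np.testing.assert_allclose(fit.params.to_numpy(), beta_ols, atol=1e-12)
        np.testing.assert_allclose(fit.naive_se.to_numpy(), se_ols, atol=1e-12)
        assert fit.working_rho == 0.0

    def test_matches_statsmodels_exchangeable(self, small_analysis):
        sm = pytest.importorskip("statsmodels.api")
        design = build_model_design(small_analysis, "model4", "categorical", "F")
        mine = fit_gee(design)
        ref = sm.GEE(
            design.y,
            design.X,
            groups=design.clusters,
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
        np.testing.assert_allclose(mine.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(mine.robust_se.to_numpy(), ref.bse, rtol=1e-4)

    def test_working_rho_recovery(self):
        y, X, clusters = _clustered_data(4000, rho=0.5, beta=[0.5, 1.0], seed=3)
        fit = FamilyGEE(y, X, clusters, ["const", "x"]).fit()
        assert fit.working_rho == pytest.approx(0.5, abs=0.04)
        assert fit.converged

    def test_coefficients_invariant_to_row_order(self, small_analysis):
        design = build_model_design(small_analysis, "baseline", "categorical", "F")
        fit1 = fit_gee(design)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(design.y))
        design2 = ModelDesign(
            y=design.y[perm],
            X=design.X[perm],
            columns=design.columns,
            clusters=design.clusters[perm],
        )
        fit2 = fit_gee(design2)
        np.testing.assert_allclose(
            fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(
            fit1.robust_se.to_numpy(), fit2.robust_se.to_numpy(), atol=1e-10
        )

    def test_sandwich_matches_cluster_bootstrap(self):
        """Sandwich SE agrees with a nonparametric family bootstrap on a
        200-family fixture within Monte-Carlo error."""
        y, X, clusters = _clustered_data(200, rho=0.4, beta=[0.0, 0.8], seed=7)
        fit = FamilyGEE(y, X, clusters, ["const", "x"]).fit()
        rng = np.random.default_rng(11)
        reps = []
        ids = np.arange(200)
        for _ in range(400):
            chosen = rng.choice(ids, size=200, replace=True)
            rows = np.concatenate([np.flatnonzero(clusters == c) for c in chosen])
            new_clusters = np.repeat(np.arange(200), 2)
            reps.append(
                FamilyGEE(y[rows], X[rows], new_clusters, ["const", "x"])
                .fit()
                .params["x"]
            )
        boot_se = np.std(reps, ddof=1)
        assert fit.robust_se["x"] == pytest.approx(boot_se, rel=0.2)

    def test_ci_uses_1p96_robust_se(self):
        y, X, clusters = _clustered_data(100, rho=0.3, beta=[0.2, 0.5], seed=9)
        fit = FamilyGEE(y, X, clusters, ["const", "x"]).fit()
        ci = fit.conf_int()
        for term in fit.params.index:
            assert ci.loc[term, "lower"] == pytest.approx(
                fit.params[term] - 1.96 * fit.robust_se[term]
            )
        assert (fit.robust_se > 0).all()
        assert fit.n_obs >= fit.n_clusters

    def test_honest_convergence_flag(self):
        y, X, clusters = _clustered_data(500, rho=0.5, beta=[0.0, 1.0], seed=4)
        fit = FamilyGEE(y, X, clusters, ["const", "x"]).fit(tol=1e-16, max_iter=2)
        assert not fit.converged
        assert fit.iterations == 2

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        with pytest.raises(ValueError, match=r"collinear columns: \['(x|dup)'\]"):
            ModelDesign(
                y=rng.normal(size=50),
                X=X,
                columns=["const", "x", "dup"],
                clusters=np.arange(50),
            )


class TestModelDesigns:
    @pytest.mark.parametrize(
        "model_id, extra_cols",
        [
            ("baseline", []),
            ("model1", ["genetic_score"]),
            ("model2", ["ses_middle", "ses_low"]),
            ("model3", ["waist_hip_ratio", "body_temp"]),
            (
                "model4",
                ["genetic_score", "ses_middle", "ses_low", "waist_hip_ratio", "body_temp"],
            ),
        ],
    )
    def test_ladder_columns(self, small_analysis, model_id, extra_cols):
        design = build_model_design(small_analysis, model_id, "categorical", "F")
        expected = ["intercept", "victimization_one", "victimization_poly"] + extra_cols
        assert design.columns == expected

    def test_stratum_filters_rows(self, small_analysis):
        d_f = build_model_design(small_analysis, "baseline", "categorical", "F")
        d_all = build_model_design(small_analysis, "baseline", "categorical", "all")
        n_female = (small_analysis["sex"] == "F").sum()
        assert d_f.n_obs == n_female
        assert d_all.n_obs == len(small_analysis)

    def test_linear_coding_values(self, small_analysis):
        design = build_model_design(small_analysis, "baseline", "linear", "all")
        assert design.columns == ["intercept", "victimization_linear"]
        assert set(np.unique(design.X[:, 1])) <= {0.0, 1.0, 2.0}

    def test_missing_score_errors_with_count(self, small_analysis):
        broken = small_analysis.copy()
        broken.loc[broken.index[:7], "genetic_score"] = np.nan
        with pytest.raises(ValueError, match="7 records"):
            build_model_design(broken, "model1", "categorical", "all")


class TestLinearTrendOracle:
    def test_study_proportions(self):
        slope = linear_trend_oracle((0.0, 0.21, 0.56), (0.726, 0.210, 0.064))
        assert slope == pytest.approx(0.252, abs=5e-4)

    def test_exact_linearity_returns_increment(self):
        for x in (0.1, 0.5, -0.2):
            assert linear_trend_oracle((0.0, x, 2 * x), (0.5, 0.3, 0.2)) == pytest.approx(x)

    def test_null_effects(self):
        assert linear_trend_oracle((0.0, 0.0, 0.0), (0.7, 0.2, 0.1)) == 0.0

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            linear_trend_oracle((0.0, 0.1, 0.2), (1.0, 0.0, 0.0))

    def test_gee_matches_oracle_on_noise_free_data(self):
        """On deterministic outcomes the fitted linear-trend slope equals the
        closed form evaluated at the empirical category proportions."""
        rng = np.random.default_rng(12)
        effects = np.array([0.0, 0.21, 0.56])
        cats = rng.choice(3, size=3000, p=[0.726, 0.210, 0.064])
        y = effects[cats]
        table = pd.DataFrame(
            {
                "family_id": np.arange(3000),
                "sex": "F",
                "exposure_category": np.asarray(EXPOSURE_CATEGORIES)[cats],
                "log_crp": y,
            }
        )
        design = build_model_design(table, "baseline", "linear", "all")
        fit = fit_gee(design)
        props = np.bincount(cats, minlength=3) / len(cats)
        assert fit.params["victimization_linear"] == pytest.approx(
            linear_trend_oracle(effects, props), abs=1e-10
        )


class TestSexInteraction:
    def test_single_sex_table_rejected(self, small_analysis):
        females = small_analysis[small_analysis["sex"] == "F"]
        with pytest.raises(ValueError, match="both sexes"):
            sex_interaction_test(females)

    def test_detects_extreme_sex_difference(self):
        rng = np.random.default_rng(8)
        n = 4000
        cats = rng.choice(3, size=n, p=[0.6, 0.3, 0.1])
        male = rng.random(n) < 0.5
        y = np.where(male, 0.0, 1.0) * cats + rng.normal(size=n)
        table = pd.DataFrame(
            {
                "family_id": np.arange(n),
                "sex": np.where(male, "M", "F"),
                "exposure_category": np.asarray(EXPOSURE_CATEGORIES)[cats],
                "log_crp": y,
            }
        )
        p, fit = sex_interaction_test(table)
        assert p < 1e-3
        assert fit.params["victimization_x_male"] < 0

    def test_type_one_error_calibrated_under_null(self):
        """With identical effects in both sexes the interaction p-value is
        roughly uniform: the rejection rate at alpha=0.2 stays near 0.2."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 50
        for _ in range(n_reps):
            n = 400
            cats = rng.choice(3, size=n, p=[0.6, 0.3, 0.1])
            male = rng.random(n) < 0.5
            y = 0.3 * cats + rng.normal(size=n)
            table = pd.DataFrame(
                {
                    "family_id": np.arange(n),
                    "sex": np.where(male, "M", "F"),
                    "exposure_category": np.asarray(EXPOSURE_CATEGORIES)[cats],
                    "log_crp": y,
                }
            )
            p, _ = sex_interaction_test(table)
            rejections += p < 0.2
        # Binomial(50, 0.2): 3 sd ~ 0.17
        assert rejections / n_reps == pytest.approx(0.2, abs=0.17)
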