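"""Quadratic fitting, ANOVA partition, fit statistics, elimination, normality."""

import numpy as np
import pytest

from cesep.design import DesignMatrix, Factor, FactorSpace, ModelSpec, build_candidate_set, d_optimal
from cesep.errors import DomainError, RankDeficiencyError
from cesep.rsm import (
    anova,
    backward_eliminate,
    fit_quadratic,
    fit_statistics,
    residual_normality,
    term_tests,
)
from cesep.synthetic import make_truth, simulate_doe_responses


@pytest.fixture(scope="module")
def noisy_fit(design30, quad_spec):
    rng = np.random.default_rng(5)
    beta = rng.normal(0, 0.3, quad_spec.n_params)
    beta[0] = 1.2
    X = quad_spec.matrix(design30.coded)
    y = X @ beta + rng.normal(0, 0.05, design30.n_runs)
    model = fit_quadratic(design30, y, quad_spec)
    return design30, y, model


class TestFitQuadratic:
    def test_exact_recovery_without_noise(self, fs, quad_spec, design25):
        truth = make_truth(11, fs)
        resp = simulate_doe_responses(truth, design25, seed=12, noise_scale=0.0)
        for name in ["Rs1", "Rs3", "MT"]:
            model = fit_quadratic(design25, resp[name], quad_spec)
            assert np.allclose(model.coef, truth.coef[name], atol=1e-8)

    def test_constant_response(self, design25, quad_spec):
        y = np.full(design25.n_runs, 3.7)
        model = fit_quadratic(design25, y, quad_spec)
        assert model.coef[0] == pytest.approx(3.7)
        assert np.allclose(model.coef[1:], 0.0, atol=1e-10)

    def test_too_few_runs(self, quad_spec):
        coded = np.zeros((5, 4))
        with pytest.raises(RankDeficiencyError):
            fit_quadratic(coded, np.ones(5), quad_spec)

    def test_aliased_terms_named(self):
        # candidates on the diagonal: y-column duplicates x-column
        spec = ModelSpec.linear(["x", "y"])
        coded = np.array([[v, v] for v in np.linspace(-1, 1, 6)])
        with pytest.raises(RankDeficiencyError, match="aliased"):
            fit_quadratic(coded, np.ones(6), spec)

    def test_statsmodels_cross_check(self, noisy_fit, quad_spec):
        """Coefficients, term p-values and R² agree with an independent OLS."""
        import statsmodels.api as sm

        design, y, model = noisy_fit
        X = quad_spec.matrix(design.coded)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(model.coef, ref.params, atol=1e-10)
        tests = term_tests(model, design, y)
        assert np.allclose(tests["p"], ref.pvalues, atol=1e-10)
        stats = fit_statistics(model, design, y)
        assert stats.r2 == pytest.approx(ref.rsquared, abs=1e-10)
        assert stats.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-10)


class TestAnova:
    def test_partition_additivity(self, noisy_fit):
        design, y, model = noisy_fit
        table = anova(model, design, y)
        assert table.model.ss + table.residual.ss == pytest.approx(table.total.ss, rel=1e-8)
        assert table.model.df + table.residual.df == table.total.df
        assert table.lof_available
        assert table.lack_of_fit.ss + table.pure_error.ss == pytest.approx(
            table.residual.ss, rel=1e-8
        )
        assert table.lack_of_fit.df + table.pure_error.df == table.residual.df

    def test_exact_fit_zero_residual(self, fs, quad_spec, design25):
        truth = make_truth(13, fs)
        resp = simulate_doe_responses(truth, design25, seed=14, noise_scale=0.0)
        model = fit_quadratic(design25, resp["MT"], quad_spec)
        table = anova(model, design25, resp["MT"])
        assert table.residual.ss == pytest.approx(0.0, abs=1e-16)

    def test_replicates_with_identical_y_zero_pure_error(self, quad_spec):
        rng = np.random.default_rng(3)
        grid = build_candidate_set(FactorSpace.default(), 3)
        non_center = np.where(np.any(grid != 0.0, axis=1))[0]
        base = grid[rng.choice(non_center, 20, replace=False)]
        coded = np.vstack([base, np.zeros((5, 4))])
        y = rng.normal(size=25)
        y[20:] = 1.0  # identical values on the five replicated center runs
        model = fit_quadratic(coded, y, quad_spec)
        table = anova(model, coded, y)
        assert table.pure_error.ss == pytest.approx(0.0, abs=1e-16)

    def test_no_replicates_no_lof_row(self, quad_spec):
        rng = np.random.default_rng(4)
        grid = build_candidate_set(FactorSpace.default(), 3)
        coded = grid[rng.choice(len(grid), 25, replace=False)]
        y = rng.normal(size=25)
        model = fit_quadratic(coded, y, quad_spec)
        table = anova(model, coded, y)
        assert not table.lof_available

    def test_null_rejection_rate_calibrated(self, design30, quad_spec):
        """Pure-noise responses reject the model F-test at ~alpha over seeds."""
        rejections = 0
        n_seeds = 500
        for s in range(n_seeds):
            rng = np.random.default_rng(10_000 + s)
            y = 1.2 + rng.normal(0, 0.05, design30.n_runs)
            model = fit_quadratic(design30, y, quad_spec)
            rejections += anova(model, design30, y).model.p < 0.05
        # two-sided binomial band for a true rate of 0.05 at n=500
        assert 10 <= rejections <= 42


class TestFitStatistics:
    def test_exact_fit_r2_one(self, fs, quad_spec, design25):
        truth = make_truth(15, fs)
        resp = simulate_doe_responses(truth, design25, seed=16, noise_scale=0.0)
        stats = fit_statistics(
            fit_quadratic(design25, resp["Rs2"], quad_spec), design25, resp["Rs2"]
        )
        assert stats.r2 == pytest.approx(1.0)

    def test_intercept_only_r2_zero(self, design25):
        spec0 = ModelSpec(factor_names=FactorSpace.default().names, terms=((),))
        rng = np.random.default_rng(6)
        y = rng.normal(size=design25.n_runs)
        stats = fit_statistics(fit_quadratic(design25, y, spec0), design25, y)
        assert stats.r2 == pytest.approx(0.0, abs=1e-12)

    def test_press_equals_explicit_loo(self):
        """Leverage-formula PRESS matches brute-force leave-one-out refits."""
        spec = ModelSpec.full_quadratic(["x"])
        coded = np.linspace(-1, 1, 10).reshape(-1, 1)
        rng = np.random.default_rng(7)
        y = 1.0 + 0.5 * coded.ravel() - 0.8 * coded.ravel() ** 2 + rng.normal(0, 0.1, 10)
        model = fit_quadratic(coded, y, spec)
        stats = fit_statistics(model, coded, y)
        press_loo = 0.0
        for i in range(10):
            keep = np.arange(10) != i
            m_i = fit_quadratic(coded[keep], y[keep], spec)
            press_loo += (y[i] - m_i.predict_coded(coded[i : i + 1])[0]) ** 2
        assert stats.press == pytest.approx(press_loo, abs=1e-8)

    def test_r2_ordering_on_noisy_fixtures(self, fs, quad_spec, design25):
        for s in range(5):
            truth = make_truth(30 + s, fs, "realistic")
            resp = simulate_doe_responses(truth, design25, seed=40 + s)
            y = resp["Rs1"].to_numpy()
            stats = fit_statistics(fit_quadratic(design25, y, quad_spec), design25, y)
            assert stats.adj_r2 <= stats.r2
            assert stats.pred_r2 <= stats.adj_r2 + 1e-12

    def test_health_flags(self, noisy_fit):
        design, y, model = noisy_fit
        flags = fit_statistics(model, design, y).health_flags()
        assert set(flags) == {"r2_gap_ok", "adeq_precision_ok"}


class TestBackwardElimination:
    def test_all_significant_unchanged(self, design30):
        spec = ModelSpec.linear(FactorSpace.default().names)
        rng = np.random.default_rng(8)
        X = spec.matrix(design30.coded)
        y = X @ np.array([1.0, 0.8, -0.7, 0.9, 0.6]) + rng.normal(0, 0.02, design30.n_runs)
        model = fit_quadratic(design30, y, spec)
        refined = backward_eliminate(model, design30, y)
        assert refined.spec.terms == spec.terms

    def test_hierarchy_retains_linear_parent(self, design30, quad_spec):
        """A strong interaction keeps its linear parents in the model."""
        names = FactorSpace.default().names
        rng = np.random.default_rng(9)
        beta = np.zeros(quad_spec.n_params)
        beta[0] = 1.0
        beta[quad_spec.terms.index((names[0], names[3]))] = 0.9  # boric x pH
        X = quad_spec.matrix(design30.coded)
        y = X @ beta + rng.normal(0, 0.02, design30.n_runs)
        refined = backward_eliminate(fit_quadratic(design30, y, quad_spec), design30, y)
        assert (names[0], names[3]) in refined.spec.terms
        assert (names[0],) in refined.spec.terms
        assert (names[3],) in refined.spec.terms

    def test_no_hierarchy_can_drop_parent(self, design30, quad_spec):
        names = FactorSpace.default().names
        rng = np.random.default_rng(9)
        beta = np.zeros(quad_spec.n_params)
        beta[0] = 1.0
        beta[quad_spec.terms.index((names[0], names[3]))] = 0.9
        X = quad_spec.matrix(design30.coded)
        y = X @ beta + rng.normal(0, 0.02, design30.n_runs)
        refined = backward_eliminate(
            fit_quadratic(design30, y, quad_spec), design30, y, hierarchy=False
        )
        assert (names[0], names[3]) in refined.spec.terms
        assert (names[0],) not in refined.spec.terms

    def test_null_terms_mostly_removed(self, fs, quad_spec, design25):
        """Terms of a factor with zero true effect are removed at a high rate.

        Each truly-zero term survives elimination with probability around the
        elimination alpha (its p-value is uniform no matter how small the
        noise), somewhat above it here because design columns correlate and
        hierarchy protects linear parents; the per-term removal rate is
        therefore high but bounded away from one.
        """
        removed = total = 0
        n_doc_terms = sum(1 for t in quad_spec.terms if "doc" in t)
        for s in range(100):
            truth = make_truth(1000 + s, fs, "easy", zero_factors=("doc",))
            rng = np.random.default_rng(2000 + s)
            y = truth.surface("Rs1", design25.coded) + rng.normal(0, 0.01, design25.n_runs)
            refined = backward_eliminate(
                fit_quadratic(design25, y, quad_spec), design25, y, alpha=0.1
            )
            left = sum(1 for t in refined.spec.terms if "doc" in t)
            removed += n_doc_terms - left
            total += n_doc_terms
        assert removed / total >= 0.70

    def test_alpha_domain(self, noisy_fit):
        design, y, model = noisy_fit
        with pytest.raises(DomainError):
            backward_eliminate(model, design, y, alpha=1.5)


class TestResidualNormality:
    def test_normal_residuals_pass(self, design30, quad_spec):
        X = quad_spec.matrix(design30.coded)
        passes = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            y = 1.0 + 0.3 * X[:, 1] + rng.normal(0, 0.05, design30.n_runs)
            model = fit_quadratic(design30, y, quad_spec)
            passes += residual_normality(model, design30, y).pvalue > 0.05
        assert passes >= 90

    def test_bimodal_residuals_rejected(self, design30):
        """A heavy symmetric mixture around an intercept-only fit is detected.

        The mixture is planted against an intercept-only model: residuals of
        a many-term fit are near-normal by projection even for strongly
        bimodal errors, so the plain residual vector is the probing ground.
        """
        spec0 = ModelSpec(factor_names=FactorSpace.default().names, terms=((),))
        rejects = 0
        n = design30.n_runs
        for s in range(100):
            rng = np.random.default_rng(s)
            comp = rng.integers(0, 2, n) * 2 - 1
            y = 1.0 + comp * 0.3 + rng.normal(0, 0.03, n)
            model = fit_quadratic(design30, y, spec0)
            rejects += residual_normality(model, design30, y).pvalue < 0.05
        assert rejects >= 90

    def test_constant_residuals_not_computable(self, design25, quad_spec):
        y = quad_spec.matrix(design25.coded) @ np.r_[2.0, np.zeros(14)]
        model = fit_quadratic(design25, y, quad_spec)
        assert not residual_normality(model, design25, y).computable

    def test_tiny_residual_df_not_computable(self):
        spec = ModelSpec.full_quadratic(["x"])
        coded = np.array([[-1.0], [-0.5], [0.5], [1.0]])
        rng = np.random.default_rng(1)
        y = rng.normal(size=4)
        model = fit_quadratic(coded, y, spec)
        assert not residual_normality(model, coded, y).computable
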