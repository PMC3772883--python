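import numpy as np
import pytest

from cfakit.corr_data import CorrelationSample
from cfakit.estimator import (
    ConfirmatoryFactorAnalysis,
    ParamLayout,
    _hessian,
    embed_start,
    expected_information_F,
    fit_model,
    implied_matrix,
    information_matrix,
    ml_discrepancy,
    sign_normalize,
)
from cfakit.model_spec import (
    MODIFIED_CHC_WEIGHTS,
    FactorModelSpec,
    FactorStructure,
    simple_structure_pattern,
)
from cfakit.synthetic_data import (
    SyntheticConfig,
    exact_population_matrix,
    full_true_vector,
    modified_chc_truth,
    sample_matrix,
)
from conftest import make_toy_spec, toy_population


def align_columns(L, ref):
    """Resolve per-factor sign indeterminacy against a reference matrix."""
    out = L.copy()
    for k in range(L.shape[1]):
        if np.linalg.norm(out[:, k] - ref[:, k]) > np.linalg.norm(out[:, k] + ref[:, k]):
            out[:, k] *= -1
    return out


class TestDiscrepancy:
    def test_self_discrepancy_is_zero(self, chc_population):
        assert ml_discrepancy(chc_population.R, chc_population.R) == pytest.approx(0, abs=1e-12)

    def test_closed_form_2x2(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        # F(S, I) = -ln|S| = -ln(0.75)
        assert ml_discrepancy(S, np.eye(2)) == pytest.approx(-np.log(0.75), abs=1e-12)

    def test_permutation_invariance(self, chc_population):
        rng = np.random.default_rng(3)
        S = chc_population.R
        Sigma = 0.5 * S + 0.5 * np.eye(15)
        perm = rng.permutation(15)
        f1 = ml_discrepancy(S, Sigma)
        f2 = ml_discrepancy(S[np.ix_(perm, perm)], Sigma[np.ix_(perm, perm)])
        assert f1 == pytest.approx(f2, rel=1e-12)


class TestImpliedMatrix:
    def test_zero_loadings_identity(self, toy_spec):
        layout = ParamLayout(toy_spec)
        theta = np.concatenate([np.zeros(layout.nl), np.ones(9)])
        assert np.allclose(implied_matrix(toy_spec, theta), np.eye(9))

    def test_reference_weights_dot_product(self, chc_population):
        # (Block Design, Visual Puzzles) entry is the loading-row dot product
        expected = 0.6474 * 0.6571 + (-0.4970) * (-0.4815)
        assert chc_population.R[0, 7] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.664712, abs=1e-6)

    def test_one_factor_closed_form(self):
        pat = simple_structure_pattern({"f": ("x", "y", "z")}, ("x", "y", "z"))
        spec = FactorModelSpec("one", pat, FactorStructure("orthonormal"))
        a, b, c = 0.6, 0.3, 0.5
        theta = np.array([a, b, c, 1 - a**2, 1 - b**2, 1 - c**2])
        Sigma = implied_matrix(spec, theta)
        assert Sigma[0, 1] == pytest.approx(a * b, abs=1e-15)
        assert Sigma[0, 2] == pytest.approx(a * c, abs=1e-15)
        assert np.allclose(np.diag(Sigma), 1.0)

    def test_wrong_length_rejected(self, toy_spec):
        with pytest.raises(ValueError, match="length"):
            implied_matrix(toy_spec, np.zeros(3))


class TestExactRecovery:
    def test_modified_chc_recovers_reference_loadings(self, catalog, chc_population):
        fit = fit_model(catalog["modified_chc"], chc_population)
        assert fit.F_min < 1e-8
        L = align_columns(fit.loadings, MODIFIED_CHC_WEIGHTS)
        assert np.max(np.abs(L - MODIFIED_CHC_WEIGHTS)) < 1e-3

    @pytest.mark.parametrize("kind", ["oblique", "second_order"])
    def test_structured_models_recover_own_implied_matrix(self, catalog, kind):
        spec = catalog["ward_2011" if kind == "oblique" else "benson_2010"]
        layout = ParamLayout(spec)
        rng = np.random.default_rng(11)
        params = np.empty(layout.nl + layout.ns)
        # ranges keep the cross-loading subtest's communality below 1
        params[: layout.nl] = rng.uniform(0.35, 0.55, layout.nl)
        if kind == "oblique":
            params[layout.nl :] = rng.uniform(0.2, 0.4, layout.ns)
        else:
            m = layout.m
            params[layout.nl : layout.nl + m] = rng.uniform(0.5, 0.7, m)
            params[layout.nl + m :] = rng.uniform(0.2, 0.3, m)
        cfg = SyntheticConfig(spec=spec, true_params=params, n_obs=1000)
        pop = exact_population_matrix(cfg)
        fit = fit_model(spec, pop)
        assert fit.F_min < 1e-8
        truth = full_true_vector(cfg)

        def standardized(L, Phi):
            # the second-order form has a per-factor scale indeterminacy
            # (lambda*c, gamma/c, psi/c^2); compare scale-invariant forms
            d = np.sqrt(np.diag(Phi))
            return L * d, Phi / np.outer(d, d)

        L_est, P_est = standardized(fit.loadings, fit.phi)
        L_true, P_true = standardized(layout.loadings(truth), layout.phi(truth))
        est = align_columns(L_est, L_true)
        assert np.max(np.abs(est - L_true)) < 1e-3
        assert np.max(np.abs(np.abs(P_est) - np.abs(P_true))) < 1e-3

    def test_null_fit_closed_form(self, chc_truth):
        sample = sample_matrix(chc_truth, seed=5)
        fit = fit_model("null", sample)
        assert np.allclose(fit.Sigma_hat, np.eye(15), atol=1e-7)
        expected = -(sample.n_obs - 1) * np.linalg.slogdet(sample.R)[1]
        assert fit.chi2 == pytest.approx(expected, abs=1e-6 * expected)

    def test_fit_is_deterministic(self, catalog, chc_population):
        f1 = fit_model(catalog["modified_chc"], chc_population)
        f2 = fit_model(catalog["modified_chc"], chc_population)
        assert np.array_equal(f1.theta_hat, f2.theta_hat)


class TestStochasticRecovery:
    def test_large_sample_recovery_within_three_standard_errors(self, chc_truth, catalog):
        from dataclasses import replace

        cfg = replace(chc_truth, n_obs=5000)
        sample = sample_matrix(cfg, seed=42)
        fit = fit_model(catalog["modified_chc"], sample)
        layout = fit.layout
        truth = full_true_vector(cfg)
        est = align_columns(fit.loadings, layout.loadings(truth))
        info = information_matrix(fit)
        se = np.sqrt(np.diag(np.linalg.inv(info)))[: layout.nl]
        resid = np.abs(
            est[layout.free_rows, layout.free_cols]
            - layout.loadings(truth)[layout.free_rows, layout.free_cols]
        )
        assert np.all(resid <= 3 * se + 1e-3)

    def test_nesting_monotonicity(self, chc_truth, catalog):
        sample = sample_matrix(chc_truth, seed=9)
        chi_sub = fit_model(catalog["modified_chc"], sample).chi2
        chi_full = fit_model(catalog["orthogonal_6"], sample).chi2
        assert chi_full <= chi_sub + 1e-6

    def test_jittered_starts_reach_same_minimum(self, chc_truth, catalog):
        sample = sample_matrix(chc_truth, seed=21)
        for name in ("modified_chc", "ward_2011"):
            spec = catalog[name]
            layout = ParamLayout(spec)
            base = fit_model(spec, sample)
            rng = np.random.default_rng(77)
            for _ in range(5):
                start = layout.default_start(sample.R) + rng.uniform(
                    -0.05, 0.05, layout.n_params
                )
                refit = fit_model(spec, sample, start=start)
                assert refit.F_min == pytest.approx(base.F_min, abs=1e-6)


class TestInformation:
    def test_finite_difference_matches_expected_at_truth(self, toy_spec):
        pop = toy_population(toy_spec)
        fit = fit_model(toy_spec, pop)
        layout = fit.layout
        H_fd = _hessian(layout, fit.theta_hat, pop.R)
        H_exp = expected_information_F(layout, fit.theta_hat)
        scale = np.max(np.abs(H_exp))
        assert np.max(np.abs(H_fd - H_exp)) / scale < 1e-4

    def test_information_scales_with_n(self, toy_spec):
        pop = toy_population(toy_spec)
        fit1 = fit_model(toy_spec, pop)
        big = CorrelationSample(pop.names, pop.R, 4 * (pop.n_obs - 1) + 1)
        fit4 = fit_model(toy_spec, big)
        I1 = information_matrix(fit1)
        I4 = information_matrix(fit4)
        assert np.allclose(I4, 4 * I1, rtol=1e-6)


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self, catalog):
        est = ConfirmatoryFactorAnalysis(catalog["modified_chc"], gtol=1e-6)
        params = est.get_params()
        assert params["gtol"] == 1e-6
        est.set_params(gtol=1e-8)
        assert est.gtol == 1e-8

    def test_fit_sets_trailing_underscore_attributes(self, chc_population):
        est = ConfirmatoryFactorAnalysis("modified_chc").fit(chc_population)
        assert est.converged_ and est.df_ == 62
        assert est.loadings_.shape == (15, 6)
        assert est.score(chc_population) == pytest.approx(0.0, abs=1e-8)

    def test_bare_matrix_requires_n_obs(self, chc_population):
        est = ConfirmatoryFactorAnalysis("modified_chc")
        with pytest.raises(ValueError, match="n_obs"):
            est.fit(chc_population.R)

    def test_unknown_catalog_name_rejected(self, chc_population):
        with pytest.raises(ValueError, match="unknown catalog model"):
            ConfirmatoryFactorAnalysis("nope").fit(chc_population)


class TestSignNormalization:
    def test_largest_loading_per_factor_positive(self, catalog, chc_population):
        fit = sign_normalize(fit_model(catalog["modified_chc"], chc_population))
        L = fit.loadings
        for k in range(L.shape[1]):
            col = L[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_normalization_preserves_implied_matrix(self, catalog, chc_population):
        fit = fit_model(catalog["ward_2011"], chc_population)
        flipped = sign_normalize(fit)
        assert np.allclose(
            flipped.layout.sigma(flipped.theta_hat), fit.Sigma_hat, atol=1e-12
        )


def test_embed_start_carries_shared_parameters(toy_spec, toy_true_spec):
    pop = toy_population(toy_spec)
    fit = fit_model(toy_spec, pop)
    x0 = embed_start(fit, toy_true_spec)
    layout = ParamLayout(toy_true_spec)
    new_cell = [
        j for j, (r, c) in enumerate(zip(layout.free_rows, layout.free_cols))
        if (r, c) == (0, 1)
    ][0]
    assert x0[new_cell] == 0.0
    assert np.isclose(x0[0], fit.theta_hat[0])
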