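import numpy as np
import pytest

from cfakit.corr_data import CorrelationSample
from cfakit.estimator import ParamLayout, fit_model
from cfakit.model_spec import with_free_cell
from cfakit.modification import (
    StepwiseModification,
    candidate_cells,
    lagrange_rank,
    stepwise_modify,
    wald_rank,
)
from cfakit.synthetic_data import SyntheticConfig, exact_population_matrix, sample_matrix
from conftest import make_toy_spec, toy_population


@pytest.fixture(scope="module")
def base_fit(toy_spec, toy_true_population):
    """Under-specified fit: the data carry an extra (A, F2) loading of 0.4."""
    return fit_model(toy_spec, toy_true_population)


class TestLagrange:
    def test_planted_cross_loading_ranks_first(self, base_fit):
        lm = lagrange_rank(base_fit)
        assert lm[0][0] == ("A", "F2")
        assert lm[0][2] < 1e-10

    def test_projection_within_quarter_of_refit(self, base_fit, toy_true_spec,
                                                toy_true_population):
        lm = lagrange_rank(base_fit)
        refit = fit_model(toy_true_spec, toy_true_population)
        actual = base_fit.chi2 - refit.chi2
        assert lm[0][1] == pytest.approx(actual, rel=0.25)

    def test_all_projections_nonnegative(self, base_fit):
        assert all(stat >= 0 for _, stat, _ in lagrange_rank(base_fit))

    def test_true_model_has_vanishing_scores(self, toy_true_spec, toy_true_population):
        fit = fit_model(toy_true_spec, toy_true_population)
        lm = lagrange_rank(fit)
        assert max(stat for _, stat, _ in lm) < 1e-6


@pytest.fixture(scope="module")
def overfit(toy_true_spec):
    # spurious free cell (B, F3) whose true loading is 0
    spec = with_free_cell(toy_true_spec, "B", "F3")
    pop = toy_population(spec, overrides={(0, 1): 0.4, (1, 2): 0.0})
    return spec, pop, fit_model(spec, pop)


class TestWald:
    def test_spurious_loading_ranks_smallest(self, overfit):
        _, _, fit = overfit
        w = wald_rank(fit)
        assert w[0][0] == ("B", "F3")
        assert w[0][2] > 0.9

    def test_drop_projection_matches_refit_for_small_effect(self, toy_true_spec):
        spec = with_free_cell(toy_true_spec, "B", "F3")
        pop = toy_population(spec, overrides={(0, 1): 0.4, (1, 2): 0.1})
        fit = fit_model(spec, pop)
        w = {cell: stat for cell, stat, _ in wald_rank(fit)}
        drop_fit = fit_model(toy_true_spec, pop)
        actual = drop_fit.chi2 - fit.chi2
        assert w[("B", "F3")] == pytest.approx(actual, rel=0.25)

    def test_statistics_scale_with_n(self, overfit):
        spec, pop, fit = overfit
        big = CorrelationSample(pop.names, pop.R, 2 * (pop.n_obs - 1) + 1)
        fit2 = fit_model(spec, big)
        w1 = dict((c, s) for c, s, _ in wald_rank(fit))
        w2 = dict((c, s) for c, s, _ in wald_rank(fit2))
        for cell, stat in w1.items():
            assert w2[cell] == pytest.approx(2 * stat, rel=1e-5)


class TestStepwise:
    def test_no_steps_at_truth(self, toy_true_spec, toy_true_population):
        final, log = stepwise_modify(toy_true_spec, toy_true_population)
        assert log.steps == []
        assert np.array_equal(final.pattern.free, toy_true_spec.pattern.free)

    def test_single_add_restores_missing_loading(self, toy_spec, toy_true_spec,
                                                 toy_true_population):
        final, log = stepwise_modify(toy_spec, toy_true_population)
        accepted = [s for s in log.steps if s.accepted]
        assert [(s.action, s.parameter) for s in accepted] == [("ADD", ("A", "F2"))]
        assert np.array_equal(final.pattern.free, toy_true_spec.pattern.free)

    def test_single_drop_removes_spurious_loading(self, toy_true_spec):
        spec = with_free_cell(toy_true_spec, "B", "F3")
        pop = toy_population(spec, overrides={(0, 1): 0.4, (1, 2): 0.0})
        final, log = stepwise_modify(spec, pop)
        accepted = [s for s in log.steps if s.accepted]
        assert [(s.action, s.parameter) for s in accepted] == [("DROP", ("B", "F3"))]
        assert np.array_equal(final.pattern.free, toy_true_spec.pattern.free)

    def test_df_bookkeeping_identity(self, toy_spec, toy_true_population):
        final, log = stepwise_modify(toy_spec, toy_true_population)
        assert final.df == toy_spec.df - log.n_added + log.n_dropped

    def test_accepted_adds_decrease_chi2(self, toy_spec, toy_true_population):
        _, log = stepwise_modify(toy_spec, toy_true_population)
        for s in log.steps:
            if s.accepted and s.action == "ADD":
                assert s.actual_dchi2 > 0

    def test_search_is_deterministic(self, toy_spec, toy_true_population):
        f1, l1 = stepwise_modify(toy_spec, toy_true_population)
        f2, l2 = stepwise_modify(toy_spec, toy_true_population)
        assert l1.steps == l2.steps
        assert np.array_equal(f1.pattern.free, f2.pattern.free)

    def test_estimator_wrapper(self, toy_spec, toy_true_population):
        est = StepwiseModification(toy_spec).fit(toy_true_population)
        assert est.log_.n_added == 1
        assert est.result_.converged

    def test_large_general_loadings_survive_on_noisy_replicates(self, catalog):
        """Stepwise search on nested-model surrogate data must not strip the
        general factor when its loadings are large in truth."""
        spec = catalog["nested_chc"]
        layout = ParamLayout(spec)
        params = np.full(layout.nl, 0.45)
        params[layout.free_cols == 0] = 0.6  # general column
        cfg = SyntheticConfig(spec=spec, true_params=params, n_obs=1000)
        for rep in range(6):
            sample = sample_matrix(cfg, seed=300 + rep)
            _, log = stepwise_modify(spec, sample, max_steps=12)
            for s in log.steps:
                if s.accepted and s.action == "DROP":
                    assert s.parameter[1] != "g"


def test_candidate_cells_are_fixed_zero_cells(toy_spec):
    cells = candidate_cells(toy_spec)
    assert ("A", "F2") in cells and ("A", "F1") not in cells
    assert len(cells) == 9 * 3 - 9
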