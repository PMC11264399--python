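"""Fitting, standard errors, pruning, model search, fit indices, BIC."""

import numpy as np
import pytest

from panelgvar.estimation import (
    FittedModel,
    _wald_p,
    compare_bic,
    fit_gvar,
    fit_indices,
    indices_from_chi2,
    model_search,
    prune,
    saturated_loglik,
    standard_errors,
)
from panelgvar.estimation import _iter_candidate_edges
from panelgvar.gvar import EdgePattern, GVARParameters
from panelgvar.synthetic import TruthSpec, make_truth, simulate_panel

from conftest import make_dataset


@pytest.fixture(scope="module")
def sparse_truth():
    return make_truth(TruthSpec(p=4, temporal_density=0.15, seed=42))


@pytest.fixture(scope="module")
def big_sim(sparse_truth):
    return simulate_panel(sparse_truth, 2000, seed=43)


@pytest.fixture(scope="module")
def fitted_true_pattern(sparse_truth, big_sim):
    pattern = EdgePattern(
        sparse_truth.B != 0,
        (sparse_truth.K_zeta != 0) | np.eye(4, dtype=bool),
        (sparse_truth.K_between != 0) | np.eye(4, dtype=bool),
    )
    model = fit_gvar(big_sim, pattern)
    standard_errors(model, big_sim)
    return model


class TestFitGvar:
    def test_recovers_truth_within_three_se(self, sparse_truth, fitted_true_pattern):
        m = fitted_true_pattern
        assert m.converged
        for name, true in (("B", sparse_truth.B), ("K_zeta", sparse_truth.K_zeta),
                           ("K_between", sparse_truth.K_between)):
            est = getattr(m.params, name)
            se = m.se[name]
            free = ~np.isnan(se)
            z = np.abs(est[free] - true[free]) / se[free]
            assert z.max() < 3.0, f"{name} off by >3 SE"

    def test_null_truth_estimates_near_zero(self):
        # under a B=0 truth the largest of the 9 coefficients is a max of
        # near-Gaussian noise (SE ~ 0.033 at n=2000): typically < 0.08 and
        # never far beyond 4 SE; median over replicates is a stable check
        p = 3
        truth = GVARParameters(np.zeros((p, p)), np.eye(p), np.eye(p), np.zeros((3, p)))
        maxima = []
        for seed in (7, 8, 9):
            ds = simulate_panel(truth, 2000, seed=seed)
            m = fit_gvar(ds)
            assert m.converged
            se = standard_errors(m, ds)["B"]
            assert (np.abs(m.params.B) < 4.0 * se).all()
            maxima.append(np.abs(m.params.B).max())
        assert np.median(maxima) < 0.08

    def test_refit_from_solution_is_fixed_point(self, big_sim, fitted_true_pattern):
        again = fit_gvar(big_sim, fitted_true_pattern.pattern, fitted_true_pattern.params)
        assert again.converged
        assert again.n_iterations <= 2
        assert again.loglik == pytest.approx(fitted_true_pattern.loglik, abs=1e-6)

    def test_nonconvergence_contract_returns_flag(self, rng):
        # 4 persons cannot identify a saturated 3-item model
        ds = make_dataset(rng.normal(0, 1, (4, 3, 3)), ordinal=False)
        m = fit_gvar(ds, max_iter=5)
        assert isinstance(m, FittedModel)

    def test_requires_three_waves(self, rng):
        from panelgvar.gvar import GVARModelError
        ds = make_dataset(rng.normal(0, 1, (10, 2, 2)), ordinal=False)
        with pytest.raises(GVARModelError):
            fit_gvar(ds)


class TestStandardErrors:
    def test_mean_se_closed_form(self):
        # random-intercept-only univariate model: SE(nu_t) = sqrt(Sigma_tt / n)
        p, n = 1, 500
        truth = GVARParameters(np.zeros((p, p)), np.eye(p), np.eye(p), np.zeros((3, p)))
        ds = simulate_panel(truth, n, seed=3)
        pattern = EdgePattern(np.zeros((p, p), bool), np.eye(p, dtype=bool), np.eye(p, dtype=bool))
        m = fit_gvar(ds, pattern)
        se = standard_errors(m, ds)
        from panelgvar.gvar import implied_covariance
        Sigma, _ = implied_covariance(m.params)
        expected = np.sqrt(Sigma[0, 0] / n)
        assert se["nu"][0, 0] == pytest.approx(expected, rel=0.02)

    def test_doubling_data_shrinks_se_by_sqrt2(self, rng):
        truth = make_truth(TruthSpec(p=2, seed=5))
        ds = simulate_panel(truth, 400, seed=6)
        doubled = make_dataset(np.concatenate([ds.scores, ds.scores]), ordinal=False)
        m1 = fit_gvar(ds)
        m2 = fit_gvar(doubled)
        se1 = standard_errors(m1, ds)["B"]
        se2 = standard_errors(m2, doubled)["B"]
        np.testing.assert_allclose(se2, se1 / np.sqrt(2), rtol=0.02)

    def test_matches_parametric_bootstrap(self, fitted_true_pattern, sparse_truth, big_sim):
        # bootstrap SD of the strongest temporal coefficient vs observed-information SE
        free = np.argwhere(fitted_true_pattern.pattern.temporal)
        i, j = max(free, key=lambda ij: abs(sparse_truth.B[ij[0], ij[1]]))
        reps = 200
        ests = np.empty(reps)
        for r in range(reps):
            sim = simulate_panel(fitted_true_pattern.params, 400, seed=1000 + r)
            m = fit_gvar(sim, fitted_true_pattern.pattern, fitted_true_pattern.params)
            ests[r] = m.params.B[i, j]
        boot_sd = ests.std(ddof=1)
        # fitted at n=2000; rescale the information SE to the bootstrap's n=400
        se_400 = fitted_true_pattern.se["B"][i, j] * np.sqrt(2000 / 400)
        assert abs(boot_sd - se_400) / boot_sd < 0.10


class TestPrune:
    def test_wald_arithmetic_boundary(self):
        # z = 0.10/0.05 = 2.0 -> p ~ 0.0455, retained at alpha = 0.05
        p = _wald_p(0.10, 0.05)
        assert 0.045 < p < 0.046
        assert not p > 0.05

    def test_alpha_one_removes_nothing(self, big_sim, fitted_true_pattern):
        pruned = prune(fitted_true_pattern, big_sim, alpha=1.0)
        assert pruned.pattern.temporal.sum() == fitted_true_pattern.pattern.temporal.sum()
        assert pruned.pattern.is_subset_of(fitted_true_pattern.pattern)

    def test_detects_single_strong_edge(self):
        p = 4
        B = np.zeros((p, p))
        B[2, 1] = 0.4  # only temporal effect: item 2 driven by item 1
        truth = GVARParameters(B, np.eye(p), np.eye(p), np.zeros((3, p)))
        ds = simulate_panel(truth, 2000, seed=9)
        pruned = prune(fit_gvar(ds), ds, alpha=0.01)
        assert pruned.pattern.temporal[2, 1]
        null_cells = ~np.eye(p, dtype=bool)
        null_cells[2, 1] = False
        kept_nulls = pruned.pattern.temporal[null_cells].sum()
        assert kept_nulls <= 0.1 * null_cells.sum()

    def test_alpha_zero_removes_every_edge(self, big_sim, fitted_true_pattern):
        pruned = prune(fitted_true_pattern, big_sim, alpha=0.0)
        assert pruned.pattern.temporal.sum() == 0
        assert np.triu(pruned.pattern.contemporaneous, 1).sum() == 0
        assert np.triu(pruned.pattern.between, 1).sum() == 0
        assert np.isfinite(pruned.bic())

    def test_pattern_is_subset(self, big_sim, fitted_true_pattern):
        pruned = prune(fitted_true_pattern, big_sim, alpha=0.01)
        assert pruned.pattern.is_subset_of(fitted_true_pattern.pattern)


class TestModelSearch:
    def test_candidate_enumeration_is_lexical(self):
        pat = EdgePattern(
            np.zeros((2, 2), bool), np.ones((2, 2), bool), np.zeros((2, 2), bool))
        edges = list(_iter_candidate_edges(pat))
        assert edges == [
            ("temporal", 0, 0), ("temporal", 0, 1), ("temporal", 1, 0),
            ("temporal", 1, 1), ("between", 0, 1),
        ]

    def test_search_never_worsens_bic_and_is_deterministic(self):
        truth = make_truth(TruthSpec(p=3, temporal_density=0.2, seed=21))
        ds = simulate_panel(truth, 600, seed=22)
        pruned = prune(fit_gvar(ds), ds, alpha=0.01)
        out1 = model_search(pruned, ds, alpha=0.01)
        out2 = model_search(pruned, ds, alpha=0.01)
        assert out1.bic() <= pruned.bic() + 1e-6
        assert out1.loglik == pytest.approx(out2.loglik, abs=1e-9)
        np.testing.assert_array_equal(out1.pattern.temporal, out2.pattern.temporal)

    def test_strong_sparse_truth_is_search_stable(self):
        p = 3
        B = np.zeros((p, p)); B[1, 0] = 0.5
        truth = GVARParameters(B, np.eye(p), np.eye(p), np.zeros((3, p)))
        ds = simulate_panel(truth, 1500, seed=23)
        pruned = prune(fit_gvar(ds), ds, alpha=0.01)
        searched = model_search(pruned, ds, alpha=0.01)
        assert searched.bic() <= pruned.bic() + 1e-6
        assert searched.pattern.temporal[1, 0]


class TestFitIndices:
    def test_saturated_equivalent_model_is_perfect(self, rng):
        ds = make_dataset(rng.normal(0, 1, (50, 3, 2)), ordinal=False)
        ll_sat, k_sat = saturated_loglik(ds)
        dummy = FittedModel(
            params=None, pattern=None, loglik=ll_sat, n_params=k_sat,
            n_persons=50, se=None, converged=True, n_iterations=0)
        fi = fit_indices(dummy, ds, saturated=(ll_sat, k_sat))
        assert fi.chi2 == pytest.approx(0, abs=1e-9)
        assert fi.cfi == 1.0 and fi.tli == 1.0 and fi.rmsea == 0.0
        assert fi.rmsea_undefined

    def test_bic_formula_arithmetic(self):
        dummy = FittedModel(params=None, pattern=None, loglik=-100.0, n_params=5,
                            n_persons=100, se=None, converged=True, n_iterations=0)
        assert dummy.bic() == pytest.approx(200 + 5 * np.log(100), abs=1e-10)
        assert dummy.bic() == pytest.approx(223.03, abs=0.01)

    def test_hand_evaluated_index_formulas(self):
        cfi, tli, rmsea = indices_from_chi2(50.0, 40, 500.0, 60, 500)
        assert cfi == pytest.approx(1 - 10 / 440, abs=1e-12)
        assert tli == pytest.approx(((500 / 60) - (50 / 40)) / ((500 / 60) - 1), abs=1e-12)
        assert rmsea == pytest.approx(np.sqrt(10 / (40 * 499)), abs=1e-12)
        assert rmsea == pytest.approx(0.0224, abs=5e-4)

    def test_correct_specification_fits_well(self, big_sim, fitted_true_pattern):
        fi = fit_indices(fitted_true_pattern, big_sim)
        assert fi.cfi > 0.99
        assert fi.rmsea < 0.02

    def test_em_saturated_matches_dense_on_complete_data(self, rng):
        ds = make_dataset(rng.normal(0, 1, (40, 3, 2)), ordinal=False)
        ll, k = saturated_loglik(ds)
        Y = ds.scores.reshape(40, -1)
        mu = Y.mean(axis=0)
        S = np.cov(Y.T, ddof=0)
        from scipy.stats import multivariate_normal
        dense = multivariate_normal(mu, S, allow_singular=True).logpdf(Y).sum()
        assert ll == pytest.approx(dense, abs=1e-8)
        assert k == 6 + 21

    def test_em_saturated_beats_any_structured_model(self, rng):
        scores = rng.normal(0, 1, (80, 3, 2))
        mask = rng.random((80, 3, 2)) < 0.25
        scores[mask] = np.nan
        ds = make_dataset(scores, mask, ordinal=False)
        ll_sat, _ = saturated_loglik(ds)
        m = fit_gvar(ds)
        assert ll_sat >= m.loglik - 1e-6


class TestCompareBic:
    def test_identical_models_tie(self, fitted_true_pattern, big_sim):
        out = compare_bic(fitted_true_pattern, fitted_true_pattern)
        assert out.delta == 0.0
        assert out.favored == "tie"

    def test_one_parameter_penalty(self):
        m1 = FittedModel(params=None, pattern=None, loglik=-500.0, n_params=10,
                         n_persons=869, se=None, converged=True, n_iterations=0)
        m2 = FittedModel(params=None, pattern=None, loglik=-500.0, n_params=11,
                         n_persons=869, se=None, converged=True, n_iterations=0)
        out = compare_bic(m1, m2)
        assert abs(out.delta) == pytest.approx(np.log(869), abs=1e-10)
        assert out.favored == "m1"

    def test_pruned_favored_on_sparse_truth(self):
        truth = make_truth(TruthSpec(p=3, temporal_density=0.15, seed=31))
        ds = simulate_panel(truth, 800, seed=32)
        sat = fit_gvar(ds)
        pruned = prune(sat, ds, alpha=0.01)
        out = compare_bic(sat, pruned)
        assert out.delta > 0  # pruned (m2) wins

    def test_nested_loglik_ordering(self):
        truth = make_truth(TruthSpec(p=3, temporal_density=0.2, seed=33))
        ds = simulate_panel(truth, 600, seed=34)
        sat = fit_gvar(ds)
        pruned = prune(sat, ds, alpha=0.01)
        searched = model_search(pruned, ds, alpha=0.01)
        assert sat.loglik >= searched.loglik - 1e-6
        assert searched.loglik >= pruned.loglik - 1e-6
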