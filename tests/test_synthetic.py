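"""Ground-truth construction, simulation, ordinalization, attrition."""

import numpy as np
import pytest
from scipy import stats

from panelgvar.descriptives import attrition_comparison
from panelgvar.gvar import implied_covariance, spectral_radius
from panelgvar.panel_data import screen_variance
from panelgvar.synthetic import (
    AttritionSpec,
    TruthSpec,
    _categorical_moments,
    apply_attrition,
    calibrate_thresholds,
    feasible_sd_interval,
    lin_preset,
    make_truth,
    ordinalize,
    simulate_panel,
)


class TestMakeTruth:
    def test_zero_density_gives_diagonal_matrices(self):
        t = make_truth(TruthSpec(p=4, temporal_density=0, contemporaneous_density=0,
                                 between_density=0, seed=1))
        for M in (t.B, t.K_zeta, t.K_between):
            assert np.allclose(M, np.diag(np.diag(M)))

    def test_spectral_radius_hits_target(self):
        spec = TruthSpec(p=5, temporal_density=0.3, target_spectral_radius=0.62, seed=2)
        t = make_truth(spec)
        assert spectral_radius(t.B) == pytest.approx(0.62, abs=1e-6)

    def test_same_seed_identical(self):
        a = make_truth(TruthSpec(seed=9))
        b = make_truth(TruthSpec(seed=9))
        np.testing.assert_array_equal(a.B, b.B)
        np.testing.assert_array_equal(a.K_zeta, b.K_zeta)

    def test_precisions_positive_definite(self):
        for seed in range(5):
            t = make_truth(TruthSpec(p=8, contemporaneous_density=0.5,
                                     between_density=0.5, seed=seed))
            assert np.linalg.eigvalsh(t.K_zeta).min() > 0
            assert np.linalg.eigvalsh(t.K_between).min() > 0


class TestSimulatePanel:
    def test_independent_waves_when_dynamics_vanish(self):
        p = 2
        from panelgvar.gvar import GVARParameters
        params = GVARParameters(np.zeros((p, p)), np.eye(p), np.eye(p) * 1e8,
                                np.zeros((3, p)))
        ds = simulate_panel(params, 100_000, seed=3)
        lag = np.mean(ds.scores[:, 0, 0] * ds.scores[:, 1, 0])
        assert abs(lag) < 0.02

    def test_wave_invariant_moments(self):
        truth = make_truth(TruthSpec(p=3, seed=4))
        ds = simulate_panel(truth, 100_000, seed=5)
        means = ds.scores.mean(axis=0)
        sds = ds.scores.std(axis=0)
        assert np.abs(means).max() < 0.02
        assert np.abs(sds - sds[0]).max() < 0.02


class TestOrdinalize:
    def test_threshold_counting(self):
        scores = np.array([[[1.5]]])
        from conftest import make_dataset
        ds = make_dataset(scores, ordinal=False)
        out = ordinalize(ds, np.array([[0.0, 1.0, 2.0]]))
        assert out.scores[0, 0, 0] == 2.0

    def test_huge_thresholds_give_all_zeros(self, rng):
        from conftest import make_dataset
        ds = make_dataset(rng.normal(0, 1, (50, 3, 2)), ordinal=False)
        out = ordinalize(ds, np.full((2, 3), [1e6, 2e6, 3e6]))
        assert (out.scores == 0).all()

    def test_quantile_thresholds_reproduce_category_shares(self, rng):
        from conftest import make_dataset
        probs = np.array([0.55, 0.38, 0.06, 0.01])
        cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
        ds = make_dataset(rng.normal(0, 1, (100_000, 1, 1)), ordinal=False,
                          wave_labels=("T1",))
        out = ordinalize(ds, cuts[None, :])
        shares = np.bincount(out.scores.astype(int).ravel(), minlength=4) / 100_000
        np.testing.assert_allclose(shares, probs, atol=0.01)

    def test_nonascending_thresholds_rejected(self, rng):
        from conftest import make_dataset
        ds = make_dataset(rng.normal(0, 1, (5, 3, 1)), ordinal=False)
        with pytest.raises(ValueError):
            ordinalize(ds, np.array([[1.0, 0.5, 2.0]]))


class TestCalibrateThresholds:
    @pytest.mark.parametrize("mean,sd", [(0.532, 0.720), (0.114, 0.371), (0.012, 0.135)])
    def test_printed_item_targets_matched(self, mean, sd):
        u = calibrate_thresholds(mean, sd)
        got_mean, got_sd = _categorical_moments(u)
        assert got_mean == pytest.approx(mean, abs=0.01)
        assert got_sd == pytest.approx(sd, abs=0.01)

    def test_simulated_item_mean_matches_target(self, rng):
        u = calibrate_thresholds(0.532, 0.720)
        z = rng.normal(0, 1, 100_000)
        cats = (z[:, None] > u).sum(axis=1)
        assert cats.mean() == pytest.approx(0.532, abs=0.02)

    def test_latent_sd_scaling(self):
        u1 = calibrate_thresholds(0.5, 0.7, latent_sd=1.0)
        u2 = calibrate_thresholds(0.5, 0.7, latent_sd=2.0)
        np.testing.assert_allclose(u2, 2 * u1, atol=1e-6)

    def test_zero_mean_infeasible(self):
        with pytest.raises(ValueError):
            calibrate_thresholds(0.0, 0.5)

    def test_infeasible_sd_reports_interval(self):
        lo, hi = feasible_sd_interval(1.5)
        with pytest.raises(ValueError, match="feasible interval"):
            calibrate_thresholds(1.5, hi + 0.5)

    def test_mean_only_fallback(self):
        u = calibrate_thresholds(1.5, 10.0, on_infeasible_sd="mean_only")
        mean, _ = _categorical_moments(u)
        assert mean == pytest.approx(1.5, abs=1e-6)

    def test_maximal_sd_approaches_two_point_mixture(self):
        # near the SD boundary mass concentrates on the extreme categories
        lo, hi = feasible_sd_interval(1.5)
        u = calibrate_thresholds(1.5, hi - 0.02)
        cdf = stats.norm.cdf(u)
        probs = np.diff(np.concatenate([[0], cdf, [1]]))
        assert probs[0] + probs[3] > 0.9


class TestApplyAttrition:
    def _ds(self, rng, n=4000):
        from conftest import make_dataset
        return make_dataset(rng.integers(0, 4, (n, 3, 5)).astype(float))

    def test_rate_without_slope(self, rng):
        ds = apply_attrition(self._ds(rng), AttritionSpec(base_rate=0.1, slope=0.0), seed=1)
        at2 = ds.observed_at_wave(1).mean()
        assert at2 == pytest.approx(0.9, abs=0.02)

    def test_no_attrition_configuration(self, rng):
        ds0 = self._ds(rng)
        out = apply_attrition(ds0, AttritionSpec(base_rate=0.0, slope=0.0), seed=1)
        assert not out.missing_mask.any()

    def test_monotone_missingness(self, rng):
        out = apply_attrition(self._ds(rng), AttritionSpec(base_rate=0.2, slope=0.1), seed=2)
        obs = ~out.missing_mask.any(axis=2) & ~out.missing_mask.all(axis=2)
        present = (~out.missing_mask).any(axis=2)
        for person in range(out.n_persons):
            w = present[person]
            # once absent, absent forever
            assert all(w[t] or not w[t + 1] for t in range(2))

    def test_positive_slope_selects_high_scorers(self, rng):
        ds = apply_attrition(self._ds(rng), AttritionSpec(base_rate=0.1, slope=0.3), seed=3)
        res = attrition_comparison(ds, 0, 2)
        assert res.t < 0
        assert res.mean_dropouts > res.mean_completers


@pytest.fixture(scope="module")
def study():
    return lin_preset("mothers", seed=17)


class TestLinPreset:
    def test_default_sample_size_and_shape(self, study):
        assert study.dataset.n_persons == 869
        assert study.dataset.n_waves == 3
        assert study.dataset.n_items == 10

    def test_screening_excludes_only_the_near_constant_item(self, study):
        _, excluded = screen_variance(study.dataset, 0.95)
        assert excluded == ["EPDS10"]

    def test_item_means_near_printed_targets(self, study):
        from panelgvar.synthetic import LIN_T1_MOMENTS
        t1 = study.dataset.scores[:, 0, :]
        means = np.nanmean(t1, axis=0)
        targets = np.array([m for m, _ in LIN_T1_MOMENTS["mothers"]])
        assert np.abs(means - targets).max() < 0.08

    def test_dropout_direction_matches_mechanism(self, study):
        res = attrition_comparison(study.dataset, 0, 2)
        assert res.t < 0

    def test_reproducible(self):
        a = lin_preset("fathers", n_persons=100, seed=5)
        b = lin_preset("fathers", n_persons=100, seed=5)
        np.testing.assert_array_equal(a.dataset.missing_mask, b.dataset.missing_mask)
        np.testing.assert_array_equal(
            a.dataset.scores[~a.dataset.missing_mask],
            b.dataset.scores[~b.dataset.missing_mask])
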