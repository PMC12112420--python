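"""Estimators: identity readout, closed-form inversion, reliability algebra,
censored-normal fits, hierarchical joint estimation, distance trend."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from lambdaslider.estimation import (
    CensoredMvnLikelihood,
    estimate_sigma_from_repeats,
    fit_censored_mvnormal,
    fit_distance_trend,
    fit_hierarchical_lambda_kappa,
    lambda_readout,
    point_estimate_lambda_kappa,
    reliability_of_average,
)
from lambdaslider.respondent import NoiseModel, Preference, simulate_response
from lambdaslider.synthetic_data import (
    KappaMixture,
    generate_panel,
    inequity_panel_config,
    reliability_panel_config,
)


class TestLambdaReadout:
    def test_interior_identity(self, standard):
        r = simulate_response(standard, Preference(0.4), noise=NoiseModel(0.0), rng=0)
        out = lambda_readout(standard, r)
        assert out.estimate == 0.4 and not out.censored

    def test_bound_is_one_sided(self, standard):
        r = simulate_response(standard, Preference(3.0), noise=NoiseModel(0.0), rng=0)
        out = lambda_readout(standard, r)
        assert out.estimate == 2.0 and out.censored and out.bound_side == "upper"

    def test_roundtrip_recovers_lambda_exactly(self, standard, rng):
        for lam in rng.uniform(-1.99, 1.99, 50):
            r = simulate_response(standard, Preference(lam), noise=NoiseModel(0.0), rng=rng)
            assert lambda_readout(standard, r).estimate == pytest.approx(lam, abs=1e-12)

    def test_mismatched_slider_rejected(self, sliders):
        r = simulate_response(sliders["standard"], Preference(0.0), noise=NoiseModel(0.0), rng=0)
        with pytest.raises(ValueError):
            lambda_readout(sliders["balanced"], r)


class TestPointEstimate:
    def test_worked_inversion(self):
        # forward: lam=0.5, kappa=0.25 gives x1=1.0, x2=0.2
        est = point_estimate_lambda_kappa(1.0, 0.2)
        assert est.lam == pytest.approx(0.5) and est.kappa == pytest.approx(0.25)

    def test_equal_positions_mean_no_inequity(self):
        est = point_estimate_lambda_kappa(0.7, 0.7)
        assert est.lam == pytest.approx(0.7) and est.kappa == pytest.approx(0.0)

    def test_fallback_to_average(self):
        est = point_estimate_lambda_kappa(0.1, 0.4)
        assert est.fallback and est.lam == pytest.approx(0.25) and est.kappa is None

    def test_degenerate_sum(self):
        with pytest.raises(ValueError):
            point_estimate_lambda_kappa(-1.0, -1.0)

    def test_roundtrip_exact_on_grid(self):
        """Forward optima -> inversion recovers (lam, kappa) to 1e-12
        wherever the branch-feasibility condition holds."""
        checked = 0
        for lam in np.arange(-1.9, 1.91, 0.1):
            for kappa in np.arange(0.0, 0.91, 0.1):
                x1 = (lam + kappa) / (1 - kappa)
                x2 = (lam - kappa) / (1 + kappa)
                if not ((x1 >= x2 > -1) or (x1 <= x2 < -1)):
                    continue
                if abs(2 + x1 + x2) < 1e-9:  # lam = -1 is degenerate
                    continue
                est = point_estimate_lambda_kappa(x1, x2)
                assert not est.fallback
                assert est.lam == pytest.approx(lam, abs=1e-12)
                assert est.kappa == pytest.approx(kappa, abs=1e-12)
                checked += 1
        assert checked > 200


class TestReliability:
    def test_published_value(self):
        assert reliability_of_average(0.858, 3) == pytest.approx(0.948, abs=5e-4)

    def test_single_measurement_identity(self):
        assert reliability_of_average(0.3, 1) == pytest.approx(0.3)

    def test_odds_doubling(self):
        assert reliability_of_average(0.5, 2) == pytest.approx(2 / 3)

    def test_monotone_and_limits(self):
        rhos = np.linspace(0.05, 0.95, 10)
        vals = [reliability_of_average(r, 3) for r in rhos]
        assert np.all(np.diff(vals) > 0)
        ns = [1, 2, 4, 8, 16]
        vals_n = [reliability_of_average(0.4, n) for n in ns]
        assert np.all(np.diff(vals_n) > 0)
        assert reliability_of_average(0.4, 10_000) > 0.999

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.2, 1.3])
    def test_domain(self, rho):
        with pytest.raises(ValueError):
            reliability_of_average(rho, 3)


def _bivariate_clipped(seed, n=300, rho=0.86, sd=1.11, mean=0.19, bound=2.0):
    rng = np.random.default_rng(seed)
    cov = sd * sd * np.array([[1, rho], [rho, 1]])
    x = rng.multivariate_normal([mean, mean], cov, size=n)
    return np.clip(x, -bound, bound)


class TestCensoredMvnFit:
    def test_recovers_correlation_without_censoring(self):
        rng = np.random.default_rng(3)
        x = rng.multivariate_normal([0, 0], [[1, 0.86], [0.86, 1]], size=300)
        fit = fit_censored_mvnormal(x, seed=0, n_steps=600)
        med, lo, hi = fit.corr_entry(0, 1)
        naive = np.corrcoef(x.T)[0, 1]
        assert lo <= naive <= hi
        assert abs(med - 0.86) <= (hi - lo)

    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 60)
        x = np.column_stack([a, a + 1e-6 * rng.normal(size=60)])
        fit = fit_censored_mvnormal(x, seed=0, n_steps=500)
        assert fit.corr_entry(0, 1)[0] > 0.99

    def test_censoring_correction_beats_naive_estimate(self):
        # clip hard enough that ~20% of rows touch a bound
        x = _bivariate_clipped(5, rho=0.85, bound=1.6)
        assert np.mean((np.abs(x) >= 1.6).any(axis=1)) > 0.15
        fit = fit_censored_mvnormal(x, [(-1.6, 1.6)] * 2, seed=0, n_steps=700)
        naive = np.corrcoef(x.T)[0, 1]
        assert abs(fit.corr_entry(0, 1)[0] - 0.85) < abs(naive - 0.85)

    def test_all_censored_variable_inestimable(self):
        x = _bivariate_clipped(6)
        x[:, 1] = 2.0
        with pytest.raises(ValueError):
            fit_censored_mvnormal(x, [(-2, 2), (-2, 2)])

    def test_too_few_complete_rows(self):
        x = np.full((8, 2), 0.5)
        with pytest.raises(ValueError):
            fit_censored_mvnormal(x, [(-2, 2), (-2, 2)])

    def test_batched_likelihood_matches_scalar(self):
        x = _bivariate_clipped(7)
        lik = CensoredMvnLikelihood(x, [(-2, 2), (-2, 2)])
        rng = np.random.default_rng(0)
        mus = rng.normal(0, 0.3, (5, 2))
        covs = np.array([np.eye(2) + 0.5 * np.ones((2, 2)) * u for u in rng.uniform(0.1, 0.9, 5)])
        batch = lik.log_likelihood_many(mus, covs)
        scalar = [lik.log_likelihood(mus[i], covs[i]) for i in range(5)]
        assert batch == pytest.approx(scalar, rel=1e-9)


def _small_inequity_config(seed, **kw):
    cfg = inequity_panel_config(seed=seed)
    return replace(
        cfg,
        n_participants=kw.get("n_participants", 12),
        n_targets=3,
        rank_means=(0.8, 0.1, -0.6),
        **{k: v for k, v in kw.items() if k != "n_participants"},
    )


class TestHierarchicalFit:
    def test_noiseless_lambdas_recovered(self, sliders):
        cfg = _small_inequity_config(0, noise=NoiseModel(sigma_e=0.0))
        panel = generate_panel(cfg)
        fit = fit_hierarchical_lambda_kappa(panel.responses, sliders)
        # the likelihood peaks at the truth where optima are interior; a
        # high-kappa respondent is pushed past the bounds of the offset
        # sliders and is then only partially identified, so restrict to
        # participant-targets whose responses are all uncensored
        fully_observed = (
            panel.responses.groupby(["participant_id", "target_id"])["censored"]
            .any()
            .loc[lambda s: ~s]
            .index
        )
        merged = panel.truth.merge(fit.lam, on=["participant_id", "target_id"])
        merged = merged.set_index(["participant_id", "target_id"]).loc[fully_observed]
        assert len(merged) >= 10
        err = np.abs(merged["median"] - merged["lam"])
        assert err.max() < 0.02

    def test_null_kappa_panel(self, sliders):
        cfg = _small_inequity_config(1, kappa_distribution=KappaMixture(point_weight=1.0))
        panel = generate_panel(cfg)
        fit = fit_hierarchical_lambda_kappa(panel.responses, sliders)
        # with no true inequity aversion, nearly all intervals reach below 0.1
        frac = np.mean(fit.kappa["lo"] < 0.1)
        assert frac >= 0.95

    def test_single_slider_not_identifiable(self, sliders):
        cfg = _small_inequity_config(2)
        cfg = replace(cfg, sliders=(sliders["balanced"],))
        panel = generate_panel(cfg)
        with pytest.raises(ValueError):
            fit_hierarchical_lambda_kappa(panel.responses, sliders)

    def test_sigma_estimated_from_repeats(self, sliders):
        cfg = _small_inequity_config(3, noise=NoiseModel(sigma_e=0.25))
        panel = generate_panel(cfg)
        est = estimate_sigma_from_repeats(panel.responses)
        assert est == pytest.approx(0.25, abs=0.06)


class TestDistanceTrend:
    def test_recovers_generating_decline(self):
        panel = generate_panel(reliability_panel_config(seed=3))
        true_slope = np.diff(panel.config.rank_means).mean()
        fit = fit_distance_trend(panel.responses, "position", bounds=(-2, 2), seed=0, n_steps=1200)
        assert fit.b3_lo <= true_slope <= fit.b3_hi
        assert fit.b3 < 0
        assert np.all(np.diff(fit.rank_means) <= 1e-9)  # monotone nonincreasing

    def test_flat_panel_slope_near_zero(self):
        cfg = replace(reliability_panel_config(seed=0), rank_means=tuple([0.0] * 10))
        panel = generate_panel(cfg)
        fit = fit_distance_trend(panel.responses, "position", bounds=(-2, 2), seed=0, n_steps=1200)
        assert fit.b3_lo <= 0.0 <= fit.b3_hi

    def test_needs_three_ranks(self):
        df = pd.DataFrame(
            {
                "participant_id": ["p0"] * 4,
                "target_rank": [1, 1, 2, 2],
                "position": [0.1, 0.2, 0.0, 0.1],
            }
        )
        with pytest.raises(ValueError):
            fit_distance_trend(df, "position")
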