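"""Joined two-segment changepoint models: structure, recovery, oracle."""

import numpy as np
import pytest

from owlprov import synthetic
from owlprov.changepoint import (
    DeliveryFitResult,
    PiecewiseRateParams,
    changepoint_profile_oracle,
    fit_changepoint_counts,
    fit_delivery_changepoint,
    fit_growth_hierarchical,
    piecewise_log_rate,
    rate_curve_summaries,
)
from owlprov.mcmc import ChainConfig, ParamSummary, PosteriorSummary

DRY_NIGHT = PiecewiseRateParams(37.85, 0.05, -0.02, delta2=90.0)


class TestPiecewiseLogRate:
    def test_zero_at_origin(self):
        assert piecewise_log_rate(0.0, DRY_NIGHT) == 0.0

    def test_hand_value_at_60_min(self):
        # dry-year nightly posterior means: 0.05*37.85 - 0.02*(60-37.85)
        assert piecewise_log_rate(60.0, DRY_NIGHT) == pytest.approx(1.4495)

    def test_continuous_at_changepoint(self):
        eps = 1e-9
        left = piecewise_log_rate(DRY_NIGHT.delta1 - eps, DRY_NIGHT)
        at = piecewise_log_rate(DRY_NIGHT.delta1, DRY_NIGHT)
        right = piecewise_log_rate(DRY_NIGHT.delta1 + eps, DRY_NIGHT)
        assert at == pytest.approx(left, abs=1e-9)
        assert at == pytest.approx(right, abs=1e-9)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            piecewise_log_rate(95.0, DRY_NIGHT)
        with pytest.raises(ValueError):
            piecewise_log_rate(-1.0, DRY_NIGHT)

    def test_param_ordering_enforced(self):
        with pytest.raises(ValueError):
            PiecewiseRateParams(50.0, 0.1, 0.1, delta2=40.0)


class TestDeliveryFit:
    def test_parameter_recovery_single_replicate(self, truth, standard_chains):
        obs = synthetic.gen_delivery_dataset(
            truth, "dry", axis="night", rng=np.random.default_rng(42))
        fit = fit_delivery_changepoint(obs, "minutes_after_sunset",
                                       standard_chains)
        for name, true in (("delta1", 37.85), ("beta1", 0.05), ("beta2", -0.02)):
            lo, hi = fit.posterior.cri(name)
            assert lo <= true <= hi, f"{name}: truth {true} outside ({lo}, {hi})"
        assert fit.posterior.converged

    def test_no_changepoint_data_slopes_agree(self, rng, standard_chains):
        # single log-linear trend: the two segment slopes straddle each other
        x = rng.uniform(0, 90, 600)
        y = rng.poisson(np.exp(0.02 * x))
        fit = fit_changepoint_counts(x, y, standard_chains)
        from owlprov.mcmc import intervals_overlap
        assert intervals_overlap(fit.posterior.cri("beta1"),
                                 fit.posterior.cri("beta2"))

    def test_null_constant_counts(self, quick_chains):
        x = np.tile(np.arange(1.0, 91.0, 3.0), 4)
        y = np.ones_like(x)
        fit = fit_changepoint_counts(x, y, quick_chains)
        for name in ("beta1", "beta2"):
            lo, hi = fit.posterior.cri(name)
            assert lo <= 0.0 <= hi

    def test_expected_count_exactly_one_at_origin_every_draw(self, truth,
                                                             quick_chains):
        obs = synthetic.gen_delivery_dataset(
            truth, "dry", axis="night", rng=np.random.default_rng(1),
            n_nests=20)
        fit = fit_delivery_changepoint(obs, "minutes_after_sunset", quick_chains)
        post = fit.posterior
        for d1, b1, b2 in zip(post.flat("delta1")[::40], post.flat("beta1")[::40],
                              post.flat("beta2")[::40]):
            p = PiecewiseRateParams(d1, b1, b2, delta2=90.0)
            assert np.exp(piecewise_log_rate(0.0, p)) == 1.0

    def test_fitted_curve_continuous_at_changepoint_every_draw(
            self, truth, quick_chains):
        obs = synthetic.gen_delivery_dataset(
            truth, "dry", axis="night", rng=np.random.default_rng(2),
            n_nests=20)
        fit = fit_delivery_changepoint(obs, "minutes_after_sunset", quick_chains)
        post = fit.posterior
        for d1, b1, b2 in zip(post.flat("delta1")[::40], post.flat("beta1")[::40],
                              post.flat("beta2")[::40]):
            p = PiecewiseRateParams(d1, b1, b2, delta2=90.0)
            gap = (piecewise_log_rate(min(d1 + 1e-12, 90.0), p)
                   - piecewise_log_rate(d1, p))
            assert abs(gap) < 1e-10

    def test_preconditions(self, quick_chains):
        with pytest.raises(ValueError):
            fit_changepoint_counts([1.0] * 12, [1] * 12, quick_chains)
        with pytest.raises(ValueError):
            fit_changepoint_counts(np.arange(5.0), np.ones(5), quick_chains)
        with pytest.raises(ValueError):
            fit_delivery_changepoint([], "elevation", quick_chains)


def _fake_result(d1, b1, b2, x_max=90.0, n=50):
    """A DeliveryFitResult with constant posterior draws, for functional
    summaries whose expected values are known in closed form."""
    draws = {"delta1": np.full((2, n), d1), "beta1": np.full((2, n), b1),
             "beta2": np.full((2, n), b2)}
    params = {k: ParamSummary(float(v[0, 0]), float(v[0, 0]), float(v[0, 0]), 1.0)
              for k, v in draws.items()}
    x = np.linspace(0, x_max, 30)
    return DeliveryFitResult(
        posterior=PosteriorSummary(params=params, draws=draws),
        x=x, y=np.ones_like(x), x_axis="x")


class TestRateCurveSummaries:
    def test_zero_slopes_give_unit_rates(self):
        out = rate_curve_summaries(_fake_result(45.0, 0.0, 0.0))
        for k in ("mean", "min", "max"):
            assert out[k].mean == pytest.approx(1.0)
            assert out[k].cri == (1.0, 1.0)

    def test_monotone_curve_max_at_grid_end(self):
        grid = np.linspace(0, 90, 10)
        out = rate_curve_summaries(_fake_result(90.0, 0.02, 0.0), x_grid=grid)
        assert out["max"].mean == pytest.approx(np.exp(0.02 * 90))
        assert out["min"].mean == pytest.approx(1.0)

    def test_analytic_functionals_at_truth(self):
        # min of the dry nightly curve over a grid including 0 is exactly 1
        grid = np.linspace(0, 90, 91)
        out = rate_curve_summaries(
            _fake_result(37.85, 0.05, -0.02), x_grid=grid)
        curve = np.exp([piecewise_log_rate(g, DRY_NIGHT) for g in grid])
        assert out["mean"].mean == pytest.approx(curve.mean())
        assert out["min"].mean == pytest.approx(curve.min())
        assert out["max"].mean == pytest.approx(curve.max())

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            rate_curve_summaries(_fake_result(45.0, 0.0, 0.0), x_grid=[])


class TestProfileOracle:
    def test_single_point_grid(self, truth):
        obs = synthetic.gen_delivery_dataset(
            truth, "dry", axis="night", rng=np.random.default_rng(3),
            n_nests=30)
        x = np.array([o.minutes_after_sunset for o in obs])
        y = np.array([o.n_total for o in obs])
        d1, b1, b2 = changepoint_profile_oracle(x, y, [40.0])
        assert d1 == 40.0 and np.isfinite(b1) and np.isfinite(b2)

    def test_flat_likelihood_ties_break_to_smallest(self, rng):
        # pure single-slope truth: the changepoint is unidentified and the
        # profile is flat, so the smallest grid value is returned
        x = np.concatenate([np.arange(1.0, 91.0)] * 8)
        y = np.exp(0.02 * x)  # deterministic "counts" on the exact line
        d1, b1, b2 = changepoint_profile_oracle(x, y, [20.0, 40.0, 60.0])
        assert d1 == 20.0
        assert b1 == pytest.approx(0.02, abs=1e-4)

    def test_grid_outside_data_rejected(self, rng):
        x = rng.uniform(0, 90, 50)
        with pytest.raises(ValueError):
            changepoint_profile_oracle(x, np.ones(50), [200.0])


class TestGrowthHierarchical:
    def test_degenerate_identical_nestlings(self, truth):
        # identical deterministic curves, tiny noise: estimates collapse
        t = synthetic.default_truth(growth=synthetic.GrowthTruth(
            sd_alpha=1e-6, sd_b1=1e-6, sd_b2=1e-6, sd_delta=1e-6,
            sigma_resid=0.05))
        masses = synthetic.gen_growth_and_mass(
            t, rng=np.random.default_rng(8), n_nestlings=8,
            n_adult_females=0, n_adult_males=0)
        fit = fit_growth_hierarchical(masses, ChainConfig(2000, 900, seed=4))
        g = t.growth
        assert fit.posterior["mu_alpha"].mean == pytest.approx(g.mu_alpha, abs=0.3)
        assert fit.posterior["mu_b1"].mean == pytest.approx(g.mu_b1, abs=0.1)
        assert fit.posterior["mu_b2"].mean == pytest.approx(g.mu_b2, abs=0.15)
        assert fit.posterior["mu_delta"].mean == pytest.approx(g.mu_delta, abs=0.5)

    def test_underdetermined_nestlings_excluded(self, truth, quick_chains):
        masses = synthetic.gen_growth_and_mass(
            truth, rng=np.random.default_rng(9), n_nestlings=6,
            n_adult_females=0, n_adult_males=0)
        # an owlet weighed only once cannot inform slopes
        lone = masses[0]
        from dataclasses import replace
        masses.append(replace(lone, band_id="LONE01"))
        fit = fit_growth_hierarchical(masses, quick_chains)
        assert "LONE01" in fit.excluded
        assert "LONE01" not in fit.bands

    def test_too_few_nestlings_rejected(self, truth, quick_chains):
        masses = synthetic.gen_growth_and_mass(
            truth, rng=np.random.default_rng(10), n_nestlings=3,
            n_adult_females=0, n_adult_males=0)
        with pytest.raises(ValueError):
            fit_growth_hierarchical(masses, quick_chains)
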