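"""Synthetic-study generators: round trips, consistency, determinism."""

import numpy as np
import pytest

from owlprov import synthetic
from owlprov.io_data import attribute_sex, filter_observations
from owlprov.weather import aggregate_owl_year


class TestWeatherGenerator:
    def test_hourly_roundtrip_reproduces_annual_values(self, truth):
        years, hourly = synthetic.gen_weather_years(
            synthetic.default_truth(n_years=3))
        for y in years:
            agg = aggregate_owl_year(hourly, y.year_label)
            assert agg.total_precip_mm == pytest.approx(
                y.total_precip_mm, abs=1e-6)
            assert agg.mean_daily_min_temp_c == pytest.approx(
                y.mean_daily_min_temp_c, abs=1e-9)

    def test_large_sample_correlation(self):
        t = synthetic.default_truth(n_years=10_000)
        years, _ = synthetic.gen_weather_years(t, expand_hourly=False)
        p = [y.total_precip_mm for y in years]
        m = [y.mean_daily_min_temp_c for y in years]
        assert np.corrcoef(p, m)[0, 1] == pytest.approx(0.67, abs=0.02)

    def test_zero_correlation(self):
        t = synthetic.default_truth(n_years=4000, precip_temp_corr=0.0)
        years, _ = synthetic.gen_weather_years(t, expand_hourly=False)
        p = [y.total_precip_mm for y in years]
        m = [y.mean_daily_min_temp_c for y in years]
        assert abs(np.corrcoef(p, m)[0, 1]) < 0.05


class TestDeliveryGenerator:
    def test_attribution_cues_reproduce_counts(self, truth):
        obs, events = synthetic.gen_delivery_dataset(
            truth, "dry", rng=np.random.default_rng(4), n_nests=15,
            return_events=True)
        counts = {i: {"male": 0, "female": 0, "unknown": 0}
                  for i in range(len(obs))}
        for i, cues in events:
            counts[i][attribute_sex(cues)] += 1
        for i, o in enumerate(obs):
            assert counts[i] == {"male": o.n_male, "female": o.n_female,
                                 "unknown": o.n_unknown}

    def test_totals_match_event_count(self, truth):
        obs, events = synthetic.gen_delivery_dataset(
            truth, "wet", rng=np.random.default_rng(5), n_nests=15,
            return_events=True)
        assert sum(o.n_total for o in obs) == len(events)

    def test_all_intervals_pass_protocol_filters(self, truth):
        obs = synthetic.gen_delivery_dataset(
            truth, "cold", rng=np.random.default_rng(6), n_nests=10)
        res = filter_observations(obs)
        assert len(res) == len(obs)

    def test_zero_unknown_fraction(self):
        t = synthetic.default_truth(unknown_frac=0.0)
        obs = synthetic.gen_delivery_dataset(
            t, "dry", rng=np.random.default_rng(7), n_nests=10)
        assert all(o.n_unknown == 0 for o in obs)

    def test_unit_rate_at_sunset(self):
        # force every watch to start at sunset: expected count is e^0 = 1
        t = synthetic.default_truth()
        obs = synthetic.gen_delivery_dataset(
            t, "dry", rng=np.random.default_rng(8), n_nests=400,
            intervals_per_nest=5)
        early = [o.n_total for o in obs if o.minutes_after_sunset < 4]
        # E[count] at x<4 is between 1 and e^{0.2}; a loose sanity band
        assert 0.8 < np.mean(early) < 1.4


class TestMassGenerator:
    def test_near_deterministic_growth_on_the_curve(self):
        g = synthetic.GrowthTruth(sd_alpha=0.0, sd_b1=0.0, sd_b2=0.0,
                                  sd_delta=0.0, sigma_resid=1e-9)
        t = synthetic.default_truth(growth=g)
        masses = synthetic.gen_growth_and_mass(
            t, rng=np.random.default_rng(9), n_nestlings=4,
            n_adult_females=0, n_adult_males=0)
        for m in masses:
            age = m.nestling_age_days
            expect = (g.mu_alpha + g.mu_b1 * min(age, g.mu_delta)
                      + (g.mu_b2 * (age - g.mu_delta) if age > g.mu_delta
                         else 0.0))
            assert m.mass_g == pytest.approx(expect, abs=1e-6)

    def test_cohort_structure(self, truth):
        masses = synthetic.gen_growth_and_mass(
            truth, rng=np.random.default_rng(10), n_nestlings=5,
            n_adult_females=4, n_adult_males=3)
        cohorts = {m.cohort for m in masses}
        assert cohorts == {"nestling", "adult_female", "adult_male"}
        for m in masses:
            assert (m.nestling_age_days is not None) == (m.cohort == "nestling")
            assert m.mass_g > 0


class TestProductivityGenerator:
    def test_certain_survival_collapses_stages(self):
        t = synthetic.default_truth(p_hatch=1.0, p_fledge=1.0,
                                    fledgling_log_effect=0.0)
        nests, _ = synthetic.gen_productivity(
            t, rng=np.random.default_rng(11), n_per_category=50)
        assert all(n.clutch == n.brood == n.fledglings for n in nests)

    def test_clutch_support_and_mean(self):
        nests, _ = synthetic.gen_productivity(
            synthetic.default_truth(), rng=np.random.default_rng(12),
            n_per_category=1000)
        clutches = np.array([n.clutch for n in nests])
        assert clutches.min() >= 1 and clutches.max() <= 4
        # truncated-Poisson(3.5) on {1..4} has mean ~2.70
        assert clutches.mean() == pytest.approx(2.70, abs=0.06)

    def test_indicator_map_complete(self):
        nests, ind = synthetic.gen_productivity(
            synthetic.default_truth(), rng=np.random.default_rng(13),
            n_per_category=20)
        assert set(ind) == {n.nest_id for n in nests}
        assert sorted(set(ind.values())) == [0, 1]


class TestDeterminism:
    def test_generators_reproducible_under_truth_seed(self, truth):
        a = synthetic.gen_delivery_dataset(truth, "dry", n_nests=5)
        b = synthetic.gen_delivery_dataset(truth, "dry", n_nests=5)
        assert a == b
        ma = synthetic.gen_growth_and_mass(truth, n_nestlings=3,
                                           n_adult_females=2, n_adult_males=2)
        mb = synthetic.gen_growth_and_mass(truth, n_nestlings=3,
                                           n_adult_females=2, n_adult_males=2)
        assert ma == mb


class TestTable1Fixture:
    def test_shape_and_2004_row(self):
        t1 = synthetic.table1_fixture()
        assert len(t1) == 17
        row = t1[t1.year == 2004].iloc[0]
        assert (row.precip_mm, row.min_temp_c) == (224.03, -3.07)
        assert (row.wet_dry, row.warm_cold) == ("dry", "cold")
        assert (row.nests_delivery, row.nests_productivity) == (11, 21)
        assert (row.mean_clutch, row.mean_brood, row.mean_fledglings) == \
            (3.00, 2.74, 2.45)

    def test_total_productivity_nests(self):
        t1 = synthetic.table1_fixture()
        assert int(t1.nests_productivity.sum()) == 400
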