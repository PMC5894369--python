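"""Income model, financial-protection probabilities and revenue arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tobacco_ecea as te
from tobacco_ecea import financial_outcomes as fin


class TestLognormalFromGini:
    def test_zero_gini_degenerates_to_mean(self):
        model = te.lognormal_from_gini(0.0, 1000.0)
        assert model.sigma == 0.0
        assert model.ppf(0.37) == 1000.0

    def test_closed_form_parameters(self):
        # sigma = sqrt(2) * Phi^-1((0.46+1)/2) = 0.86665, cross-checked by the
        # Monte-Carlo Gini of 10^6 lognormal(mu, sigma) draws (0.4602)
        model = te.lognormal_from_gini(0.46, 10_000.0)
        assert model.sigma == pytest.approx(0.86665, abs=1e-5)
        assert model.mu == pytest.approx(math.log(10_000) - 0.37554, abs=1e-5)

    def test_mean_is_pinned(self):
        for gini in (0.1, 0.35, 0.53):
            m = te.lognormal_from_gini(gini, 7_500.0)
            implied = math.exp(m.mu + m.sigma**2 / 2)
            assert implied == pytest.approx(7_500.0, abs=1e-6)

    def test_gini_round_trip(self):
        for gini in (0.05, 0.32, 0.46, 0.53, 0.8):
            m = te.lognormal_from_gini(gini, 5_000.0)
            assert fin.gini_of_lognormal(m.sigma) == pytest.approx(gini, abs=1e-9)

    def test_invalid_gini_rejected(self):
        with pytest.raises(ValueError):
            te.lognormal_from_gini(1.0, 1000.0)


class TestOopShare:
    def test_full_public_financing_means_no_oop(self, by_name):
        p = te.CountryProfile(**{**by_name["Brazil"].__dict__,
                                 "coverage_fraction": 1.0, "public_cost_share": 1.0})
        assert te.oop_share(p, 3, "stroke") == 0.0

    def test_no_coverage_means_full_oop(self, by_name):
        p = te.CountryProfile(**{**by_name["India"].__dict__, "coverage_fraction": 0.0})
        assert te.oop_share(p, 1, "copd") == 1.0

    def test_india_from_published_row(self, by_name):
        assert te.oop_share(by_name["India"], 2, "cancers") == pytest.approx(0.944)

    def test_mexico_override_applies(self, by_name):
        mex = by_name["Mexico"]
        assert te.oop_share(mex, 1, "copd") == 0.0
        assert te.oop_share(mex, 2, "stroke") == 1.0
        assert te.oop_share(mex, 3, "copd") == pytest.approx(1 - 0.82 * 0.70)
        assert te.oop_share(mex, 1, "stroke", apply_overrides=False) == pytest.approx(
            1 - 0.89 * 0.82
        )


class TestCostsAverted:
    def test_single_disease_product(self):
        total, oop = te.costs_averted({"copd": 0.001}, {"copd": 5000.0}, {"copd": 0.0})
        assert total == pytest.approx(5.0)
        assert oop == 0.0

    def test_two_disease_hand_sum(self):
        total, oop = te.costs_averted(
            {"copd": 0.001, "stroke": 0.002},
            {"copd": 4000.0, "stroke": 2500.0},
            {"copd": 0.5, "stroke": 1.0},
        )
        assert total == pytest.approx(9.0)
        assert oop == pytest.approx(7.0)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            te.costs_averted({"copd": 1.0}, {"copd": -1.0}, {"copd": 1.0})


class TestCatastrophicAndPoverty:
    def test_zero_cost_zero_cases(self):
        m = te.lognormal_from_gini(0.4, 5000.0)
        assert te.catastrophic_averted(1.0, 0.0, m, 1) == 0.0
        assert te.poverty_averted(1.0, 0.0, m, 1) == 0.0

    def test_degenerate_income_point_mass(self):
        m = te.lognormal_from_gini(0.0, 1000.0)
        # cost 200 > 10% of income 1000: every case is catastrophic
        assert te.catastrophic_averted(2.0, 200.0, m, 3) == pytest.approx(2.0)
        assert te.catastrophic_averted(2.0, 50.0, m, 3) == 0.0

    def test_everyone_already_below_line_cannot_fall(self):
        m = te.lognormal_from_gini(0.0, 300.0)  # below 1.90*365 = 693.5
        assert te.poverty_averted(1.0, 500.0, m, 1) == 0.0

    def test_probability_non_increasing_in_quintile(self, by_name):
        p = by_name["India"]
        m = te.lognormal_from_gini(p.gini, p.mean_income)
        probs = [fin.catastrophic_probability(m, q, 800.0) for q in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(probs, probs[1:]))

    @pytest.mark.parametrize("quintile, cost", [(1, 400.0), (2, 900.0), (3, 2500.0)])
    def test_catastrophic_matches_monte_carlo(self, by_name, quintile, cost):
        p = by_name["India"]
        m = te.lognormal_from_gini(p.gini, p.mean_income)
        n = 100_000
        x = te.sample_quintile_incomes(p, quintile, n=n, seed=11, income_model=m)
        mc = float((x < 10.0 * cost).mean())
        se = math.sqrt(max(mc * (1 - mc), 1e-12) / n)
        analytic = fin.catastrophic_probability(m, quintile, cost)
        assert abs(analytic - mc) <= 3 * se + 1e-9

    @pytest.mark.parametrize("quintile, cost", [(1, 300.0), (1, 900.0), (2, 2000.0)])
    def test_poverty_matches_monte_carlo(self, by_name, quintile, cost):
        p = by_name["Bangladesh"]
        m = te.lognormal_from_gini(p.gini, p.mean_income)
        line = 1.90 * 365
        n = 100_000
        x = te.sample_quintile_incomes(p, quintile, n=n, seed=13, income_model=m)
        mc = float(((x >= line) & (x - cost < line)).mean())
        se = math.sqrt(max(mc * (1 - mc), 1e-12) / n)
        analytic = fin.poverty_probability(m, quintile, cost)
        assert abs(analytic - mc) <= 3 * se + 1e-9


class TestExciseArithmetic:
    @pytest.mark.parametrize("price, expected",
                             [(9.2, 4.6), (2.2, 1.1), (10.3, 5.15)])
    def test_excise_increase_full_pass_through(self, price, expected):
        assert te.excise_increase_for_price_rise(price, 0.5) == pytest.approx(expected)

    def test_zero_price_increase(self):
        assert te.excise_increase_for_price_rise(5.0, 0.0) == 0.0

    @pytest.mark.parametrize("price, share, expected",
                             [(2.8, 0.508, 197), (10.3, 0.821, 122), (9.2, 0.431, 232)])
    def test_rate_increase_matches_published(self, price, share, expected):
        assert te.excise_rate_increase_pct(price, share, 0.5) == expected

    def test_rate_increase_doubling_case(self):
        assert te.excise_rate_increase_pct(4.0, 0.5, 0.5, excise_fraction_of_tax=1.0) == 100

    def test_zero_tax_share_rejected(self):
        with pytest.raises(ValueError):
            te.excise_rate_increase_pct(4.0, 0.0, 0.5)


class TestExtraTaxRevenue:
    def test_zero_price_increase_zero_delta(self):
        assert te.extra_tax_revenue(1.0, 10.0, 4.0, 0.5, 0.0, 0.0, 0.0) == pytest.approx(0.0)

    def test_pure_price_effect_without_behaviour(self):
        # no quitting, no intensity change: delta = smokers * packs * dp * price
        delta = te.extra_tax_revenue(1.0, 10.0, 4.0, 0.5, 0.5, 0.0, 0.0)
        assert delta == pytest.approx(1.0 * 182.5 * 0.5 * 4.0)

    def test_hand_computed_case(self):
        # 1M smokers, 10 sticks/day, $4/pack, tax share 0.5, eps=-0.4, dp=0.5:
        # before 365, after 0.9 * 164.25 * 4.0 = 591.3 -> delta 226.3 ($M)
        qf = te.quit_fraction(-0.4, 0.5, 0.5)
        ir = te.intensity_reduction(-0.4, 0.5, 0.5)
        delta = te.extra_tax_revenue(1.0, 10.0, 4.0, 0.5, 0.5, qf, ir)
        assert delta == pytest.approx(226.3, abs=0.05)

    @settings(deadline=None, max_examples=60)
    @given(eps=st.floats(-0.6, -0.01), dp=st.floats(0.01, 1.0),
           share=st.floats(0.05, 0.9), sticks=st.floats(1.0, 30.0),
           price=st.floats(0.5, 20.0))
    def test_positive_within_literature_envelope(self, eps, dp, share, sticks, price):
        """Higher tax dominates demand loss for elasticities in the evidence range."""
        qf = te.quit_fraction(eps, dp, 0.5)
        ir = te.intensity_reduction(eps, dp, 0.5)
        delta = te.extra_tax_revenue(1.0, sticks, price, share, dp, qf, ir)
        assert delta > 0
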