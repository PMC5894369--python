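"""Financial-protection and revenue arithmetic.

Covers: the lognormal income model parameterized from the Gini coefficient
and mean income; out-of-pocket (OOP) shares of treatment costs under each
country's public-financing scheme; treatment costs averted; men avoiding
catastrophic health expenditure (OOP > 10% of annual income, the WHO
definition) and extreme poverty (income pushed below $1.90/day, the World
Bank line); and excise-revenue accounting under full pass-through of the
tax increase to retail prices.

For a lognormal income distribution with log-scale sigma, the Gini
coefficient is G = 2*Phi(sigma/sqrt(2)) - 1, which inverts to
sigma = sqrt(2) * Phi^{-1}((G+1)/2); the location mu is then pinned by the
mean: E[income] = exp(mu + sigma^2/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .country_data import DISEASES, QUINTILES, CountryProfile, oop_overrides

POVERTY_LINE_PER_DAY = 1.90
DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class IncomeModel:
    """Lognormal income distribution pinned to a Gini coefficient and mean."""

    mu: float
    sigma: float
    mean_income: float
    gini: float

    def cdf(self, x: float | np.ndarray) -> float | np.ndarray:
        if self.sigma == 0.0:
            return np.where(np.asarray(x) >= self.mean_income, 1.0, 0.0)[()]
        return stats.lognorm.cdf(x, s=self.sigma, scale=math.exp(self.mu))

    def ppf(self, u: float | np.ndarray) -> float | np.ndarray:
        if self.sigma == 0.0:
            return np.full_like(np.asarray(u, dtype=float), self.mean_income)[()]
        return stats.lognorm.ppf(u, s=self.sigma, scale=math.exp(self.mu))

    def quintile_bounds(self, quintile: int) -> tuple[float, float]:
        """Income support of the given population quintile."""
        lo = float(self.ppf((quintile - 1) / 5.0)) if quintile > 1 else 0.0
        hi = float(self.ppf(quintile / 5.0)) if quintile < 5 else math.inf
        return lo, hi


def lognormal_from_gini(gini: float, mean_income: float) -> IncomeModel:
    """Construct the country income model from its Gini coefficient and mean income."""
    if not 0.0 <= gini < 1.0:
        raise ValueError(f"gini must be in [0, 1), got {gini}")
    if mean_income <= 0:
        raise ValueError("mean_income must be positive")
    sigma = math.sqrt(2.0) * stats.norm.ppf((gini + 1.0) / 2.0)
    mu = math.log(mean_income) - sigma**2 / 2.0
    return IncomeModel(mu=mu, sigma=sigma, mean_income=mean_income, gini=gini)


def gini_of_lognormal(sigma: float) -> float:
    """Closed-form Gini of a lognormal with log-scale sigma."""
    return 2.0 * stats.norm.cdf(sigma / math.sqrt(2.0)) - 1.0


def oop_share(
    profile: CountryProfile,
    quintile: int,
    disease: str,
    apply_overrides: bool = True,
) -> float:
    """Out-of-pocket fraction of treatment cost for one quintile and disease.

    The publicly financed fraction is coverage * public cost share; the
    remainder is paid out of pocket.  Country-specific per-quintile,
    per-disease overrides (Mexico's Seguro Popular) take precedence.
    """
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}")
    coverage, cost_share = profile.coverage_fraction, profile.public_cost_share
    if apply_overrides:
        overrides = oop_overrides(profile)
        if overrides is not None and (quintile, disease) in overrides:
            coverage, cost_share = overrides[(quintile, disease)]
    return 1.0 - coverage * cost_share


def costs_averted(
    deaths_by_disease: dict[str, float],
    unit_costs: dict[str, float],
    oop_shares: dict[str, float],
) -> tuple[float, float]:
    """Total and out-of-pocket treatment costs averted ($PPP millions for deaths in millions).

    Lifetime treatment cost attaches to each averted fatal case; the OOP part
    scales by the payer split.
    """
    total = 0.0
    oop = 0.0
    for d, deaths in deaths_by_disease.items():
        cost = unit_costs[d]
        if cost < 0:
            raise ValueError(f"negative unit cost for {d}")
        total += deaths * cost
        oop += deaths * cost * oop_shares[d]
    return total, oop


def _interval_probability(model: IncomeModel, quintile: int, a: float, b: float) -> float:
    """P(a <= income < b | income in quintile), quintiles being 20% population slices."""
    lo, hi = model.quintile_bounds(quintile)
    if model.sigma == 0.0:
        return 1.0 if a <= model.mean_income < b else 0.0
    a, b = max(a, lo), min(b, hi)
    if b <= a:
        return 0.0
    return float((model.cdf(b) - model.cdf(a)) / 0.2)


def catastrophic_probability(model: IncomeModel, quintile: int, oop_cost: float) -> float:
    """P(OOP cost exceeds 10% of annual income | income in quintile)."""
    if oop_cost <= 0:
        return 0.0
    return _interval_probability(model, quintile, 0.0, 10.0 * oop_cost)


def poverty_probability(
    model: IncomeModel,
    quintile: int,
    oop_cost: float,
    poverty_line_per_day: float = POVERTY_LINE_PER_DAY,
    days: int = DAYS_PER_YEAR,
) -> float:
    """P(income >= L and income - OOP cost < L | quintile), L the annual poverty line.

    Only men above the line who are pushed below it count; those already in
    poverty cannot newly fall into it.
    """
    if oop_cost <= 0:
        return 0.0
    line = poverty_line_per_day * days
    return _interval_probability(model, quintile, line, line + oop_cost)


def catastrophic_averted(
    cases: float, oop_cost_per_case: float, model: IncomeModel, quintile: int
) -> float:
    """Men (millions) avoiding catastrophic health expenditure among averted cases."""
    return cases * catastrophic_probability(model, quintile, oop_cost_per_case)


def poverty_averted(
    cases: float,
    oop_cost_per_case: float,
    model: IncomeModel,
    quintile: int,
    poverty_line_per_day: float = POVERTY_LINE_PER_DAY,
    days: int = DAYS_PER_YEAR,
) -> float:
    """Men (millions) avoiding falling into extreme poverty among averted cases."""
    return cases * poverty_probability(model, quintile, oop_cost_per_case,
                                       poverty_line_per_day, days)


def excise_increase_for_price_rise(price_per_pack: float, price_increase: float) -> float:
    """Excise increase ($PPP/pack) needed for the price rise under full pass-through."""
    if price_increase < 0:
        raise ValueError("price_increase must be non-negative")
    return price_increase * price_per_pack


def excise_rate_increase_pct(
    price_per_pack: float,
    tax_share: float,
    price_increase: float,
    excise_fraction_of_tax: float = 0.5,
) -> int:
    """Percent increase in the excise rate implied by the price rise.

    Baseline excise is taken as ``excise_fraction_of_tax`` of the total tax
    share of the retail price (default 0.5, which reproduces the published
    per-country values exactly).
    """
    if tax_share <= 0:
        raise ValueError("tax_share must be positive")
    return round(
        100.0 * (price_increase * price_per_pack)
        / (excise_fraction_of_tax * tax_share * price_per_pack)
    )


def extra_tax_revenue(
    smokers: float,
    sticks_per_day: float,
    price_per_pack: float,
    tax_share: float,
    price_increase: float,
    quit_fraction: float,
    intensity_reduction: float,
    sticks_per_pack: int = 20,
) -> float:
    """Change in annual tobacco tax revenue for a smoker stratum.

    Revenue before = smokers x packs/year x tax/pack.  After the price rise,
    continuing smokers (1 - quit fraction) buy fewer packs (scaled by
    1 - intensity reduction) but each pack carries the old tax plus the full
    excise increase (price_increase x price).  Units: smokers in millions ->
    revenue in $PPP millions.
    """
    packs_per_year = sticks_per_day * DAYS_PER_YEAR / sticks_per_pack
    before = smokers * packs_per_year * tax_share * price_per_pack
    after = (
        smokers
        * (1.0 - quit_fraction)
        * packs_per_year
        * (1.0 - intensity_reduction)
        * (tax_share * price_per_pack + price_increase * price_per_pack)
    )
    return after - before


def stratum_financials(
    profile: CountryProfile,
    quintile: int,
    deaths_averted: float,
    model: IncomeModel,
    treated_case_multiplier: float = 1.0,
    apply_overrides: bool = True,
) -> dict[str, float]:
    """Disease-resolved financial outcomes for one (country, quintile) cell.

    Averted fatal cases (optionally scaled by a non-fatal treated-case
    multiplier) carry the country's per-disease lifetime treatment cost;
    catastrophic-expenditure and poverty aversion are evaluated per disease
    at that disease's OOP cost and summed.  Catastrophic/poverty outcomes are
    reported only for countries in the low-coverage subset.
    """
    deaths_by_disease = {d: deaths_averted * profile.disease_mix[d] for d in DISEASES}
    shares = {d: oop_share(profile, quintile, d, apply_overrides) for d in DISEASES}
    total, oop = costs_averted(deaths_by_disease, profile.unit_treatment_cost, shares)
    cat = pov = 0.0
    if profile.in_catastrophic_subset:
        for d in DISEASES:
            cases = deaths_by_disease[d] * treated_case_multiplier
            cost_d = profile.unit_treatment_cost[d] * shares[d]
            cat += catastrophic_averted(cases, cost_d, model, quintile)
            pov += poverty_averted(cases, cost_d, model, quintile)
    return {
        "cost_averted_total": total,
        "cost_averted_oop": oop,
        "catastrophic_averted": cat,
        "poverty_averted": pov,
    }
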