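# Methods

## Model overview

`tobacco_ecea` implements a static compartmental model of a one-time increase
in the retail price of cigarettes, evaluated for 13 middle-income countries
(India, Indonesia, Bangladesh, the Philippines, Vietnam, Armenia, China,
Mexico, Turkey, Brazil, Colombia, Thailand, Chile) and resolved by income
quintile (1 = poorest 20% of the population, 5 = richest 20%). It is an
extended cost-effectiveness analysis (ECEA): alongside health outcomes it
tracks financial-risk-protection outcomes (catastrophic health expenditure and
impoverishment averted) and the fiscal transfer (extra excise revenue), each
by income group.

The causal chain is:

1. **Price response.** A price rise of fraction Δp changes cigarette
   consumption by ε·Δp (arc approximation), where ε is the price elasticity of
   demand. Half of the consumption response (configurable `quit_share`) is
   smokers quitting outright; the other half is reduced daily consumption
   among continuing smokers. No health benefit is credited for reduced
   consumption — only quitting counts, a deliberately conservative choice.
2. **Health outcomes.** Each quitter gains life years according to an
   age-at-cessation schedule; deaths averted are quitters × 0.5 scaled by the
   same schedule relative to its maximum (see below). Averted deaths are
   apportioned over four disease groups — COPD, stroke, heart disease,
   cancers — by a fixed mortality mix.
3. **Financial outcomes.** Each averted fatal case carries a per-disease
   lifetime treatment cost, split between public financing and out-of-pocket
   (OOP) payment by the country's coverage fraction and public cost share. A
   case whose OOP cost exceeds 10% of the individual's annual income would
   have been catastrophic (WHO definition); one that pushes income below
   $1.90/day would have been impoverishing (World Bank line, annualized over
   365 days). Both probabilities are evaluated in closed form on the
   country's lognormal income distribution, restricted to the quintile's
   population-quantile interval. Extra excise revenue is the post-rise
   revenue of continuing smokers (old tax per pack plus the full excise
   increase Δp·price, fewer packs) minus baseline revenue.

All computations are deterministic; the only randomness is the optional
Dirichlet jitter in the synthetic age structure and the Monte-Carlo oracles
used in tests, both driven by a single top-level seed with per-country child
seeds derived from a CRC32 of the country name (stable under country
reordering).

## Elasticity matrix

The literature on cigarette price elasticity in low- and middle-income
countries clusters between −0.2 and −0.6 with a central value of −0.4, and
consistently finds young smokers (15–24) and poorer smokers about twice as
responsive as older and richer ones. The default matrix pins two anchors —
−1.27 for young smokers in the bottom quintile, −0.24 for smokers 25+ in the
top quintile — and fills the 25+ row geometrically from −0.635 (= −1.27/2) at
quintile 1 down to −0.24 at quintile 5 (per-quintile ratio
(0.24/0.635)^(1/4) ≈ 0.7839); the young row is twice the 25+ row. Entries are
rounded to 4 decimals. The geometric interpolation is this package's design
choice — it reproduces both anchors exactly, preserves the monotone gradients,
and yields a smoker-weighted mean near −0.4 for realistic age/quintile
weights; the realized mean is reported, not renormalized. A fully custom
matrix can be injected, and country-specific overall elasticities rescale the
matrix cell-wise by ε_country/−0.4.

## Life-year schedule and deaths averted

Cohort evidence puts the benefit of cessation at ~10 life years before age
30 and 9, 6 and 3 years for cessation by 30–44, 45–64 and 65+. These steps
are smoothed onto 5-year age bands (15–90) with a monotone shape-preserving
cubic (PCHIP) through the interval midpoints (22.5, 10), (37.5, 9), (55, 6),
(75, 3), clamped to constant values outside the knot span. PCHIP was chosen
over a smoothing spline precisely because it guarantees the schedule never
increases with age; midpoint knot placement is a declared convention.

Smoking kills at least half of persistent smokers who start early in adult
life, costing ~10 years each. The age profile of *death* aversion per quitter
is not separately documented, so the package scales the 0.5 probability by
the life-year schedule relative to its maximum: a quitter at 20–24 averts
death with probability 0.5; at 75–79, 0.5 × 3/10 = 0.15. This anchors the
canonical 0.5-death/10-year pair for young quitters and decays with age in
proportion to the cessation benefit. The risk and the rule are configurable.

## Synthetic population

Survey-derived smoking prevalence by 5-year age band × quintile is not
published for these countries; only per-quintile smoker totals are. The
synthetic-population module spreads each quintile total across the 15 age
bands with triangular weights peaking at 35–39 and falling to zero above 84
(a realistic unimodal smoker age profile), optionally perturbed by Dirichlet
jitter. Quintile totals are conserved exactly under any weights or jitter.
This emulates the *shape* of a survey age profile but not country-specific
age patterns, cohort effects, or age-varying smoking intensity — so
model-mode outputs demonstrate the mechanics and distributional gradients of
the method, not a reproduction of the published country estimates, which
were computed from the unpublished survey strata. Cigarettes/day is constant
across a country's strata by default (only a national mean is published).

The under-15 future-smoker cohort (which receives the young-age elasticity)
defaults to off because its size is not quantified in the source material;
`initiation_fraction` enables it.

## Income model

Each country's income distribution is lognormal with
σ = √2·Φ⁻¹((G+1)/2) and μ = ln(mean) − σ²/2, so that the distribution's Gini
coefficient equals G (Gini of a lognormal = 2Φ(σ/√2) − 1) and its mean equals
the mean per-capita income exactly. Quintiles are population quantiles
(equal-headcount slices), not income-share quintiles. Catastrophic and
poverty probabilities are closed-form lognormal CDF differences on the
quintile's quantile interval; tests verify them against 10⁶-sample
Monte-Carlo estimates within 3 standard errors. G = 0 degenerates to a point
mass at the mean.

## Inputs and provenance

Published inputs shipped as packaged CSVs: the country indicator table
(prices, tax shares, prevalence, coverage) and the per-country × quintile
table of smokers, life years, disease costs and tax revenues. Cells printed
as "<0.1" are parsed as the midpoint 0.05 and flagged. Gini coefficients,
mean incomes, the disease mix and unit treatment costs are **synthetic
placeholders** (files suffixed `_synthetic`): plausible, field-realistic
values chosen once so the full pipeline runs; user-supplied files replace
them for real analyses. The same applies to the per-country elasticities
used by the corresponding sensitivity scenario.

Mexico's public scheme is special-cased: for the two poorest quintiles only
COPD is covered (fully); the richer quintiles get 82% coverage with a 70%
cost share across all four diseases. Catastrophic/poverty outcomes are
computed only for the seven-country low-coverage subset (India, Indonesia,
Bangladesh, the Philippines, Vietnam, China, Mexico); other countries report
zero by policy. The financial-protection case count defaults to averted
fatal cases; a multiplier for non-fatal treated cases is a config knob.

## Replay mode and known tolerances

Replay mode runs only the aggregation layer over the published per-quintile
outcome table, verifying totals, bottom/top sums, ratios and per-country
bottom-share medians. Because the published cells are rounded (0.1 million /
0.1 billion precision), some summary statistics differ slightly from the
published ones, which were computed from unrounded internals:

* share medians and ranges can shift by ±1 percentage point (e.g. the tax
  bottom-share median computes to 11% vs the published 10%);
* Armenia's five 0.1-cells make its bottom share exactly 20–22%, so the
  published life-years share minimum (26%) is not recoverable from cells;
* ratios reported to 1 decimal can differ in the last digit (6.6 vs 6.7).

Validation of quintile sums against printed country totals therefore accepts
max(2% relative, 0.3 million absolute); the absolute term covers five
half-cell roundings plus the total's own rounding.

## Numerical and degenerate-input choices

* Δp = 0 is accepted everywhere and yields exactly zero response, revenue
  change and excise increase.
* Quit and intensity fractions are capped at 1.
* The excise-rate increase assumes baseline excise is half the total tax
  share (configurable `excise_fraction_of_tax`); this reproduces the
  published "% increase in tax rate" for all 13 countries exactly.
* The extra-revenue-positivity property is guaranteed only on the evidence
  envelope |ε| ≤ 0.6, tax share ≤ 0.9, quit share 0.5; outside it (e.g.
  ε = −1.27 young/bottom strata in high-tax-share countries) a stratum's
  revenue change can be negative while country aggregates stay positive.
* Medians over 13 countries are the 7th order statistic; shares are rounded
  to integer percent before taking min/max.

## Problem sizes

Default runs use 13 countries × 15 age bands × 5 quintiles = 975 strata; the
full model chain completes in well under a second. Monte-Carlo oracles use
10⁵ samples in unit tests and 10⁶ in the acceptance-level checks.

## Limitations

The model is static (one-time increase, no discounting, no demographic
change), excludes bidis and oral tobacco, credits no benefit for reduced
smoking intensity, ignores productivity losses and second-hand smoke, and
assumes full pass-through of the excise increase to retail prices. Synthetic
placeholder inputs mean model-mode financial-protection magnitudes are
illustrative; the distributional *gradients* (pro-poor health and financial
benefits, pro-rich tax burden) are robust to those placeholders and are what
the property tests assert.
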