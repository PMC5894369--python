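"""Scenario orchestration, aggregation and reporting.

Two run modes:

* **model** — the full synthetic chain: age-by-quintile strata are
  synthesized from the published quintile smoker totals, the elasticity
  matrix converts the price rise into quitting and reduced consumption,
  and health and financial outcomes are accumulated per (country, quintile).
* **replay** — the aggregation layer alone, run over the packaged table of
  published per-country, per-quintile outcomes, which verifies the summary
  statistics (totals, bottom/top sums and ratios, per-country bottom-share
  medians and ranges) against the published aggregates without simulating.

Summaries follow the published conventions: ratios to 1 decimal, shares as
percentages rounded to the nearest integer, the median over 13 countries
being the 7th order statistic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import financial_outcomes as fin
from . import health_outcomes as health
from . import price_response as pr
from . import synthetic_population as synth
from .country_data import QUINTILES, CountryProfile, load_quintile_outcomes

log = logging.getLogger("tobacco_ecea")

MODEL_OUTCOME_COLUMNS = (
    "smokers_before", "quitters", "life_years", "deaths_averted",
    "cost_averted_total", "cost_averted_oop",
    "catastrophic_averted", "poverty_averted", "extra_tax",
)

SENSITIVITY_LABELS = ("dp25", "dp100", "excl_CN_IN", "incl_female", "country_elasticities")


@dataclass(frozen=True)
class OutcomeSummary:
    """Cross-country summary for one outcome column."""

    total: float
    bottom_sum: float
    top_sum: float
    ratio: float | None          # bottom/top, 1 decimal
    bottom_shares_pct: dict[str, int]  # per-country, integer percent
    median_share_pct: float
    min_share_pct: int
    max_share_pct: int

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "bottom_sum": self.bottom_sum,
            "top_sum": self.top_sum,
            "ratio": self.ratio,
            "bottom_shares_pct": self.bottom_shares_pct,
            "median_share_pct": self.median_share_pct,
            "min_share_pct": self.min_share_pct,
            "max_share_pct": self.max_share_pct,
        }


def _scenario_smokers(profile: CountryProfile, scenario: pr.Scenario) -> CountryProfile:
    """Apply the include-female adjustment to a profile's smoker counts."""
    if scenario.include_female and profile.name in scenario.female_shares:
        share = scenario.female_shares[profile.name]
        factor = 1.0 / (1.0 - share)  # male counts -> all-smoker counts
        return CountryProfile(
            **{
                **profile.__dict__,
                "smokers_by_quintile": tuple(
                    s * factor for s in profile.smokers_by_quintile
                ),
                "smokers_total_printed": profile.smokers_total_printed * factor,
            }
        )
    return profile


def run_scenario(
    profiles: list[CountryProfile],
    scenario: pr.Scenario,
    schedule: health.LifeYearSchedule | None = None,
    mortality: health.MortalityModel | None = None,
    treated_case_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Run the full model chain; returns the outcome table.

    The result is a DataFrame indexed by (country, quintile) with the
    columns in ``MODEL_OUTCOME_COLUMNS``: smoker counts, quitters, life
    years and deaths averted in millions, costs and extra tax in $PPP
    millions.  Deterministic for a given scenario seed.
    """
    schedule = schedule or health.fit_life_year_schedule()
    mortality = mortality or health.MortalityModel()
    included = [
        p for p in profiles
        if scenario.include_countries is None or p.name in scenario.include_countries
    ]
    if not included:
        raise ValueError("no countries selected")
    rows = []
    for profile in included:
        t0 = time.perf_counter()
        profile = _scenario_smokers(profile, scenario)
        matrix = pr.scenario_matrix(scenario, profile.name)
        strata = synth.synthesize_age_structure(
            profile, seed=scenario.seed, jitter=scenario.age_jitter
        )
        quit_table = pr.quitters_by_stratum(strata, matrix, scenario)
        quit_table = health.deaths_averted(quit_table, schedule, mortality)

        # future (<15) cohort: young-row elasticity, full young-age benefit
        for cohort in synth.synthesize_future_cohort(
            profile, scenario.future_initiation_fraction, seed=scenario.seed
        ):
            if cohort.future_smokers == 0:
                continue
            eps = pr.effective_elasticity(matrix, cohort, cohort.quintile)
            qf = pr.quit_fraction(eps, scenario.price_increase, scenario.quit_share)
            quit_table = pd.concat(
                [quit_table, pd.DataFrame([{
                    "country": profile.name, "age_band": "15-19",
                    "quintile": cohort.quintile,
                    "smokers": 0.0,  # not yet smoking: excluded from revenue base
                    "sticks_per_day": profile.sticks_per_day,
                    "elasticity": eps, "quit_fraction": qf,
                    "quitters": cohort.future_smokers * qf,
                    "life_years_per_quitter": schedule.at_band("15-19"),
                    "life_years": cohort.future_smokers * qf * schedule.at_band("15-19"),
                    "deaths_averted": cohort.future_smokers * qf
                    * mortality.death_risk_if_continue
                    * schedule.at_band("15-19") / schedule.max_gain,
                }])],
                ignore_index=True,
            )

        income_model = fin.lognormal_from_gini(profile.gini, profile.mean_income)
        for q in QUINTILES:
            cell = quit_table[quit_table["quintile"] == q]
            deaths_q = float(cell["deaths_averted"].sum())
            money = fin.stratum_financials(
                profile, q, deaths_q, income_model,
                treated_case_multiplier=treated_case_multiplier,
            )
            qf_mean = 0.0
            smokers_q = float(cell["smokers"].sum())
            tax = 0.0
            for _, s in cell.iterrows():
                if s["smokers"] == 0:
                    continue
                ir = pr.intensity_reduction(
                    s["elasticity"], scenario.price_increase, scenario.quit_share
                )
                tax += fin.extra_tax_revenue(
                    s["smokers"], s["sticks_per_day"], profile.price_per_pack,
                    profile.tax_share, scenario.price_increase,
                    s["quit_fraction"], ir,
                )
            rows.append({
                "country": profile.name, "quintile": q,
                "smokers_before": smokers_q,
                "quitters": float(cell["quitters"].sum()),
                "life_years": float(cell["life_years"].sum()),
                "deaths_averted": deaths_q,
                "extra_tax": tax,
                **money,
            })
        log.info("%s: %.1f ms", profile.name, 1e3 * (time.perf_counter() - t0))
    table = pd.DataFrame(rows).set_index(["country", "quintile"]).sort_index()
    return table[list(MODEL_OUTCOME_COLUMNS)]


def replay_outcomes(source: str = "bundled") -> pd.DataFrame:
    """Outcome table built from the published per-quintile values (replay mode)."""
    raw = load_quintile_outcomes(source)
    cells = raw[raw.index.get_level_values("quintile") != 0]
    return cells.rename(columns={"smokers": "smokers_before"}).drop(columns=["flagged"])


def summarize(
    outcomes: pd.DataFrame,
    columns: list[str] | None = None,
    groups: tuple[int, int] = (1, 5),
) -> dict[str, OutcomeSummary]:
    """Cross-country summary statistics for each outcome column.

    For every outcome: the grand total, bottom- and top-quintile sums, the
    bottom:top ratio (1 decimal), per-country bottom shares as integer
    percentages, and their median / min / max.
    """
    if outcomes.empty:
        raise ValueError("empty outcome table")
    bottom, top = groups
    numeric = [c for c in outcomes.columns if outcomes[c].dtype.kind in "fi"]
    columns = columns or numeric
    result: dict[str, OutcomeSummary] = {}
    for col in columns:
        series = outcomes[col]
        total = float(series.sum())
        by_q = series.groupby(level="quintile").sum()
        bottom_sum = float(by_q.get(bottom, 0.0))
        top_sum = float(by_q.get(top, 0.0))
        ratio = round(bottom_sum / top_sum, 1) if top_sum > 0 else None
        shares = {}
        for country, sub in series.groupby(level="country"):
            ctotal = float(sub.sum())
            if ctotal > 0:
                share = 100.0 * float(sub.xs(bottom, level="quintile").sum()) / ctotal
                shares[country] = int(round(share))
        share_values = sorted(shares.values())
        result[col] = OutcomeSummary(
            total=total,
            bottom_sum=bottom_sum,
            top_sum=top_sum,
            ratio=ratio,
            bottom_shares_pct=shares,
            median_share_pct=float(np.median(share_values)) if shares else float("nan"),
            min_share_pct=min(share_values) if shares else 0,
            max_share_pct=max(share_values) if shares else 0,
        )
    return result


def sensitivity_suite(
    profiles: list[CountryProfile],
    base_scenario: pr.Scenario,
    country_elasticities: dict[str, float] | None = None,
    labels: tuple[str, ...] = SENSITIVITY_LABELS,
) -> dict[str, tuple[pd.DataFrame, dict[str, OutcomeSummary]]]:
    """Run the published sensitivity scenarios against a base scenario.

    Labels: ``dp25`` / ``dp100`` (25% / 100% price rises), ``excl_CN_IN``
    (drop China and India), ``incl_female`` (add female smokers in Chile,
    Colombia and Mexico), ``country_elasticities`` (country-specific overall
    elasticities instead of the common matrix).
    """
    def _variant(label: str) -> pr.Scenario:
        kw = base_scenario.__dict__.copy()
        if label == "dp25":
            kw["price_increase"] = 0.25
        elif label == "dp100":
            kw["price_increase"] = 1.0
        elif label == "excl_CN_IN":
            names = {p.name for p in profiles} - {"China", "India"}
            kw["include_countries"] = frozenset(names)
        elif label == "incl_female":
            kw["include_female"] = True
        elif label == "country_elasticities":
            if country_elasticities is None:
                raise ValueError("country_elasticities required for that scenario")
            kw["elasticity_spec"] = "country_specific"
            kw["country_elasticities"] = country_elasticities
        else:
            raise ValueError(f"unknown sensitivity label {label!r}")
        return pr.Scenario(**kw)

    out = {}
    for label in labels:
        scenario = _variant(label)
        table = run_scenario(profiles, scenario)
        out[label] = (table, summarize(table))
    return out


def render_report(
    outcomes: pd.DataFrame,
    stats: dict[str, OutcomeSummary],
    directory,
    fmt: str = "csv",
) -> list[str]:
    """Write outcome matrices and summaries to disk; returns the files written.

    ``csv`` writes one country x quintile matrix per outcome plus a summary
    table and (when present) catastrophic/poverty and bottom-vs-top share
    files; ``json`` writes the summaries; ``markdown`` writes one table per
    outcome with summary rows.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _matrix(col: str) -> pd.DataFrame:
        return outcomes[col].unstack("quintile")

    if fmt == "csv":
        for col in outcomes.columns:
            path = directory / f"{col}_by_country_quintile.csv"
            _matrix(col).round(4).to_csv(path)
            written.append(str(path))
        summary = pd.DataFrame({k: {
            "total": v.total, "bottom_sum": v.bottom_sum, "top_sum": v.top_sum,
            "bottom_top_ratio": v.ratio, "median_bottom_share_pct": v.median_share_pct,
            "min_bottom_share_pct": v.min_share_pct, "max_bottom_share_pct": v.max_share_pct,
        } for k, v in stats.items()}).T
        path = directory / "summary.csv"
        summary.to_csv(path)
        written.append(str(path))
        if {"catastrophic_averted", "poverty_averted"} <= set(outcomes.columns):
            sub = outcomes[["catastrophic_averted", "poverty_averted"]]
            sub = sub[sub.groupby(level="country").transform("sum").iloc[:, 0] > 0]
            path = directory / "financial_protection_by_quintile.csv"
            sub.round(6).to_csv(path)
            written.append(str(path))
        shares = pd.DataFrame({
            col: {"bottom_share_pct": 100 * v.bottom_sum / v.total if v.total else np.nan,
                  "top_share_pct": 100 * v.top_sum / v.total if v.total else np.nan}
            for col, v in stats.items()
        }).T
        path = directory / "bottom_vs_top_shares.csv"
        shares.round(1).to_csv(path)
        written.append(str(path))
    elif fmt == "json":
        path = directory / "summary.json"
        path.write_text(json.dumps({k: v.to_dict() for k, v in stats.items()}, indent=2))
        written.append(str(path))
    elif fmt == "markdown":
        lines = []
        for col in outcomes.columns:
            m = _matrix(col).round(2)
            lines.append(f"## {col}\n")
            lines.append("| country | " + " | ".join(str(q) for q in m.columns) + " |")
            lines.append("|" + "---|" * (len(m.columns) + 1))
            for country, row in m.iterrows():
                lines.append(f"| {country} | " + " | ".join(str(v) for v in row) + " |")
            s = stats[col]
            lines.append("")
            lines.append(
                f"Total {s.total:.1f}; bottom:top ratio {s.ratio}; "
                f"bottom share median {s.median_share_pct:.0f}% "
                f"(range {s.min_share_pct}-{s.max_share_pct}%)."
            )
            lines.append("")
        path = directory / "report.md"
        path.write_text("\n".join(lines))
        written.append(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return written
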