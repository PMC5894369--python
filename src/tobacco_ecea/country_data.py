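"""Country-level model inputs: data classes, packaged fixtures, readers and validators.

The packaged fixtures transcribe the published country indicator table
(population, smoking prevalence, cigarette prices, tax shares, public
financing) and the per-quintile smoker counts for the 13 middle-income
countries studied.  Gini coefficients, mean per-capita incomes, the
four-disease mortality mix and unit treatment costs are not published at
country level; the packaged ``country_economics_synthetic.csv`` carries
clearly-labelled synthetic placeholder values so the full pipeline runs
end to end, and user-supplied files can replace them.

Cells printed as ``<0.1`` in the source tables are parsed as the midpoint
0.05 and recorded in the profile's ``flagged`` set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

#: Disease groups carrying smoking-attributable mortality (tuberculosis excluded).
DISEASES = ("copd", "stroke", "heart_disease", "cancers")

#: Quintile indices, 1 = poorest 20%, 5 = richest 20%.
QUINTILES = (1, 2, 3, 4, 5)

# Countries with low effective universal health coverage, plus Mexico (high
# out-of-pocket costs for smoking-attributable disease): the subset for which
# catastrophic-expenditure and poverty outcomes are computed.
CATASTROPHIC_SUBSET = frozenset(
    {"India", "Indonesia", "Bangladesh", "Philippines", "Vietnam", "China", "Mexico"}
)

# Mexico's public scheme fully covers COPD (only) for the two poorest
# quintiles; the remaining quintiles have 82% coverage with a 70% cost share
# across all four diseases.
MEXICO_COVERAGE_OVERRIDE = {
    (q, d): ((1.0, 1.0) if d == "copd" else (0.0, 0.0))
    for q in (1, 2)
    for d in DISEASES
} | {(q, d): (0.82, 0.70) for q in (3, 4, 5) for d in DISEASES}

COVERAGE_OVERRIDES = {"Mexico": MEXICO_COVERAGE_OVERRIDE}


class SchemaError(ValueError):
    """An input table is missing a required column or is otherwise malformed."""


class ValidationError(ValueError):
    """A country profile violates a model invariant."""


@dataclass
class CountryProfile:
    """All per-country inputs required by the price-increase model.

    Monetary values are 2015/2016 $PPP; populations and smoker counts are in
    millions of persons.
    """

    name: str
    income_class: str
    male_population: float
    smoking_prevalence_15_74: float
    sticks_per_day: float
    price_per_pack: float
    tax_share: float
    coverage_fraction: float
    public_cost_share: float
    gini: float
    mean_income: float
    poverty_headcount: float
    smokers_by_quintile: tuple[float, ...]
    disease_mix: dict[str, float]
    unit_treatment_cost: dict[str, float]
    in_catastrophic_subset: bool
    smokers_total_metadata: float = math.nan
    smokers_total_printed: float = math.nan
    flagged: set[str] = field(default_factory=set)

    def validate(self) -> "CountryProfile":
        def _frac(fname: str) -> None:
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.name}: {fname}={v} outside [0, 1]")

        for fname in (
            "smoking_prevalence_15_74",
            "tax_share",
            "coverage_fraction",
            "public_cost_share",
            "gini",
        ):
            _frac(fname)
        if self.income_class not in ("lower-middle", "upper-middle"):
            raise ValidationError(f"{self.name}: unknown income_class {self.income_class!r}")
        if self.price_per_pack <= 0:
            raise ValidationError(f"{self.name}: price_per_pack must be positive")
        if self.sticks_per_day <= 0:
            raise ValidationError(f"{self.name}: sticks_per_day must be positive")
        if abs(sum(self.disease_mix.values()) - 1.0) > 1e-9:
            raise ValidationError(f"{self.name}: disease_mix does not sum to 1")
        if any(v < 0 for v in self.smokers_by_quintile):
            raise ValidationError(f"{self.name}: negative smokers_by_quintile entry")
        if any(c < 0 for c in self.unit_treatment_cost.values()):
            raise ValidationError(f"{self.name}: negative unit_treatment_cost")
        if not math.isnan(self.smokers_total_printed):
            total = sum(self.smokers_by_quintile)
            # 0.3 absolute allowance covers 0.1-precision rounding of the five
            # cells plus the printed total (binding for Armenia and Chile).
            tol = max(0.02 * self.smokers_total_printed, 0.3)
            if abs(total - self.smokers_total_printed) > tol:
                raise ValidationError(
                    f"{self.name}: quintile smokers sum {total:.2f} deviates from "
                    f"printed total {self.smokers_total_printed}"
                )
        return self


def _parse_cell(raw: object, flags: set[str], label: str) -> float:
    """Parse a numeric table cell, mapping '<0.1' to its midpoint 0.05."""
    if isinstance(raw, str) and raw.strip().startswith("<"):
        flags.add(label)
        return float(raw.strip().lstrip("<")) / 2.0
    return float(raw)


def _read_csv(source: str | Path, name: str) -> pd.DataFrame:
    """Read a fixture CSV either from a directory on disk or the packaged data."""
    if source == "bundled":
        with resources.files("tobacco_ecea.data").joinpath(name).open() as fh:
            df = pd.read_csv(fh, dtype=str)
    else:
        path = Path(source) / name if Path(source).is_dir() else Path(source)
        df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise SchemaError(f"{name}: no data rows")
    return df


def _require(df: pd.DataFrame, columns: list[str], name: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing column {col!r}")


def load_quintile_outcomes(source: str | Path = "bundled") -> pd.DataFrame:
    """Load the per-(country, quintile) outcome table used for replay mode.

    Returns a DataFrame indexed by (country, quintile) with float columns
    ``smokers`` / ``life_years`` (millions), ``cost_averted`` ($PPP millions)
    and ``extra_tax`` ($PPP billions), plus a boolean ``flagged`` marking
    '<0.1' cells; printed 'total' rows are kept under quintile 0.
    """
    df = _read_csv(source, "quintile_outcomes.csv")
    _require(df, ["country", "quintile", "smokers", "life_years", "cost_averted", "extra_tax"],
             "quintile_outcomes.csv")
    records = []
    for _, row in df.iterrows():
        flags: set[str] = set()
        q = 0 if row["quintile"] == "total" else int(row["quintile"])
        rec = {"country": row["country"], "quintile": q}
        for col in ("smokers", "life_years", "cost_averted", "extra_tax"):
            rec[col] = _parse_cell(row[col], flags, col)
        rec["flagged"] = bool(flags)
        records.append(rec)
    out = pd.DataFrame.from_records(records).set_index(["country", "quintile"]).sort_index()
    return out


def load_country_profiles(source: str | Path = "bundled") -> list[CountryProfile]:
    """Load and validate the country input fixtures.

    Parameters
    ----------
    source
        ``"bundled"`` for the packaged fixtures, or a directory containing
        ``country_indicators.csv``, ``quintile_outcomes.csv`` and
        ``country_economics_synthetic.csv`` with the same schemas.
    """
    ind = _read_csv(source, "country_indicators.csv")
    _require(
        ind,
        ["country", "income_class", "male_population", "smoking_prevalence_15_74",
         "sticks_per_day", "price_per_pack", "tax_share", "coverage_fraction",
         "public_cost_share", "poverty_headcount", "smokers_total_metadata",
         "in_catastrophic_subset"],
        "country_indicators.csv",
    )
    econ = _read_csv(source, "country_economics_synthetic.csv").set_index("country")
    _require(
        econ.reset_index(),
        ["country", "gini", "mean_income"]
        + [f"mix_{d}" for d in DISEASES]
        + [f"cost_{d}" for d in DISEASES],
        "country_economics_synthetic.csv",
    )
    quint = load_quintile_outcomes(source)

    profiles = []
    for _, row in ind.iterrows():
        name = row["country"]
        if name not in econ.index:
            raise SchemaError(f"country_economics_synthetic.csv: no row for {name}")
        flags: set[str] = set()
        sub = quint.loc[name]
        smokers = tuple(
            float(sub.loc[q, "smokers"]) for q in QUINTILES
        )
        for q in QUINTILES:
            if bool(sub.loc[q, "flagged"]):
                flags.add(f"smokers_q{q}")
        e = econ.loc[name]
        profile = CountryProfile(
            name=name,
            income_class=row["income_class"],
            male_population=float(row["male_population"]),
            smoking_prevalence_15_74=float(row["smoking_prevalence_15_74"]),
            sticks_per_day=float(row["sticks_per_day"]),
            price_per_pack=float(row["price_per_pack"]),
            tax_share=float(row["tax_share"]),
            coverage_fraction=float(row["coverage_fraction"]),
            public_cost_share=float(row["public_cost_share"]),
            gini=float(e["gini"]),
            mean_income=float(e["mean_income"]),
            poverty_headcount=_parse_cell(row["poverty_headcount"], flags, "poverty_headcount"),
            smokers_by_quintile=smokers,
            disease_mix={d: float(e[f"mix_{d}"]) for d in DISEASES},
            unit_treatment_cost={d: float(e[f"cost_{d}"]) for d in DISEASES},
            in_catastrophic_subset=str(row["in_catastrophic_subset"]).lower() == "true",
            smokers_total_metadata=float(row["smokers_total_metadata"]),
            smokers_total_printed=float(sub.loc[0, "smokers"]),
            flagged=flags,
        )
        profiles.append(profile.validate())
    return profiles


def baseline_smoker_total(profile: CountryProfile) -> float:
    """Male cigarette smokers aged >=15 (millions), summed over quintiles."""
    return float(sum(profile.smokers_by_quintile))


def load_country_elasticities(source: str | Path = "bundled") -> dict[str, float]:
    """Per-country overall price elasticities for the sensitivity analysis.

    The packaged file carries synthetic literature-scale values; elasticities
    must be negative.
    """
    df = _read_csv(source, "country_elasticities_synthetic.csv")
    _require(df, ["country", "elasticity"], "country_elasticities_synthetic.csv")
    out = {row["country"]: float(row["elasticity"]) for _, row in df.iterrows()}
    for c, e in out.items():
        if e >= 0:
            raise ValidationError(f"{c}: elasticity must be negative, got {e}")
    return out


def write_country_profiles(profiles: list[CountryProfile], directory: str | Path) -> None:
    """Write profiles back to the fixture CSV schema (round-trip support)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ind_rows, econ_rows, quint_rows = [], [], []
    for p in profiles:
        ind_rows.append({
            "country": p.name, "income_class": p.income_class,
            "male_population": p.male_population,
            "smoking_prevalence_15_74": p.smoking_prevalence_15_74,
            "sticks_per_day": p.sticks_per_day, "price_per_pack": p.price_per_pack,
            "tax_share": p.tax_share, "coverage_fraction": p.coverage_fraction,
            "public_cost_share": p.public_cost_share,
            "poverty_headcount": p.poverty_headcount,
            "smokers_total_metadata": p.smokers_total_metadata,
            "in_catastrophic_subset": str(p.in_catastrophic_subset).lower(),
        })
        econ_rows.append(
            {"country": p.name, "gini": p.gini, "mean_income": p.mean_income}
            | {f"mix_{d}": p.disease_mix[d] for d in DISEASES}
            | {f"cost_{d}": p.unit_treatment_cost[d] for d in DISEASES}
        )
        for q in QUINTILES:
            quint_rows.append({
                "country": p.name, "quintile": q,
                "smokers": p.smokers_by_quintile[q - 1],
                "life_years": 0.0, "cost_averted": 0.0, "extra_tax": 0.0,
            })
        quint_rows.append({
            "country": p.name, "quintile": "total",
            "smokers": p.smokers_total_printed,
            "life_years": 0.0, "cost_averted": 0.0, "extra_tax": 0.0,
        })
    pd.DataFrame(ind_rows).to_csv(directory / "country_indicators.csv", index=False)
    pd.DataFrame(econ_rows).to_csv(directory / "country_economics_synthetic.csv", index=False)
    pd.DataFrame(quint_rows).to_csv(directory / "quintile_outcomes.csv", index=False)


def oop_overrides(profile: CountryProfile) -> dict[tuple[int, str], tuple[float, float]] | None:
    """Per-(quintile, disease) coverage override for this country, if any."""
    return COVERAGE_OVERRIDES.get(profile.name)
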