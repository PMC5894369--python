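"""Demand response to a cigarette price increase.

The price elasticity of demand (percent consumption change per percent price
change) averages about -0.4 in the middle-income-country literature, with
young smokers (15-24) and poorer smokers roughly twice as responsive as
older and richer ones.  The default elasticity matrix anchors the young/
bottom-quintile cell at -1.27 and the older/top-quintile cell at -0.24 and
interpolates geometrically across quintiles.

The response is applied as an arc approximation: fractional consumption
change = elasticity x fractional price change, with half of the response
(by default) attributed to quitting outright and half to reduced daily
consumption among continuing smokers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .country_data import QUINTILES
from .synthetic_population import FutureCohort, PopulationStratum

AGE_GROUPS = ("15-24", "25+")
YOUNG_BANDS = frozenset({"15-19", "20-24"})

#: Female-to-total smoker shares in the three countries with notable female
#: smoking, used by the include-female sensitivity scenario.
FEMALE_SMOKER_SHARES = {"Chile": 0.46, "Colombia": 0.29, "Mexico": 0.29}


@dataclass(frozen=True)
class ElasticityMatrix:
    """Price elasticity by age group (15-24 / 25+) x income quintile (1-5)."""

    values: np.ndarray  # shape (2, 5), all entries <= 0
    mean_target: float = -0.4

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (2, 5):
            raise ValueError("elasticity matrix must be 2x5 (age group x quintile)")
        if np.any(v > 0):
            raise ValueError("elasticities must be <= 0")
        # |value| weakly decreasing from poorest to richest quintile
        if np.any(np.diff(np.abs(v), axis=1) > 1e-12):
            raise ValueError("|elasticity| must not increase with quintile")
        if np.any(np.abs(v[0]) < np.abs(v[1]) - 1e-12):
            raise ValueError("young smokers cannot be less responsive than older ones")
        object.__setattr__(self, "values", v)

    def cell(self, age_group: str, quintile: int) -> float:
        return float(self.values[AGE_GROUPS.index(age_group), quintile - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(AGE_GROUPS), columns=list(QUINTILES))


@dataclass(frozen=True)
class Scenario:
    """One model run configuration.

    ``elasticity_spec`` selects the demand model: ``"matrix"`` (the anchored
    age x quintile matrix), ``"uniform"`` (a single elasticity everywhere,
    default -0.4), or ``"country_specific"`` (the matrix rescaled cell-wise
    by each country's overall elasticity relative to -0.4).
    """

    price_increase: float = 0.5
    quit_share: float = 0.5
    elasticity_spec: str = "matrix"
    uniform_elasticity: float = -0.4
    country_elasticities: dict[str, float] | None = None
    include_countries: frozenset[str] | None = None
    include_female: bool = False
    female_shares: dict[str, float] = field(
        default_factory=lambda: dict(FEMALE_SMOKER_SHARES)
    )
    future_initiation_fraction: float = 0.0
    age_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.price_increase < 0:
            raise ValueError("price_increase must be non-negative")
        if not 0.0 <= self.quit_share <= 1.0:
            raise ValueError("quit_share must be in [0, 1]")
        if self.elasticity_spec not in ("matrix", "uniform", "country_specific"):
            raise ValueError(f"unknown elasticity_spec {self.elasticity_spec!r}")


def build_elasticity_matrix(
    anchor_young_bottom: float = -1.27,
    anchor_old_top: float = -0.24,
    age_ratio: float = 2.0,
    n_quintiles: int = 5,
) -> ElasticityMatrix:
    """Anchored geometric elasticity matrix.

    The older-age row runs geometrically from anchor_young_bottom/age_ratio
    at the poorest quintile to anchor_old_top at the richest; the young row
    is age_ratio times the older row with its bottom cell pinned exactly to
    anchor_young_bottom.  Entries are reported to 4 decimals.
    """
    if anchor_young_bottom >= 0 or anchor_old_top >= 0:
        raise ValueError("elasticity anchors must be negative")
    if age_ratio <= 0:
        raise ValueError("age_ratio must be positive")
    old_bottom = anchor_young_bottom / age_ratio
    ratio = (anchor_old_top / old_bottom) ** (1.0 / (n_quintiles - 1))
    old = old_bottom * ratio ** np.arange(n_quintiles)
    young = age_ratio * old
    young[0] = anchor_young_bottom
    return ElasticityMatrix(values=np.round(np.vstack([young, old]), 4))


def uniform_matrix(elasticity: float = -0.4) -> ElasticityMatrix:
    """Flat matrix: the same elasticity in every age group and quintile."""
    if elasticity > 0:
        raise ValueError("elasticity must be <= 0")
    return ElasticityMatrix(values=np.full((2, 5), float(elasticity)),
                            mean_target=float(elasticity))


def scale_matrix(matrix: ElasticityMatrix, country_elasticity: float,
                 reference: float = -0.4) -> ElasticityMatrix:
    """Rescale all cells by a country's overall elasticity relative to the reference."""
    if country_elasticity >= 0:
        raise ValueError("country elasticity must be negative")
    return ElasticityMatrix(values=matrix.values * (country_elasticity / reference),
                            mean_target=country_elasticity)


def scenario_matrix(scenario: Scenario, country: str) -> ElasticityMatrix:
    """The elasticity matrix a scenario prescribes for one country."""
    if scenario.elasticity_spec == "uniform":
        return uniform_matrix(scenario.uniform_elasticity)
    base = build_elasticity_matrix()
    if scenario.elasticity_spec == "country_specific":
        if not scenario.country_elasticities or country not in scenario.country_elasticities:
            raise ValueError(f"no country elasticity provided for {country}")
        return scale_matrix(base, scenario.country_elasticities[country])
    return base


def effective_elasticity(
    matrix: ElasticityMatrix,
    age_band: str | FutureCohort,
    quintile: int,
) -> float:
    """Matrix cell for a 5-year age band (or a future cohort, mapped to the young group)."""
    if quintile not in QUINTILES:
        raise ValueError(f"quintile must be 1-5, got {quintile}")
    if isinstance(age_band, FutureCohort):
        group = "15-24"
    else:
        lo = int(age_band.split("-")[0])
        if not 15 <= lo < 90:
            raise ValueError(f"unknown age band {age_band!r}")
        group = "15-24" if age_band in YOUNG_BANDS else "25+"
    return matrix.cell(group, quintile)


def quit_fraction(elasticity: float, price_increase: float, quit_share: float) -> float:
    """Fraction of smokers who quit: |elasticity| x price rise x quit share, capped at 1."""
    if price_increase < 0:
        raise ValueError("price_increase must be non-negative")
    return min(1.0, abs(elasticity) * price_increase * quit_share)


def intensity_reduction(elasticity: float, price_increase: float, quit_share: float) -> float:
    """Fractional fall in sticks/day among continuing smokers (the non-quit response)."""
    if price_increase < 0:
        raise ValueError("price_increase must be non-negative")
    return min(1.0, abs(elasticity) * price_increase * (1.0 - quit_share))


def quitters_by_stratum(
    strata: list[PopulationStratum],
    matrix: ElasticityMatrix,
    scenario: Scenario,
) -> pd.DataFrame:
    """Per-stratum quitters (millions).

    Returns a DataFrame with one row per stratum: country, age_band,
    quintile, smokers, elasticity, quit fraction and quitters.
    """
    rows = []
    for s in strata:
        eps = effective_elasticity(matrix, s.age_band, s.quintile)
        qf = quit_fraction(eps, scenario.price_increase, scenario.quit_share)
        rows.append({
            "country": s.country,
            "age_band": s.age_band,
            "quintile": s.quintile,
            "smokers": s.smokers,
            "sticks_per_day": s.sticks_per_day,
            "elasticity": eps,
            "quit_fraction": qf,
            "quitters": s.smokers * qf,
        })
    return pd.DataFrame(rows)


def smoker_weighted_mean_elasticity(quitters: pd.DataFrame) -> float:
    """Realized smoker-weighted mean of the applied elasticities."""
    w = quitters["smokers"].to_numpy()
    if w.sum() == 0:
        return float("nan")
    return float(np.average(quitters["elasticity"].to_numpy(), weights=w))
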