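"""Health benefits of cessation: life years gained and deaths averted.

Cohort studies put the life expectancy benefit of quitting at roughly 10
years for cessation before age 30, and 9, 6 and 3 years for cessation by
ages 30-44, 45-64 and 65+.  These step estimates are smoothed onto 5-year
age bands (15-90) with a monotone shape-preserving cubic (PCHIP) through
the interval midpoints, with constant extrapolation at both ends, so the
schedule never increases with age.

Smoking kills at least half of persistent smokers who start in early adult
life.  Deaths averted per quitter are scaled by the life-year schedule
relative to its maximum, anchoring the youngest quitters at the 0.5
death-aversion probability and decaying with age in proportion to the
cessation benefit.  No health benefit is credited for reduced consumption
among continuing smokers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .country_data import DISEASES
from .synthetic_population import AGE_BANDS, AGE_MIDPOINTS

#: (cessation age midpoint, life years gained) anchors for the smoothing fit.
DEFAULT_KNOTS = ((22.5, 10.0), (37.5, 9.0), (55.0, 6.0), (75.0, 3.0))


@dataclass(frozen=True)
class LifeYearSchedule:
    """Life years gained per quitter, per 5-year age band from 15 to 90."""

    knots: tuple[tuple[float, float], ...]
    grid: np.ndarray  # one value per band in AGE_BANDS

    def at_band(self, age_band: str) -> float:
        return float(self.grid[AGE_BANDS.index(age_band)])

    @property
    def max_gain(self) -> float:
        return float(self.grid.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_band": AGE_BANDS, "life_years_per_quitter": self.grid}
        )


@dataclass(frozen=True)
class MortalityModel:
    """Death risk for persistent smokers and its four-disease apportionment."""

    death_risk_if_continue: float = 0.5
    disease_mix: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.death_risk_if_continue <= 1.0:
            raise ValueError("death_risk_if_continue must be in [0, 1]")


def fit_life_year_schedule(
    knots: tuple[tuple[float, float], ...] = DEFAULT_KNOTS,
) -> LifeYearSchedule:
    """Smooth the step estimates of cessation benefit onto the 5-year grid.

    PCHIP through the knots is monotone by construction; evaluation is
    clamped to the knot span so the schedule is constant (10 and 3 years by
    default) before the first and after the last knot.
    """
    ages = np.array([k[0] for k in knots], dtype=float)
    gains = np.array([k[1] for k in knots], dtype=float)
    if np.any(np.diff(gains) >= 0):
        raise ValueError("life-year knots must be strictly decreasing with age")
    interp = PchipInterpolator(ages, gains)
    grid = interp(np.clip(AGE_MIDPOINTS, ages[0], ages[-1]))
    return LifeYearSchedule(knots=tuple(knots), grid=np.asarray(grid, dtype=float))


def life_years_gained(quitters: pd.DataFrame, schedule: LifeYearSchedule) -> pd.DataFrame:
    """Attach per-stratum life years gained (millions): quitters x schedule at band.

    The same schedule applies to every income quintile (similar proportional
    risk reductions by age are assumed across income groups).
    """
    out = quitters.copy()
    out["life_years_per_quitter"] = [
        schedule.at_band(b) for b in out["age_band"]
    ]
    out["life_years"] = out["quitters"] * out["life_years_per_quitter"]
    return out


def deaths_averted(
    quitters: pd.DataFrame,
    schedule: LifeYearSchedule,
    model: MortalityModel = MortalityModel(),
) -> pd.DataFrame:
    """Attach per-stratum smoking-attributable deaths averted (millions).

    Deaths averted = quitters x death risk x (schedule value / schedule max),
    so the youngest quitters realize the full death-aversion probability and
    older quitters a proportionally smaller one; always within [0, quitters].
    """
    out = quitters if "life_years_per_quitter" in quitters else life_years_gained(
        quitters, schedule
    )
    out = out.copy()
    out["deaths_averted"] = (
        out["quitters"]
        * model.death_risk_if_continue
        * out["life_years_per_quitter"]
        / schedule.max_gain
    )
    return out


def apportion_deaths(
    deaths: pd.DataFrame | float, disease_mix: dict[str, float]
) -> pd.DataFrame | dict[str, float]:
    """Split deaths averted across the four disease groups by the mortality mix.

    Accepts either a scalar (returns a per-disease dict) or a DataFrame with a
    ``deaths_averted`` column (returns it with one column per disease).  The
    per-disease values sum exactly to the input.
    """
    if abs(sum(disease_mix.values()) - 1.0) > 1e-9:
        raise ValueError("disease mix must sum to 1")
    if set(disease_mix) != set(DISEASES):
        raise ValueError(f"disease mix must cover exactly {DISEASES}")
    if isinstance(deaths, pd.DataFrame):
        out = deaths.copy()
        for d in DISEASES:
            out[f"deaths_{d}"] = out["deaths_averted"] * disease_mix[d]
        return out
    return {d: deaths * disease_mix[d] for d in DISEASES}
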