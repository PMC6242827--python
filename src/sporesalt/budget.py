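"""Apportioning particulate sodium between fungal spores and sea salt.

Given mass-concentration series C_spore and C_seasalt, the per-step
fungal-spore share of total sodium is

    f = (p_rich · w_spore · C_spore)
        / (p_rich · w_spore · C_spore + w_seasalt · C_seasalt)

with w_spore = 0.13 (Na dry-mass fraction of sodium-rich spores),
w_seasalt = 0.30 (sea salt), and p_rich the assumed fraction of spores that
are sodium-rich (0.70 by default; 0.30 and 0.50 as sensitivity cases).

Seasonal summaries average *per-step fractions* (on heterogeneous series
this differs from the fraction of mean masses; both are exposed).
Uncertainty bounds recompute every per-step fraction with spore mass
divided/multiplied by ``spore_factor`` (10) while sea salt is multiplied/
divided by ``seasalt_factor`` (2), then average — per-step dominance makes
``bound_low <= mean <= bound_high`` exact, not statistical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class BudgetParams:
    """Sodium-budget constants.

    ``night_window`` is half-open: hours h with h >= 18 or h < 6 are night.
    """

    w_na_spore: float = 0.13
    w_na_seasalt: float = 0.30
    p_rich: float = 0.70
    spore_factor: float = 10.0
    seasalt_factor: float = 2.0
    night_window: tuple[int, int] = (18, 6)

    def __post_init__(self) -> None:
        for name in ("w_na_spore", "w_na_seasalt", "p_rich"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.spore_factor <= 1 or self.seasalt_factor <= 1:
            raise ValueError("bound factors must exceed 1")


@dataclass
class BudgetResult:
    """Seasonal sodium-budget summary for one series."""

    mean_fraction: float
    bound_low: float
    bound_high: float
    sensitivity: Mapping[float, float]
    pct_days_ge_threshold: float
    threshold: float
    n_steps: int
    diel: pd.DataFrame | None = None


def sodium_fraction(c_spore, c_seasalt, params: BudgetParams | None = None,
                    p_rich: float | None = None):
    """Per-step fungal-spore fraction of total sodium mass.

    Vectorized; steps where both concentrations are zero are undefined and
    returned as NaN with a warning.
    """
    params = params or BudgetParams()
    p = params.p_rich if p_rich is None else p_rich
    cs = np.asarray(c_spore, dtype=float)
    css = np.asarray(c_seasalt, dtype=float)
    if np.any(cs < 0) or np.any(css < 0):
        raise ValueError("concentrations must be nonnegative")
    spore_na = p * params.w_na_spore * cs
    sea_na = params.w_na_seasalt * css
    total = spore_na + sea_na
    undefined = total == 0
    if np.any(undefined):
        warnings.warn("step(s) with zero total sodium: fraction undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(undefined, np.nan, spore_na / np.where(undefined, 1.0, total))
    if np.isscalar(c_spore) and np.isscalar(c_seasalt):
        return float(f)
    return f


def _series_fractions(series: pd.DataFrame, params: BudgetParams,
                      p_rich: float | None = None,
                      spore_scale: float = 1.0,
                      seasalt_scale: float = 1.0) -> np.ndarray:
    if series.empty:
        raise ValueError("empty concentration series")
    return sodium_fraction(series["spore_ugm3"].to_numpy() * spore_scale,
                           series["seasalt_ugm3"].to_numpy() * seasalt_scale,
                           params, p_rich=p_rich)


def mean_fraction(series: pd.DataFrame,
                  params: BudgetParams | None = None,
                  p_rich: float | None = None) -> float:
    """Seasonal mean of per-step sodium fractions."""
    params = params or BudgetParams()
    return float(np.nanmean(_series_fractions(series, params, p_rich)))


def fraction_of_mean_masses(series: pd.DataFrame,
                            params: BudgetParams | None = None) -> float:
    """Alternative diagnostic: fraction computed from season-mean masses.

    Differs from :func:`mean_fraction` on heterogeneous series (Jensen);
    exposed for comparison, not used in the headline summaries.
    """
    params = params or BudgetParams()
    if series.empty:
        raise ValueError("empty concentration series")
    return float(sodium_fraction(series["spore_ugm3"].mean(),
                                 series["seasalt_ugm3"].mean(), params))


def bounds(series: pd.DataFrame,
           params: BudgetParams | None = None) -> tuple[float, float]:
    """Lower/upper bounds on the mean fraction.

    Low: spores ÷ spore_factor and sea salt × seasalt_factor; high: the
    reverse.  Per-step recomputation then averaging makes the bracket
    ``low <= mean <= high`` hold exactly on every series.
    """
    params = params or BudgetParams()
    low = np.nanmean(_series_fractions(
        series, params, spore_scale=1.0 / params.spore_factor,
        seasalt_scale=params.seasalt_factor))
    high = np.nanmean(_series_fractions(
        series, params, spore_scale=params.spore_factor,
        seasalt_scale=1.0 / params.seasalt_factor))
    return float(low), float(high)


def sensitivity_p_rich(series: pd.DataFrame,
                       params: BudgetParams | None = None,
                       p_values: Sequence[float] = (0.3, 0.5, 0.7)
                       ) -> dict[float, float]:
    """Mean fraction under alternative sodium-rich spore fractions."""
    params = params or BudgetParams()
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p_rich values must lie in (0, 1], got {p}")
    return {float(p): mean_fraction(series, params, p_rich=p) for p in p_values}


def _daily_fractions(series: pd.DataFrame, params: BudgetParams) -> pd.Series:
    f = _series_fractions(series, params)
    return pd.Series(f, index=series.index).groupby(series["date"]).mean()


def pct_days_above(series: pd.DataFrame,
                   params: BudgetParams | None = None,
                   threshold: float = 0.5) -> float:
    """Percentage of days whose mean sodium fraction reaches ``threshold``.

    Sub-daily steps are first averaged to daily mean fractions.
    """
    params = params or BudgetParams()
    daily = _daily_fractions(series, params).dropna()
    if daily.empty:
        raise ValueError("no days with a defined sodium fraction")
    return float(100.0 * (daily >= threshold).mean())


def _is_night(hours: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    start, end = window
    if start > end:  # wraps midnight, e.g. [18, 6)
        return (hours >= start) | (hours < end)
    return (hours >= start) & (hours < end)


def diel_split(series: pd.DataFrame,
               params: BudgetParams | None = None) -> pd.DataFrame:
    """Night vs day distribution summary of per-step sodium fractions.

    Requires sub-daily timestamps (an ``hour`` column with values); night
    is the half-open window [18:00, 06:00).  Returns one row per window
    with median, quartiles, range and count — the statistics of a
    violin-plot summary.
    """
    params = params or BudgetParams()
    if "hour" not in series.columns or series["hour"].isna().all():
        raise ValueError(
            "diel split needs sub-daily resolution; use daily statistics "
            "(mean_fraction, pct_days_above) for daily series")
    sub = series.dropna(subset=["hour"])
    f = _series_fractions(sub, params)
    hours = sub["hour"].to_numpy(dtype=int)
    night = _is_night(hours, params.night_window)
    rows = []
    for name, sel in (("night", night), ("day", ~night)):
        vals = f[sel]
        vals = vals[~np.isnan(vals)]
        rows.append({
            "window": name,
            "median": float(np.median(vals)),
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": int(vals.size),
        })
    return pd.DataFrame(rows)


def grid_map(grid_series: pd.DataFrame,
             params: BudgetParams | None = None,
             threshold: float = 0.5) -> pd.DataFrame:
    """Per-cell percentage of days at or above the threshold fraction.

    One row per cell, ordered by ``cell_id`` for reproducibility.
    """
    params = params or BudgetParams()
    rows = []
    for cell, sub in grid_series.groupby("cell_id", sort=True):
        rows.append({"cell_id": cell,
                     "pct_days_ge_threshold":
                         pct_days_above(sub, params, threshold)})
    return pd.DataFrame(rows)


def budget_result(series: pd.DataFrame,
                  params: BudgetParams | None = None,
                  threshold: float = 0.5,
                  p_values: Sequence[float] = (0.3, 0.5, 0.7)) -> BudgetResult:
    """Full seasonal budget summary for one series."""
    params = params or BudgetParams()
    low, high = bounds(series, params)
    has_hours = "hour" in series.columns and series["hour"].notna().any()
    return BudgetResult(
        mean_fraction=mean_fraction(series, params),
        bound_low=low,
        bound_high=high,
        sensitivity=sensitivity_p_rich(series, params, p_values),
        pct_days_ge_threshold=pct_days_above(series, params, threshold),
        threshold=threshold,
        n_steps=len(series),
        diel=diel_split(series, params) if has_hours else None,
    )
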