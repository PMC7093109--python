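"""Time-series mechanics for decade-spaced mortality estimates.

Annualization of decade anchors by constant annual growth ratios,
backcasting before the first anchor, decade cumulation, lagged
cigarettes-per-death ratios, and share-of-total summaries.  Series carry
unit metadata; operations combining two series treat unit mismatch as a
hard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "DecadeSeries",
    "SalesSeries",
    "PeriodTotal",
    "LagRatioReport",
    "TrendsError",
    "DegenerateRatioError",
    "ArityError",
    "AlignmentError",
    "RatioUndefinedError",
    "UnitMismatchError",
    "ZeroSalesWarning",
    "annualize",
    "backcast",
    "cumulate_decades",
    "lagged_cigarettes_per_death",
    "share_of_total",
]

DECADE = 10


class TrendsError(ValueError):
    """Base class for trend-mechanics errors."""


class DegenerateRatioError(TrendsError):
    """Geometric interpolation hit a zero anchor next to a nonzero one."""


class ArityError(TrendsError):
    """Wrong number of decadal values."""


class AlignmentError(TrendsError):
    """Sales and death windows do not line up under the requested lag."""


class RatioUndefinedError(TrendsError):
    """Cigarettes-per-death ratio undefined (zero deaths)."""


class UnitMismatchError(TrendsError):
    """Two series with different units were combined."""


class ZeroSalesWarning(UserWarning):
    """Zero cigarette sales against a nonzero death window."""


@dataclass(frozen=True)
class DecadeSeries:
    """Decade-spaced (anchor_year, value) pairs with stratum labels."""

    anchors: Tuple[Tuple[int, float], ...]
    country: str = ""
    sex: str = ""
    metric: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.anchors) < 1:
            raise TrendsError("decade series needs at least one anchor")
        years = [y for y, _ in self.anchors]
        for y0, y1 in zip(years, years[1:]):
            if y1 - y0 != DECADE:
                raise TrendsError(f"anchor years must be spaced {DECADE} apart: {years}")
        for _, v in self.anchors:
            if v < 0:
                raise TrendsError(f"anchor values must be non-negative: {self.anchors}")

    @property
    def years(self) -> Tuple[int, ...]:
        return tuple(y for y, _ in self.anchors)

    @property
    def values(self) -> Tuple[float, ...]:
        return tuple(v for _, v in self.anchors)

    def scaled(self, c: float) -> "DecadeSeries":
        return DecadeSeries(
            tuple((y, v * c) for y, v in self.anchors),
            country=self.country,
            sex=self.sex,
            metric=self.metric,
            unit=self.unit,
        )


@dataclass(frozen=True)
class PeriodTotal:
    """A quantity aggregated over calendar years [start_year, end_year]."""

    start_year: int
    end_year: int
    total: float

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise TrendsError(f"period inverted: {self.start_year}-{self.end_year}")
        if self.total < 0:
            raise TrendsError(f"period total must be non-negative, got {self.total}")


@dataclass(frozen=True)
class SalesSeries:
    """Cigarettes sold (absolute sticks) per country: annual and/or period total."""

    country: str = ""
    annual: Optional[pd.Series] = None
    period: Optional[PeriodTotal] = None

    def __post_init__(self) -> None:
        if self.annual is None and self.period is None:
            raise TrendsError("sales series needs annual data or a period total")
        if self.annual is not None and (self.annual < 0).any():
            raise TrendsError("annual sales must be non-negative")
        if self.annual is not None and self.period is not None:
            window = self.annual.loc[self.period.start_year : self.period.end_year]
            if len(window) == self.period.end_year - self.period.start_year + 1:
                if not math.isclose(float(window.sum()), self.period.total, rel_tol=1e-6):
                    raise TrendsError(
                        f"period total {self.period.total} inconsistent with annual sum "
                        f"{float(window.sum())}"
                    )


def _interval_values(y0: int, v0: float, v1: float, mode: str) -> np.ndarray:
    """Values for years y0..y0+9 within one decade interval."""
    k = np.arange(DECADE)
    if mode == "linear":
        return v0 + (v1 - v0) * k / DECADE
    if mode != "geometric":
        raise TrendsError(f"unknown interpolation mode {mode!r}")
    if (v0 == 0) != (v1 == 0):
        raise DegenerateRatioError(
            f"zero anchor adjacent to nonzero one at {y0}; use mode='linear'"
        )
    if v0 == 0:
        return np.zeros(DECADE)
    ratio = (v1 / v0) ** (1.0 / DECADE)
    return v0 * ratio**k


def annualize(series: DecadeSeries, mode: str = "geometric") -> pd.Series:
    """Annual series through the decade anchors.

    ``geometric`` (default) applies a constant annual growth ratio
    ``(v_next / v_prev) ** (1/10)`` within each interval, matching the
    multiplicative annual-rate-of-change convention for mortality
    series; ``linear`` interpolates additively and tolerates zeros.
    Anchor years reproduce anchor values exactly.
    """
    if len(series.anchors) < 2:
        raise TrendsError("annualize needs at least two anchors")
    pieces = []
    for (y0, v0), (_, v1) in zip(series.anchors, series.anchors[1:]):
        pieces.append(pd.Series(_interval_values(y0, v0, v1, mode), index=range(y0, y0 + DECADE)))
    last_year, last_value = series.anchors[-1]
    pieces.append(pd.Series([last_value], index=[last_year]))
    out = pd.concat(pieces)
    out.name = series.metric or "value"
    return out


def backcast(series: DecadeSeries, to_year: int, mode: str = "geometric") -> pd.Series:
    """Annualized series extended back to ``to_year``.

    Years before the first anchor are filled by running the first
    interval's constant annual ratio (or linear step) in reverse.
    ``to_year`` equal to the first anchor year returns the annualized
    series unchanged.
    """
    first_year, v0 = series.anchors[0]
    if to_year > first_year:
        raise TrendsError(f"backcast target {to_year} is after the first anchor {first_year}")
    annual = annualize(series, mode=mode)
    if to_year == first_year:
        return annual
    _, v1 = series.anchors[1]
    years = np.arange(to_year, first_year)
    if mode == "linear":
        step = (v1 - v0) / DECADE
        values = v0 + step * (years - first_year)
        values = np.maximum(values, 0.0)
    else:
        if (v0 == 0) != (v1 == 0):
            raise DegenerateRatioError(
                f"zero anchor adjacent to nonzero one at {first_year}; use mode='linear'"
            )
        if v0 == 0:
            values = np.zeros(len(years))
        else:
            ratio = (v1 / v0) ** (1.0 / DECADE)
            values = v0 * ratio ** (years - first_year).astype(float)
    head = pd.Series(values, index=years)
    out = pd.concat([head, annual])
    out.name = annual.name
    return out


def cumulate_decades(decadal_values: Sequence[float]) -> float:
    """Cumulative total over six decades: ``10 * sum`` of the six
    decade-midpoint values (the 1965-2015 grid)."""
    values = list(decadal_values)
    if len(values) != 6:
        raise ArityError(f"expected exactly 6 decadal values, got {len(values)}")
    return 10.0 * float(sum(values))


@dataclass(frozen=True)
class LagRatioReport:
    """Aligned cigarettes-per-death ratio and its reciprocal."""

    cigarettes_per_death: float
    deaths_per_million_cigarettes: float
    total_sticks: float
    total_deaths: float
    lag_years: int
    sales_window: Tuple[int, int]
    deaths_window: Tuple[int, int]
    notes: Tuple[str, ...] = ()


def _as_period(obj: Union[PeriodTotal, Tuple[int, int, float]]) -> PeriodTotal:
    if isinstance(obj, PeriodTotal):
        return obj
    return PeriodTotal(*obj)


def lagged_cigarettes_per_death(
    sales: SalesSeries,
    deaths: Union[PeriodTotal, Tuple[int, int, float], pd.Series],
    lag: int = 20,
) -> LagRatioReport:
    """Cigarettes sold per (lagged) smoking-attributable death.

    The death window must equal the sales window shifted forward by
    ``lag`` years (default 20, the conventional exposure-outcome delay).
    Accepts period totals on both sides, or annual series (summed over
    the aligned overlap).  Returns both sticks-per-death and deaths per
    million cigarettes.
    """
    notes: list = []
    if isinstance(deaths, pd.Series):
        if sales.annual is None:
            raise AlignmentError("annual death series requires annual sales data")
        sales_years = sales.annual.index.to_numpy()
        wanted = sales_years + lag
        missing = set(wanted) - set(deaths.index)
        if missing:
            raise AlignmentError(
                f"death series missing lagged years: {sorted(missing)[:5]}..."
                if len(missing) > 5
                else f"death series missing lagged years: {sorted(missing)}"
            )
        total_sticks = float(sales.annual.sum())
        total_deaths = float(deaths.loc[wanted].sum())
        sales_window = (int(sales_years.min()), int(sales_years.max()))
        deaths_window = (sales_window[0] + lag, sales_window[1] + lag)
    else:
        if sales.period is None:
            raise AlignmentError("period-total deaths require a period total on the sales side")
        dper = _as_period(deaths)
        expected = (sales.period.start_year + lag, sales.period.end_year + lag)
        if (dper.start_year, dper.end_year) != expected:
            raise AlignmentError(
                f"death window {dper.start_year}-{dper.end_year} does not equal sales window "
                f"shifted by +{lag} years ({expected[0]}-{expected[1]})"
            )
        total_sticks = sales.period.total
        total_deaths = dper.total
        sales_window = (sales.period.start_year, sales.period.end_year)
        deaths_window = (dper.start_year, dper.end_year)

    if total_deaths == 0:
        raise RatioUndefinedError("zero deaths in the lagged window; ratio undefined")
    if total_sticks == 0:
        warnings.warn(
            "zero cigarette sales against a nonzero death window", ZeroSalesWarning, stacklevel=2
        )
        notes.append("zero sales window")
        return LagRatioReport(
            cigarettes_per_death=0.0,
            deaths_per_million_cigarettes=math.inf,
            total_sticks=0.0,
            total_deaths=total_deaths,
            lag_years=lag,
            sales_window=sales_window,
            deaths_window=deaths_window,
            notes=tuple(notes),
        )
    return LagRatioReport(
        cigarettes_per_death=total_sticks / total_deaths,
        deaths_per_million_cigarettes=total_deaths / (total_sticks / 1e6),
        total_sticks=total_sticks,
        total_deaths=total_deaths,
        lag_years=lag,
        sales_window=sales_window,
        deaths_window=deaths_window,
        notes=tuple(notes),
    )


def share_of_total(
    numerator: Union[Sequence[float], pd.Series, DecadeSeries],
    denominator: Union[Sequence[float], pd.Series, DecadeSeries],
) -> float:
    """``100 * sum(numerator) / sum(denominator)`` with unit checking."""
    if isinstance(numerator, DecadeSeries) and isinstance(denominator, DecadeSeries):
        if numerator.unit != denominator.unit:
            raise UnitMismatchError(
                f"unit mismatch: {numerator.unit!r} vs {denominator.unit!r}"
            )
    num = numerator.values if isinstance(numerator, DecadeSeries) else numerator
    den = denominator.values if isinstance(denominator, DecadeSeries) else denominator
    total = float(np.sum(np.asarray(den, dtype=float)))
    if total == 0:
        raise ZeroDivisionError("share_of_total: denominator sums to zero")
    return 100.0 * float(np.sum(np.asarray(num, dtype=float))) / total
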