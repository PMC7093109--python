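"""Bundled published-table inputs.

Small CSVs of the printed decade-spaced smoking-attributable death
series, the 2000/2015 prevalence and daily-amount table, and cumulative
cigarette-sales totals for the US, UK and Canada.  These are *inputs* to
the toolkit (every downstream number is recomputed from them), packaged
so that tests and reports run without external files.

The decade series store their last anchor under 2015 even where the
source reported a 2013 value for data-availability reasons; the
cumulation rule operates on the 1965-2015 decade grid.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .trends import DecadeSeries, PeriodTotal, SalesSeries

__all__ = [
    "COUNTRIES",
    "load_table2_decades",
    "load_table1_smoking",
    "load_sales_totals",
    "decade_series",
    "cumulation_values",
]

COUNTRIES = ("US", "UK", "Canada")

#: Decade grid used for cumulative 1960-2020 totals.
CUMULATION_YEARS = (1965, 1975, 1985, 1995, 2005, 2015)


def _read(name: str) -> pd.DataFrame:
    with resources.files("smokemort.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_table2_decades() -> pd.DataFrame:
    """Decade-spaced attributable/total death series (thousands)."""
    return _read("table2_decades.csv")


def load_table1_smoking() -> pd.DataFrame:
    """Adult smoking prevalence (%) and daily amount, 2000 and 2015."""
    return _read("table1_smoking.csv")


def load_sales_totals() -> Dict[str, SalesSeries]:
    """Cumulative cigarette sales (absolute sticks) per country."""
    df = _read("cigarette_sales_totals.csv")
    return {
        row["country"]: SalesSeries(
            country=row["country"],
            period=PeriodTotal(int(row["start_year"]), int(row["end_year"]), float(row["total_sticks"])),
        )
        for _, row in df.iterrows()
    }


def decade_series(country: str, sex: str, metric: str) -> DecadeSeries:
    """One stratum's decade series as a :class:`DecadeSeries`."""
    df = load_table2_decades()
    sub = df[(df["country"] == country) & (df["sex"] == sex) & (df["metric"] == metric)]
    if sub.empty:
        raise KeyError(f"no decade series for ({country}, {sex}, {metric})")
    sub = sub.sort_values("year")
    return DecadeSeries(
        anchors=tuple((int(y), float(v)) for y, v in zip(sub["year"], sub["value"])),
        country=country,
        sex=sex,
        metric=metric,
        unit=str(sub["unit"].iloc[0]),
    )


def cumulation_values(country: str, sex: str, metric: str) -> List[float]:
    """The six decade-midpoint values (1965-2015) feeding the cumulative total."""
    series = decade_series(country, sex, metric)
    by_year = dict(series.anchors)
    return [by_year[y] for y in CUMULATION_YEARS]
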