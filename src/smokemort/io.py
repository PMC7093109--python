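"""CSV ingest/egress, label normalization, run configuration and the
end-to-end summation report.

Dialect: comma-separated UTF-8 with a mandatory header row and ``.`` as
the decimal separator.  Thousands separators are rejected.  Sex labels
and en-dash age ranges are normalized to the controlled vocabulary at
ingest; unknown labels are errors, not guesses.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (
    AttributionResult,
    ReferenceRateTable,
    ReferenceRates,
    attribute_all,
)
from .riskmath import (
    CAUSES,
    AgeBand,
    RelativeRiskEntry,
    attributable_fraction,
    excess_risk_reduction,
)
from .trends import (
    DecadeSeries,
    PeriodTotal,
    SalesSeries,
    UnitMismatchError,
    cumulate_decades,
    lagged_cigarettes_per_death,
)

logger = logging.getLogger("smokemort")

__all__ = [
    "SchemaError",
    "EmptyInputWarning",
    "RunConfig",
    "normalize_sex",
    "read_mortality_csv",
    "read_rr_csv",
    "read_reference_rates_csv",
    "read_decade_series_csv",
    "read_sales_csv",
    "write_attribution_csv",
    "load_run_config",
    "run_summation",
]

_SEX_ALIASES = {
    "m": "male",
    "male": "male",
    "males": "male",
    "men": "male",
    "f": "female",
    "female": "female",
    "females": "female",
    "women": "female",
}


class SchemaError(ValueError):
    """CSV schema violation with per-row diagnostics."""

    def __init__(self, path, problems: List[str]):
        self.path = str(path)
        self.problems = problems
        lines = "\n  ".join(problems[:20])
        more = "" if len(problems) <= 20 else f"\n  ... and {len(problems) - 20} more"
        super().__init__(f"{path}: schema violations:\n  {lines}{more}")


class EmptyInputWarning(UserWarning):
    """An input file parsed correctly but contained zero data rows."""


def normalize_sex(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValueError(f"unknown sex label {label!r}")
    return _SEX_ALIASES[key]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(path, [f"missing columns: {sorted(missing)}"])


def _read_csv(path) -> pd.DataFrame:
    # thousands separators are deliberately NOT accepted
    return pd.read_csv(path, dtype=str, keep_default_na=True, skipinitialspace=True)


def _to_float(value, row: int, col: str, problems: List[str], allow_empty=False):
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        if allow_empty:
            return None
        problems.append(f"row {row}: {col} is empty")
        return None
    text = str(value).strip()
    if " " in text or "," in text:
        problems.append(f"row {row}: {col}={text!r} contains a thousands separator")
        return None
    try:
        return float(text)
    except ValueError:
        problems.append(f"row {row}: {col}={text!r} is not a number")
        return None


def read_mortality_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a mortality table.

    Columns: country, sex, age_lo, age_hi (empty = open-ended), cause,
    year, deaths, population (optional).  Checks the controlled cause
    vocabulary and that cause-specific deaths never exceed the
    ``all_causes`` row of their stratum.
    """
    raw = _read_csv(path)
    _require_columns(raw, ["country", "sex", "age_lo", "age_hi", "cause", "year", "deaths"], path)
    problems: List[str] = []
    rows = []
    for i, rec in raw.iterrows():
        line = i + 2  # header is line 1
        try:
            sex = normalize_sex(rec["sex"])
        except ValueError as exc:
            problems.append(f"row {line}: {exc}")
            continue
        cause = str(rec["cause"]).strip()
        if cause not in CAUSES:
            problems.append(f"row {line}: unknown cause {cause!r}")
            continue
        age_lo = _to_float(rec["age_lo"], line, "age_lo", problems)
        age_hi = _to_float(rec.get("age_hi"), line, "age_hi", problems, allow_empty=True)
        year = _to_float(rec["year"], line, "year", problems)
        deaths = _to_float(rec["deaths"], line, "deaths", problems)
        population = (
            _to_float(rec.get("population"), line, "population", problems, allow_empty=True)
            if "population" in raw.columns
            else None
        )
        if deaths is not None and deaths < 0:
            problems.append(f"row {line}: deaths < 0")
        if population is not None and population <= 0:
            problems.append(f"row {line}: population <= 0")
        if problems and problems[-1].startswith(f"row {line}"):
            continue
        rows.append(
            {
                "country": str(rec["country"]).strip(),
                "sex": sex,
                "age_lo": age_lo,
                "age_hi": np.nan if age_hi is None else age_hi,
                "cause": cause,
                "year": int(year),
                "deaths": deaths,
                "population": np.nan if population is None else population,
            }
        )
    if problems:
        raise SchemaError(path, problems)
    df = pd.DataFrame(
        rows,
        columns=["country", "sex", "age_lo", "age_hi", "cause", "year", "deaths", "population"],
    )
    if df.empty:
        warnings.warn(f"{path}: zero data rows", EmptyInputWarning, stacklevel=2)
        return df
    # stratum consistency: cause-specific sum <= all_causes (tiny float slack)
    for key, grp in df.groupby(["country", "sex", "age_lo", "age_hi", "year"], dropna=False):
        all_rows = grp[grp["cause"] == "all_causes"]
        if all_rows.empty:
            continue
        specific = grp[grp["cause"] != "all_causes"]["deaths"].sum()
        total = float(all_rows["deaths"].iloc[0])
        if specific > total * (1 + 1e-9) + 1e-9:
            problems.append(
                f"stratum {key}: cause-specific deaths {specific} exceed all_causes {total}"
            )
    if problems:
        raise SchemaError(path, problems)
    return df


def read_rr_csv(path: Union[str, Path]) -> List[RelativeRiskEntry]:
    """Relative-risk table: cause, sex, age_lo, age_hi, rr_current,
    rr_former (empty permitted).  Age bands within one (cause, sex) table
    must not overlap."""
    raw = _read_csv(path)
    _require_columns(raw, ["cause", "sex", "age_lo", "age_hi", "rr_current"], path)
    problems: List[str] = []
    entries: List[RelativeRiskEntry] = []
    for i, rec in raw.iterrows():
        line = i + 2
        try:
            sex = normalize_sex(rec["sex"])
            age_lo = _to_float(rec["age_lo"], line, "age_lo", problems)
            age_hi = _to_float(rec.get("age_hi"), line, "age_hi", problems, allow_empty=True)
            rr_c = _to_float(rec["rr_current"], line, "rr_current", problems)
            rr_f = _to_float(rec.get("rr_former"), line, "rr_former", problems, allow_empty=True)
            if age_lo is None or rr_c is None:
                continue
            entries.append(
                RelativeRiskEntry(
                    cause=str(rec["cause"]).strip(),
                    sex=sex,
                    age_band=AgeBand(age_lo, age_hi),
                    rr_current=rr_c,
                    rr_former=rr_f,
                )
            )
        except ValueError as exc:
            problems.append(f"row {line}: {exc}")
    if problems:
        raise SchemaError(path, problems)
    by_table: Dict[Tuple[str, str], List[AgeBand]] = {}
    for e in entries:
        bands = by_table.setdefault((e.cause, e.sex), [])
        for b in bands:
            if e.age_band.overlaps(b):
                problems.append(f"overlapping age bands for ({e.cause}, {e.sex}): {b} and {e.age_band}")
        bands.append(e.age_band)
    if problems:
        raise SchemaError(path, problems)
    if not entries:
        warnings.warn(f"{path}: zero data rows", EmptyInputWarning, stacklevel=2)
    return entries


def read_reference_rates_csv(
    path: Union[str, Path], rate_scale: float = 100_000.0
) -> ReferenceRateTable:
    """Reference-rate table: sex, age_lo, age_hi, never_rate_population,
    smoker_rate_study, never_rate_study.

    Input rates are per ``rate_scale`` person-years (default 100,000) and
    converted to per person-year internally.
    """
    raw = _read_csv(path)
    _require_columns(
        raw,
        ["sex", "age_lo", "age_hi", "never_rate_population", "smoker_rate_study", "never_rate_study"],
        path,
    )
    problems: List[str] = []
    table = ReferenceRateTable()
    for i, rec in raw.iterrows():
        line = i + 2
        try:
            sex = normalize_sex(rec["sex"])
            age_lo = _to_float(rec["age_lo"], line, "age_lo", problems)
            age_hi = _to_float(rec.get("age_hi"), line, "age_hi", problems, allow_empty=True)
            nrp = _to_float(rec["never_rate_population"], line, "never_rate_population", problems)
            srs = _to_float(rec["smoker_rate_study"], line, "smoker_rate_study", problems)
            nrs = _to_float(rec["never_rate_study"], line, "never_rate_study", problems)
            if None in (age_lo, nrp, srs, nrs):
                continue
            table.add(
                sex,
                AgeBand(age_lo, age_hi),
                ReferenceRates(
                    never_rate_population=nrp / rate_scale,
                    smoker_rate_study=srs / rate_scale,
                    never_rate_study=nrs / rate_scale,
                ),
            )
        except ValueError as exc:
            problems.append(f"row {line}: {exc}")
    if problems:
        raise SchemaError(path, problems)
    return table


def read_decade_series_csv(path: Union[str, Path]) -> List[DecadeSeries]:
    """Series CSV (country, sex, metric, year, value, unit) grouped into
    :class:`DecadeSeries` per (country, sex, metric)."""
    raw = _read_csv(path)
    _require_columns(raw, ["country", "sex", "metric", "year", "value", "unit"], path)
    problems: List[str] = []
    parsed = []
    for i, rec in raw.iterrows():
        line = i + 2
        try:
            sex = normalize_sex(rec["sex"])
        except ValueError as exc:
            problems.append(f"row {line}: {exc}")
            continue
        year = _to_float(rec["year"], line, "year", problems)
        value = _to_float(rec["value"], line, "value", problems)
        if year is None or value is None:
            continue
        parsed.append(
            (str(rec["country"]).strip(), sex, str(rec["metric"]).strip(), int(year), value,
             str(rec["unit"]).strip())
        )
    if problems:
        raise SchemaError(path, problems)
    if not parsed:
        warnings.warn(f"{path}: zero data rows", EmptyInputWarning, stacklevel=2)
        return []
    df = pd.DataFrame(parsed, columns=["country", "sex", "metric", "year", "value", "unit"])
    out = []
    for (country, sex, metric), grp in df.groupby(["country", "sex", "metric"], sort=True):
        units = set(grp["unit"])
        if len(units) > 1:
            raise UnitMismatchError(f"series ({country}, {sex}, {metric}) mixes units {sorted(units)}")
        grp = grp.sort_values("year")
        out.append(
            DecadeSeries(
                anchors=tuple((int(y), float(v)) for y, v in zip(grp["year"], grp["value"])),
                country=country,
                sex=sex,
                metric=metric,
                unit=units.pop(),
            )
        )
    return out


def read_sales_csv(path: Union[str, Path]) -> Dict[str, SalesSeries]:
    """Sales CSV with either period totals (country, start_year, end_year,
    total_sticks) or annual rows (country, year, cigarettes_sold)."""
    raw = _read_csv(path)
    if {"start_year", "end_year", "total_sticks"} <= set(raw.columns):
        out = {}
        for _, rec in raw.iterrows():
            out[str(rec["country"]).strip()] = SalesSeries(
                country=str(rec["country"]).strip(),
                period=PeriodTotal(
                    int(float(rec["start_year"])),
                    int(float(rec["end_year"])),
                    float(rec["total_sticks"]),
                ),
            )
        return out
    _require_columns(raw, ["country", "year", "cigarettes_sold"], path)
    out = {}
    for country, grp in raw.groupby("country"):
        series = pd.Series(
            grp["cigarettes_sold"].astype(float).to_numpy(),
            index=grp["year"].astype(float).astype(int).to_numpy(),
        ).sort_index()
        out[str(country).strip()] = SalesSeries(country=str(country).strip(), annual=series)
    return out


def _stamp(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["version"] = __version__
    return df


def write_attribution_csv(result: AttributionResult, path: Union[str, Path]) -> None:
    table = _stamp(result.table)
    table["halve_non_lung"] = result.halve_non_lung
    table.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration for the end-to-end summation report.

    All input paths are optional; each present input enables the
    corresponding output.  ``deaths_unit`` declares how the decade
    series' death counts are scaled ('thousand' or 'unit');
    ``rate_scale`` is the per-person-year divisor of reference-rate CSVs.
    """

    out_dir: Path
    series_csv: Optional[Path] = None
    rr_csv: Optional[Path] = None
    sales_csv: Optional[Path] = None
    mortality_csv: Optional[Path] = None
    refs_csv: Optional[Path] = None
    deaths_unit: str = "thousand"
    rate_scale: float = 100_000.0
    halve_non_lung: bool = True
    lag_years: int = 20
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        problems = []
        for name in ("series_csv", "rr_csv", "sales_csv", "mortality_csv", "refs_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name}: path does not exist: {p}")
        if self.deaths_unit not in ("thousand", "unit"):
            problems.append(f"deaths_unit: must be 'thousand' or 'unit', got {self.deaths_unit!r}")
        if self.lag_years < 0:
            problems.append(f"lag_years: must be >= 0, got {self.lag_years}")
        if problems:
            raise ValueError("invalid run config: " + "; ".join(problems))


def load_run_config(path: Union[str, Path]) -> RunConfig:
    path = Path(path)
    data = (
        yaml.safe_load(path.read_text())
        if path.suffix.lower() in (".yaml", ".yml")
        else json.loads(path.read_text())
    )
    base = path.parent

    def _p(key):
        return (base / data[key]).resolve() if data.get(key) else None

    return RunConfig(
        out_dir=Path(data.get("out_dir", ".")),
        series_csv=_p("series_csv"),
        rr_csv=_p("rr_csv"),
        sales_csv=_p("sales_csv"),
        mortality_csv=_p("mortality_csv"),
        refs_csv=_p("refs_csv"),
        deaths_unit=data.get("deaths_unit", "thousand"),
        rate_scale=float(data.get("rate_scale", 100_000.0)),
        halve_non_lung=bool(data.get("halve_non_lung", True)),
        lag_years=int(data.get("lag_years", 20)),
        seed=int(data.get("seed", 0)),
        verbosity=data.get("verbosity", "INFO"),
    )


def run_summation(config: RunConfig) -> Dict[str, Path]:
    """Run every pipeline stage whose inputs are configured.

    Emits, under ``config.out_dir``: cumulative attributable totals per
    country/sex, an avoidable-fraction (and former-smoker reduction)
    table, a lagged cigarettes-per-death report, and a per-cause
    attribution table.  Outputs are deterministic for a fixed config;
    every row carries the package version.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    unit_factor = 1000.0 if config.deaths_unit == "thousand" else 1.0

    cumulative_df = None
    if config.series_csv is not None:
        series_list = read_decade_series_csv(config.series_csv)
        rows = []
        for s in series_list:
            by_year = dict(s.anchors)
            try:
                values = [by_year[y] for y in (1965, 1975, 1985, 1995, 2005, 2015)]
            except KeyError as exc:
                raise ValueError(
                    f"series ({s.country}, {s.sex}, {s.metric}) lacks decade anchor {exc}"
                ) from None
            rows.append(
                {
                    "country": s.country,
                    "sex": s.sex,
                    "metric": s.metric,
                    "cumulative_1960_2020": cumulate_decades(values),
                    "unit": s.unit,
                }
            )
        cumulative_df = pd.DataFrame(rows)
        if cumulative_df.empty:
            warnings.warn("series input produced zero rows", EmptyInputWarning, stacklevel=2)
        else:
            grand = (
                cumulative_df.groupby(["country", "metric"], as_index=False)["cumulative_1960_2020"]
                .sum()
                .assign(sex="both", unit=cumulative_df["unit"].iloc[0])
            )
            cumulative_df = pd.concat([cumulative_df, grand], ignore_index=True)
            attrib = cumulative_df[
                (cumulative_df["sex"] == "both") & (cumulative_df["metric"] == "attributable")
            ]["cumulative_1960_2020"].sum()
            logger.info(
                "cumulative attributable deaths 1960-2020, all countries: %.0f %s (%.1f million)",
                attrib,
                cumulative_df["unit"].iloc[0],
                attrib * unit_factor / 1e6,
            )
        path = out_dir / "cumulative_totals.csv"
        _stamp(cumulative_df).to_csv(path, index=False)
        written["cumulative_totals"] = path

    if config.rr_csv is not None:
        entries = read_rr_csv(config.rr_csv)
        rows = []
        for e in entries:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                af = attributable_fraction(e.rr_current)
                reduction = (
                    excess_risk_reduction(e.rr_former, e.rr_current)
                    if e.rr_former is not None and e.rr_current != 1.0
                    else None
                )
            rows.append(
                {
                    "cause": e.cause,
                    "sex": e.sex,
                    "age_band": str(e.age_band),
                    "rr_current": e.rr_current,
                    "rr_former": e.rr_former,
                    "avoidable_fraction": round(af, 4),
                    "avoidable_percent": round(af * 100.0, 1),
                    "excess_risk_reduction": None if reduction is None else round(reduction, 4),
                }
            )
        df = pd.DataFrame(rows)
        if df.empty:
            warnings.warn("rr input produced zero rows", EmptyInputWarning, stacklevel=2)
        path = out_dir / "avoidable_fractions.csv"
        _stamp(df).to_csv(path, index=False)
        written["avoidable_fractions"] = path

    if config.sales_csv is not None and cumulative_df is not None and not cumulative_df.empty:
        sales = read_sales_csv(config.sales_csv)
        rows = []
        for country, s in sorted(sales.items()):
            cell = cumulative_df[
                (cumulative_df["country"] == country)
                & (cumulative_df["sex"] == "both")
                & (cumulative_df["metric"] == "attributable")
            ]
            if cell.empty or s.period is None:
                continue
            deaths_abs = float(cell["cumulative_1960_2020"].iloc[0]) * unit_factor
            report = lagged_cigarettes_per_death(
                s,
                PeriodTotal(
                    s.period.start_year + config.lag_years,
                    s.period.end_year + config.lag_years,
                    deaths_abs,
                ),
                lag=config.lag_years,
            )
            logger.info(
                "%s: %.3g cigarettes per death (%.2f deaths per million cigarettes), lag %d y",
                country,
                report.cigarettes_per_death,
                report.deaths_per_million_cigarettes,
                report.lag_years,
            )
            rows.append(
                {
                    "country": country,
                    "total_sticks": report.total_sticks,
                    "total_deaths": report.total_deaths,
                    "cigarettes_per_death": report.cigarettes_per_death,
                    "deaths_per_million_cigarettes": round(
                        report.deaths_per_million_cigarettes, 3
                    ),
                    "lag_years": report.lag_years,
                }
            )
        path = out_dir / "lag_ratios.csv"
        _stamp(pd.DataFrame(rows)).to_csv(path, index=False)
        written["lag_ratios"] = path

    if config.mortality_csv is not None:
        mortality = read_mortality_csv(config.mortality_csv)
        path = out_dir / "attribution.csv"
        if mortality.empty:
            warnings.warn("mortality input has zero rows", EmptyInputWarning, stacklevel=2)
            empty = pd.DataFrame(
                columns=[
                    "country", "sex", "age_lo", "age_hi", "year", "cause", "deaths", "sir",
                    "rr_used", "population_af", "attributable_deaths", "clamped_sir",
                    "halved_rr", "negative_floor", "version", "halve_non_lung",
                ]
            )
            empty.to_csv(path, index=False)
            written["attribution"] = path
        else:
            if config.rr_csv is None or config.refs_csv is None:
                raise ValueError("mortality attribution requires rr_csv and refs_csv")
            entries = read_rr_csv(config.rr_csv)
            refs = read_reference_rates_csv(config.refs_csv, rate_scale=config.rate_scale)
            result = attribute_all(
                mortality, entries, refs, halve_non_lung=config.halve_non_lung
            )
            write_attribution_csv(result, path)
            written["attribution"] = path

    return written
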