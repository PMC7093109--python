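"""Lung-cancer-indexed indirect attribution of deaths to smoking.

The indirect method treats a population's never-smoker-adjusted lung
cancer mortality, indexed to smoker/never-smoker lung cancer rates from a
reference prospective study, as a synthetic smoking prevalence (the
smoking impact ratio, SIR).  That prevalence is combined with
cause-specific relative risks through the standard population
attributable fraction to apportion deaths from other causes to smoking.
A conservative option halves the excess relative risk of non-lung causes
to guard against confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

import pandas as pd

from . import __version__
from .riskmath import (
    AgeBand,
    InvalidRelativeRiskError,
    InvalidProportionError,
    RelativeRiskEntry,
    attributable_fraction,
)

__all__ = [
    "ReferenceRates",
    "ReferenceRateTable",
    "AttributionResult",
    "AttributionError",
    "InvalidReferenceError",
    "CoverageError",
    "MissingDenominatorError",
    "ClampedSirWarning",
    "smoking_impact_ratio",
    "halve_excess_rr",
    "population_af",
    "attributable_deaths_lung",
    "attribute_all",
]

LUNG = "lung_cancer"
ALL_CAUSES = "all_causes"


class AttributionError(ValueError):
    """Base class for attribution-stage errors."""


class InvalidReferenceError(AttributionError):
    """Reference study rates violate smoker_rate > never_rate >= 0."""


class MissingDenominatorError(AttributionError):
    """A population denominator is required but absent."""


class CoverageError(AttributionError):
    """Needed RR entries or reference rates are missing for some strata."""

    def __init__(self, missing):
        self.missing = sorted(str(k) for k in missing)
        super().__init__("missing inputs for strata: " + "; ".join(self.missing))


class ClampedSirWarning(UserWarning):
    """A smoking impact ratio fell outside [0, 1] and was clamped."""


@dataclass(frozen=True)
class ReferenceRates:
    """Lung-cancer reference rates for one (sex, age band) stratum.

    All rates are deaths per person-year.  ``never_rate_population`` is
    the never-smoker rate in the target population; the study rates come
    from the reference prospective cohort.
    """

    never_rate_population: float
    smoker_rate_study: float
    never_rate_study: float

    def __post_init__(self) -> None:
        if self.never_rate_population < 0:
            raise InvalidReferenceError(
                f"never_rate_population must be >= 0, got {self.never_rate_population}"
            )
        if self.never_rate_study < 0:
            raise InvalidReferenceError(f"never_rate_study must be >= 0, got {self.never_rate_study}")
        if not self.smoker_rate_study > self.never_rate_study:
            raise InvalidReferenceError(
                "smoker_rate_study must exceed never_rate_study "
                f"({self.smoker_rate_study} <= {self.never_rate_study})"
            )


class ReferenceRateTable:
    """Reference rates keyed by (sex, age band); exact-key lookup only."""

    def __init__(self, entries: Mapping[Tuple[str, AgeBand], ReferenceRates] = ()):
        self._entries: Dict[Tuple[str, AgeBand], ReferenceRates] = dict(entries)

    def add(self, sex: str, age_band: AgeBand, rates: ReferenceRates) -> None:
        self._entries[(sex, age_band)] = rates

    def get(self, sex: str, age_band: AgeBand) -> Optional[ReferenceRates]:
        return self._entries.get((sex, age_band))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.items())


def smoking_impact_ratio(observed_lung_rate: float, refs: ReferenceRates) -> float:
    """Synthetic smoking prevalence from never-smoker-indexed lung cancer rates.

    ``(observed - never_population) / (smoker_study - never_study)``,
    clamped to [0, 1] with :class:`ClampedSirWarning` when outside.
    """
    sir = (observed_lung_rate - refs.never_rate_population) / (
        refs.smoker_rate_study - refs.never_rate_study
    )
    if sir < 0.0 or sir > 1.0:
        warnings.warn(
            f"smoking impact ratio {sir:.4g} outside [0, 1]; clamped",
            ClampedSirWarning,
            stacklevel=2,
        )
        sir = min(1.0, max(0.0, sir))
    return sir


def halve_excess_rr(rr: float) -> float:
    """Conservative halving of excess relative risk: ``1 + (rr - 1) / 2``."""
    if not rr > 0:
        raise InvalidRelativeRiskError(f"relative risk must be > 0, got {rr}")
    return 1.0 + (rr - 1.0) / 2.0


def population_af(sir: float, rr: float) -> float:
    """Population attributable fraction with the SIR as synthetic prevalence.

    Levin form ``sir*(rr-1) / (sir*(rr-1) + 1)``; reduces to
    ``attributable_fraction(rr)`` at ``sir == 1``.
    """
    if not 0.0 <= sir <= 1.0:
        raise InvalidProportionError(f"sir must lie in [0, 1], got {sir}")
    if not rr > 0:
        raise InvalidRelativeRiskError(f"relative risk must be > 0, got {rr}")
    excess = sir * (rr - 1.0)
    return excess / (excess + 1.0)


def attributable_deaths_lung(
    observed_deaths: float,
    refs: ReferenceRates,
    population: Optional[float],
) -> Tuple[float, bool]:
    """Lung cancer deaths above the never-smoker expectation.

    Returns ``(attributable, floored)`` where ``attributable`` is
    ``max(0, observed - never_rate_population * population)`` and
    ``floored`` reports whether the zero floor was applied.
    """
    if observed_deaths < 0:
        raise AttributionError(f"observed deaths must be >= 0, got {observed_deaths}")
    if refs.never_rate_population > 0 and population is None:
        raise MissingDenominatorError(
            "population denominator required when never_rate_population > 0"
        )
    expected_never = refs.never_rate_population * (population or 0.0)
    attributable = observed_deaths - expected_never
    floored = attributable < 0
    return (max(0.0, attributable), floored)


@dataclass
class AttributionResult:
    """Per-(stratum, cause) attribution with method metadata.

    ``table`` columns: country, sex, age_lo, age_hi, year, cause, deaths,
    sir, rr_used, population_af, attributable_deaths, clamped_sir,
    halved_rr, negative_floor.
    """

    table: pd.DataFrame
    halve_non_lung: bool
    version: str = __version__

    @property
    def total_attributable(self) -> float:
        return float(self.table["attributable_deaths"].sum())


def _rr_map(
    rrs: Union[Iterable[RelativeRiskEntry], Mapping[Tuple[str, str, AgeBand], RelativeRiskEntry]],
) -> Dict[Tuple[str, str, AgeBand], RelativeRiskEntry]:
    if isinstance(rrs, Mapping):
        return dict(rrs)
    return {e.key: e for e in rrs}


def attribute_all(
    mortality: pd.DataFrame,
    rrs: Union[Iterable[RelativeRiskEntry], Mapping[Tuple[str, str, AgeBand], RelativeRiskEntry]],
    refs: ReferenceRateTable,
    halve_non_lung: bool = True,
) -> AttributionResult:
    """Attribute deaths to smoking for every stratum and cause in a table.

    Lung cancer rows are attributed by never-smoker subtraction; every
    other cause (except ``all_causes``, which is never attributed) gets
    ``deaths * population_af(sir, rr')`` where the SIR comes from the
    stratum's lung cancer row and ``rr'`` is the (optionally halved)
    cause RR.  Missing RR entries or reference rates raise a
    :class:`CoverageError` listing every missing key before any work is
    done.
    """
    required = {"country", "sex", "age_lo", "age_hi", "cause", "year", "deaths"}
    missing_cols = required - set(mortality.columns)
    if missing_cols:
        raise AttributionError(f"mortality table missing columns: {sorted(missing_cols)}")
    has_pop = "population" in mortality.columns

    rr_by_key = _rr_map(rrs)
    stratum_cols = ["country", "sex", "age_lo", "age_hi", "year"]

    # coverage pass: collect everything missing before computing anything
    missing: list = []
    groups = []
    for key, grp in mortality.groupby(stratum_cols, sort=True, dropna=False):
        country, sex, age_lo, age_hi, year = key
        band = AgeBand(float(age_lo), None if pd.isna(age_hi) else float(age_hi))
        lung_rows = grp[grp["cause"] == LUNG]
        ref = refs.get(sex, band)
        non_lung = sorted(set(grp["cause"]) - {LUNG, ALL_CAUSES})
        if lung_rows.empty and (non_lung or ref is None):
            missing.append(f"lung_cancer row for ({country}, {sex}, {band}, {year})")
        if ref is None:
            missing.append(f"reference rates for ({sex}, {band})")
        for cause in non_lung:
            if (cause, sex, band) not in rr_by_key:
                missing.append(f"rr entry for ({cause}, {sex}, {band})")
        groups.append((key, band, grp, ref, lung_rows))
    if missing:
        raise CoverageError(set(missing))

    rows = []
    for (country, sex, age_lo, age_hi, year), band, grp, ref, lung_rows in groups:
        lung = lung_rows.iloc[0]
        lung_deaths = float(lung["deaths"])
        population = None
        if has_pop and not pd.isna(lung.get("population")):
            population = float(lung["population"])
        if population is None:
            raise MissingDenominatorError(
                f"lung_cancer row for ({country}, {sex}, {band}, {year}) has no population; "
                "a denominator is required to form the observed rate"
            )
        observed_rate = lung_deaths / population

        raw_sir = (observed_rate - ref.never_rate_population) / (
            ref.smoker_rate_study - ref.never_rate_study
        )
        clamped = raw_sir < 0.0 or raw_sir > 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampedSirWarning)
            sir = smoking_impact_ratio(observed_rate, ref)

        lung_attrib, floored = attributable_deaths_lung(lung_deaths, ref, population)
        rows.append(
            {
                "country": country,
                "sex": sex,
                "age_lo": age_lo,
                "age_hi": age_hi,
                "year": year,
                "cause": LUNG,
                "deaths": lung_deaths,
                "sir": sir,
                "rr_used": float("nan"),
                "population_af": lung_attrib / lung_deaths if lung_deaths > 0 else 0.0,
                "attributable_deaths": lung_attrib,
                "clamped_sir": clamped,
                "halved_rr": False,
                "negative_floor": floored,
            }
        )

        for _, row in grp.iterrows():
            cause = row["cause"]
            if cause in (LUNG, ALL_CAUSES):
                continue
            entry = rr_by_key[(cause, sex, band)]
            rr_used = halve_excess_rr(entry.rr_current) if halve_non_lung else entry.rr_current
            paf = population_af(sir, rr_used)
            deaths = float(row["deaths"])
            attributable = deaths * paf
            negative_floor = attributable < 0
            attributable = max(0.0, attributable)
            rows.append(
                {
                    "country": country,
                    "sex": sex,
                    "age_lo": age_lo,
                    "age_hi": age_hi,
                    "year": year,
                    "cause": cause,
                    "deaths": deaths,
                    "sir": sir,
                    "rr_used": rr_used,
                    "population_af": paf,
                    "attributable_deaths": attributable,
                    "clamped_sir": clamped,
                    "halved_rr": halve_non_lung,
                    "negative_floor": negative_floor,
                }
            )

    table = pd.DataFrame(rows)
    return AttributionResult(table=table, halve_non_lung=halve_non_lung)
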