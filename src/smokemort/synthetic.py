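"""Synthetic vital statistics with known smoking structure.

Generates stratified death-count tables from a known current/former
smoking prevalence, never-smoker baseline cause-specific rates, and
cause-specific relative risks, with optional Poisson count noise.  The
ground truth (true attributable deaths per cell, true synthetic
prevalence per stratum) travels with the output so that attribution code
can be tested by parameter recovery and exact oracles.

Former smokers are generated even though the indirect attribution method
conflates them into a single synthetic prevalence: this lets tests
measure the bias the method incurs when former-smoker prevalence is
high, rather than hiding it.

Rates are per person-year with one-year cycles and no competing-risk
depletion (populations large, risks small), matching the rate algebra
the attribution method assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .attribution import ReferenceRates, ReferenceRateTable
from .riskmath import CAUSES, SEXES, AgeBand, RelativeRiskEntry
from .trends import SalesSeries

__all__ = [
    "StratumConfig",
    "SyntheticCohortConfig",
    "SimulatedVitalStats",
    "ConfigValidationError",
    "simulate_vital_stats",
    "simulate_sales",
]

LUNG = "lung_cancer"
ALL_CAUSES = "all_causes"


class ConfigValidationError(ValueError):
    """Invalid synthetic config; lists every offending field."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid synthetic config: " + "; ".join(self.problems))


@dataclass(frozen=True)
class StratumConfig:
    country: str
    sex: str
    age_band: AgeBand
    population: int
    prevalence_current: float
    prevalence_former: float = 0.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Ground truth for a simulated population of vital statistics."""

    strata: Tuple[StratumConfig, ...]
    baseline_never_rates: Mapping[str, float]  # cause -> deaths per person-year
    rr_current: Mapping[str, float]
    rr_former: Optional[Mapping[str, float]] = None
    noise: str = "none"  # none | poisson
    seed: int = 0
    year: int = 2000

    def validate(self) -> None:
        problems = []
        if not self.strata:
            problems.append("strata: empty")
        for i, s in enumerate(self.strata):
            if s.sex not in SEXES:
                problems.append(f"strata[{i}].sex: unknown label {s.sex!r}")
            if s.population <= 0:
                problems.append(f"strata[{i}].population: must be > 0, got {s.population}")
            if not 0.0 <= s.prevalence_current <= 1.0:
                problems.append(f"strata[{i}].prevalence_current: outside [0, 1]")
            if not 0.0 <= s.prevalence_former <= 1.0:
                problems.append(f"strata[{i}].prevalence_former: outside [0, 1]")
            if s.prevalence_current + s.prevalence_former > 1.0:
                problems.append(
                    f"strata[{i}]: prevalence_current + prevalence_former > 1"
                )
        for cause, rate in self.baseline_never_rates.items():
            if cause not in CAUSES or cause == ALL_CAUSES:
                problems.append(f"baseline_never_rates[{cause!r}]: unknown cause")
            if rate < 0:
                problems.append(f"baseline_never_rates[{cause!r}]: rate < 0")
        for name, table in (("rr_current", self.rr_current), ("rr_former", self.rr_former)):
            if table is None:
                continue
            for cause, rr in table.items():
                if not rr > 0:
                    problems.append(f"{name}[{cause!r}]: rr must be > 0, got {rr}")
        missing_rr = set(self.baseline_never_rates) - set(self.rr_current)
        if missing_rr:
            problems.append(f"rr_current: missing causes {sorted(missing_rr)}")
        if any(s.prevalence_former > 0 for s in self.strata):
            missing_f = set(self.baseline_never_rates) - set(self.rr_former or {})
            if missing_f:
                problems.append(f"rr_former: missing causes {sorted(missing_f)}")
        if self.noise not in ("none", "poisson"):
            problems.append(f"noise: must be 'none' or 'poisson', got {self.noise!r}")
        if LUNG not in self.baseline_never_rates:
            problems.append("baseline_never_rates: lung_cancer rate required for SIR oracles")
        if problems:
            raise ConfigValidationError(problems)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticCohortConfig":
        strata = tuple(
            StratumConfig(
                country=s["country"],
                sex=s["sex"],
                age_band=AgeBand(float(s["age_lo"]), s.get("age_hi") and float(s["age_hi"])),
                population=int(s["population"]),
                prevalence_current=float(s["prevalence_current"]),
                prevalence_former=float(s.get("prevalence_former", 0.0)),
            )
            for s in d["strata"]
        )
        return cls(
            strata=strata,
            baseline_never_rates={k: float(v) for k, v in d["baseline_never_rates"].items()},
            rr_current={k: float(v) for k, v in d["rr_current"].items()},
            rr_former=(
                {k: float(v) for k, v in d["rr_former"].items()} if d.get("rr_former") else None
            ),
            noise=d.get("noise", "none"),
            seed=int(d.get("seed", 0)),
            year=int(d.get("year", 2000)),
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SyntheticCohortConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


@dataclass
class SimulatedVitalStats:
    """Mortality table + ground truth + the generating config."""

    mortality: pd.DataFrame
    ground_truth: pd.DataFrame  # per (stratum, cause): expected/true attributable
    strata_truth: pd.DataFrame  # per stratum: true_sir (= prevalence_current)
    config: SyntheticCohortConfig

    def reference_rates(self) -> ReferenceRateTable:
        """Reference table matching the generating process exactly.

        Study smoker/never rates are the generating lung rates, so the
        smoking impact ratio recovers the true current prevalence when
        former-smoker prevalence is zero.
        """
        n_lung = self.config.baseline_never_rates[LUNG]
        rr_lung = self.config.rr_current[LUNG]
        table = ReferenceRateTable()
        for s in self.config.strata:
            table.add(
                s.sex,
                s.age_band,
                ReferenceRates(
                    never_rate_population=n_lung,
                    smoker_rate_study=n_lung * rr_lung,
                    never_rate_study=n_lung,
                ),
            )
        return table

    def rr_entries(self):
        """RelativeRiskEntry list for the generating RRs, for attribute_all."""
        entries = []
        seen = set()
        for s in self.config.strata:
            for cause, rr in self.config.rr_current.items():
                key = (cause, s.sex, s.age_band)
                if key in seen:
                    continue
                seen.add(key)
                rr_f = (self.config.rr_former or {}).get(cause)
                entries.append(
                    RelativeRiskEntry(
                        cause=cause, sex=s.sex, age_band=s.age_band, rr_current=rr, rr_former=rr_f
                    )
                )
        return entries


def simulate_vital_stats(config: SyntheticCohortConfig) -> SimulatedVitalStats:
    """Simulate stratified death counts from known smoking structure.

    Expected deaths per cause cell are
    ``Pop * (p_c*N*RR_c + p_f*N*RR_f + (1 - p_c - p_f)*N)``; observed
    deaths equal the expectation exactly (``noise='none'``) or are
    Poisson draws with that mean (``noise='poisson'``, seeded from the
    config).  Ground truth records the smoker/former excess components.
    All randomness flows from the single config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mort_rows, truth_rows, strata_rows = [], [], []
    for s in config.strata:
        p_c, p_f = s.prevalence_current, s.prevalence_former
        p_n = 1.0 - p_c - p_f
        cell_expected: Dict[str, float] = {}
        cell_truth: Dict[str, float] = {}
        for cause, n_rate in config.baseline_never_rates.items():
            rr_c = config.rr_current[cause]
            rr_f = (config.rr_former or {}).get(cause, 1.0) if p_f > 0 else 1.0
            expected = s.population * n_rate * (p_c * rr_c + p_f * rr_f + p_n)
            true_attrib = s.population * n_rate * (p_c * (rr_c - 1.0) + p_f * (rr_f - 1.0))
            cell_expected[cause] = expected
            cell_truth[cause] = true_attrib

        if config.noise == "poisson":
            causes = sorted(cell_expected)
            draws = rng.poisson([cell_expected[c] for c in causes])
            observed = {c: float(d) for c, d in zip(causes, draws)}
        else:
            observed = dict(cell_expected)

        age_hi = s.age_band.hi
        base = {
            "country": s.country,
            "sex": s.sex,
            "age_lo": s.age_band.lo,
            "age_hi": np.nan if age_hi is None else age_hi,
            "year": config.year,
        }
        for cause in sorted(cell_expected):
            mort_rows.append(
                {**base, "cause": cause, "deaths": observed[cause], "population": s.population}
            )
            truth_rows.append(
                {
                    **base,
                    "cause": cause,
                    "expected_deaths": cell_expected[cause],
                    "true_attributable": cell_truth[cause],
                }
            )
        mort_rows.append(
            {
                **base,
                "cause": ALL_CAUSES,
                "deaths": float(sum(observed.values())),
                "population": s.population,
            }
        )
        strata_rows.append(
            {
                **base,
                "population": s.population,
                "true_sir": p_c,
                "prevalence_current": p_c,
                "prevalence_former": p_f,
            }
        )

    return SimulatedVitalStats(
        mortality=pd.DataFrame(mort_rows),
        ground_truth=pd.DataFrame(truth_rows),
        strata_truth=pd.DataFrame(strata_rows),
        config=config,
    )


def simulate_sales(
    prevalence: pd.Series,
    population: pd.Series,
    sticks_per_smoker_per_day: float,
    country: str = "",
) -> SalesSeries:
    """Annual cigarette sales implied by prevalence and population.

    ``yearly sticks = population * prevalence * sticks/day * 365``.
    """
    if sticks_per_smoker_per_day < 0:
        raise ConfigValidationError(["sticks_per_smoker_per_day: must be >= 0"])
    if (prevalence < 0).any() or (prevalence > 1).any():
        raise ConfigValidationError(["prevalence: values outside [0, 1]"])
    if (population < 0).any():
        raise ConfigValidationError(["population: negative values"])
    if not prevalence.index.equals(population.index):
        raise ConfigValidationError(["prevalence/population: year indexes differ"])
    annual = population * prevalence * sticks_per_smoker_per_day * 365.0
    annual.name = "cigarettes_sold"
    return SalesSeries(country=country, annual=annual.astype(float))
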