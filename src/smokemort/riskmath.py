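"""Closed-form risk algebra for smoking-hazard summaries.

Scalar formulas relating relative risks to avoidable death fractions,
excess risks, cessation benefits, and population life-expectancy
arithmetic.  All functions keep full floating-point precision; rounding
to the one-decimal convention used in published tables is left to the
caller (see :func:`percent_change`'s ``decimals`` argument and the CLI).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = [
    "CAUSES",
    "SEXES",
    "AgeBand",
    "RelativeRiskEntry",
    "CessationGainTable",
    "DEFAULT_CESSATION_GAINS",
    "RiskMathError",
    "InvalidRelativeRiskError",
    "InvalidFractionError",
    "InvalidProportionError",
    "UndefinedReductionError",
    "QuitAgeError",
    "ProtectiveExposureWarning",
    "ExcessRiskBoundsWarning",
    "attributable_fraction",
    "rr_from_af",
    "excess_risk_percent",
    "excess_risk_reduction",
    "population_le_loss",
    "years_gained_by_quit_age",
    "percent_change",
]

#: Controlled vocabulary for causes of death handled by the toolkit.
CAUSES = frozenset(
    {
        "lung_cancer",
        "other_cancers",
        "coronary_heart_disease",
        "cerebrovascular",
        "aortic_other_arterial",
        "diabetes",
        "influenza_pneumonia_tb",
        "copd",
        "other",
        "all_causes",
    }
)

SEXES = frozenset({"male", "female"})


class RiskMathError(ValueError):
    """Base class for domain errors in the risk algebra."""


class InvalidRelativeRiskError(RiskMathError):
    """Relative risk outside its (0, inf) domain."""


class InvalidFractionError(RiskMathError):
    """Attributable fraction outside (-inf, 1)."""


class InvalidProportionError(RiskMathError):
    """Proportion outside [0, 1]."""


class UndefinedReductionError(RiskMathError):
    """Excess-risk reduction undefined: current smokers have no excess."""


class QuitAgeError(RiskMathError):
    """Quit age outside the anchor range of a cessation-gain table."""


class ProtectiveExposureWarning(UserWarning):
    """RR < 1 yields a negative (protective) attributable fraction."""


class ExcessRiskBoundsWarning(UserWarning):
    """Former/current RR pair outside the 1 <= RR_f <= RR_c convention."""


_AGE_RE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")
_OPEN_RE = re.compile(r"^\s*(?:[≥>=]+\s*(\d+)|(\d+)\s*\+)\s*$")


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open age interval ``[lo, hi)`` in years; ``hi=None`` is open-ended."""

    lo: float
    hi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lo < 0:
            raise ValueError(f"age lower bound must be >= 0, got {self.lo}")
        if self.hi is not None and self.hi <= self.lo:
            raise ValueError(f"age band empty or inverted: [{self.lo}, {self.hi})")

    def overlaps(self, other: "AgeBand") -> bool:
        lo, hi = self.lo, self.hi
        olo, ohi = other.lo, other.hi
        if hi is None and ohi is None:
            return True
        if hi is None:
            return ohi > lo
        if ohi is None:
            return hi > olo
        return lo < ohi and olo < hi

    def __str__(self) -> str:
        if self.hi is None:
            return f"{self.lo:g}+"
        # published tables print inclusive upper ends, e.g. 35-54 for [35, 55)
        return f"{self.lo:g}-{self.hi - 1:g}"

    @classmethod
    def parse(cls, text: str) -> "AgeBand":
        """Parse labels like ``35-54``, ``35–54`` or ``≥75``/``75+``.

        An ``a-b`` label is read as the half-open interval ``[a, b+1)``,
        matching the inclusive convention of printed tables.
        """
        m = _AGE_RE.match(text)
        if m:
            return cls(float(m.group(1)), float(m.group(2)) + 1.0)
        m = _OPEN_RE.match(text)
        if m:
            return cls(float(m.group(1) or m.group(2)), None)
        raise ValueError(f"unrecognized age band label: {text!r}")


@dataclass(frozen=True)
class RelativeRiskEntry:
    """Current/former-smoker relative risks for one cause-sex-age stratum.

    The never-smoker reference is implicitly 1.0.
    """

    cause: str
    sex: str
    age_band: AgeBand
    rr_current: float
    rr_former: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cause not in CAUSES:
            raise ValueError(f"unknown cause {self.cause!r}; expected one of {sorted(CAUSES)}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {sorted(SEXES)}")
        if not self.rr_current > 0:
            raise InvalidRelativeRiskError(f"rr_current must be > 0, got {self.rr_current}")
        if self.rr_former is not None and not self.rr_former > 0:
            raise InvalidRelativeRiskError(f"rr_former must be > 0, got {self.rr_former}")

    @property
    def key(self) -> Tuple[str, str, AgeBand]:
        return (self.cause, self.sex, self.age_band)


def attributable_fraction(rr: float) -> float:
    """Proportion of deaths among the exposed avoidable at unexposed rates.

    Computed as ``(rr - 1) / rr``.  A protective exposure (``rr < 1``)
    yields a negative fraction; it is returned as computed, with a
    :class:`ProtectiveExposureWarning` — never clamped.

    >>> round(attributable_fraction(3.0), 4)
    0.6667
    """
    if not rr > 0:
        raise InvalidRelativeRiskError(f"relative risk must be > 0, got {rr}")
    af = (rr - 1.0) / rr
    if af < 0:
        warnings.warn(
            f"rr={rr} < 1 gives negative attributable fraction {af:.4g} (protective exposure)",
            ProtectiveExposureWarning,
            stacklevel=2,
        )
    return af


def rr_from_af(af: float) -> float:
    """Relative risk implied by an attributable fraction: ``1 / (1 - af)``.

    Algebraic inverse of :func:`attributable_fraction`; useful to recover
    RRs from printed avoidable proportions.
    """
    if not af < 1:
        raise InvalidFractionError(f"attributable fraction must be < 1, got {af}")
    return 1.0 / (1.0 - af)


def excess_risk_percent(rr: float) -> float:
    """Excess risk over the unexposed baseline, as a percentage: ``(rr - 1) * 100``."""
    if not rr > 0:
        raise InvalidRelativeRiskError(f"relative risk must be > 0, got {rr}")
    return (rr - 1.0) * 100.0


def excess_risk_reduction(rr_former: float, rr_current: float) -> float:
    """Proportion of a current smoker's excess risk avoided by a former smoker.

    Computed as ``1 - (rr_former - 1) / (rr_current - 1)``.  Equals 1 when
    the former-smoker RR is back at baseline and 0 when it matches the
    current-smoker RR.  Pairs outside ``1 <= rr_former <= rr_current`` are
    computed anyway (the result then falls outside [0, 1]) and flagged
    with :class:`ExcessRiskBoundsWarning`, so that published RR tables can
    be processed verbatim.
    """
    if not rr_current > 0:
        raise InvalidRelativeRiskError(f"rr_current must be > 0, got {rr_current}")
    if not rr_former > 0:
        raise InvalidRelativeRiskError(f"rr_former must be > 0, got {rr_former}")
    if rr_current == 1.0:
        raise UndefinedReductionError("rr_current == 1: current smokers have no excess risk to reduce")
    if rr_former < 1.0 or rr_former > rr_current:
        warnings.warn(
            f"rr_former={rr_former}, rr_current={rr_current} outside 1 <= RR_f <= RR_c; "
            "reduction falls outside [0, 1]",
            ExcessRiskBoundsWarning,
            stacklevel=2,
        )
    return 1.0 - (rr_former - 1.0) / (rr_current - 1.0)


def population_le_loss(prevalence: float, years_lost_per_exposed: float) -> float:
    """Population-average life-expectancy loss: prevalence x per-exposed years lost."""
    if not 0.0 <= prevalence <= 1.0:
        raise InvalidProportionError(f"prevalence must lie in [0, 1], got {prevalence}")
    if years_lost_per_exposed < 0:
        raise RiskMathError(f"years lost must be >= 0, got {years_lost_per_exposed}")
    return prevalence * years_lost_per_exposed


#: Default anchors: life-years gained by quitting at ages 30/40/50/60.
DEFAULT_CESSATION_GAINS: Tuple[Tuple[float, float], ...] = (
    (30.0, 10.0),
    (40.0, 9.0),
    (50.0, 6.0),
    (60.0, 4.0),
)


@dataclass(frozen=True)
class CessationGainTable:
    """Ordered (quit_age, years_gained) anchors; ages strictly increasing,
    gains non-increasing."""

    anchors: Tuple[Tuple[float, float], ...] = DEFAULT_CESSATION_GAINS

    def __post_init__(self) -> None:
        if len(self.anchors) < 1:
            raise ValueError("cessation gain table needs at least one anchor")
        ages = [a for a, _ in self.anchors]
        gains = [g for _, g in self.anchors]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"quit ages must be strictly increasing: {ages}")
        if any(b > a for a, b in zip(gains, gains[1:])):
            raise ValueError(f"years gained must be non-increasing: {gains}")

    @property
    def min_age(self) -> float:
        return self.anchors[0][0]

    @property
    def max_age(self) -> float:
        return self.anchors[-1][0]


def years_gained_by_quit_age(
    quit_age: float,
    table: Optional[CessationGainTable] = None,
    interpolate: bool = False,
) -> float:
    """Life-years gained by quitting at ``quit_age``, from an anchor table.

    With ``interpolate=False`` (default) the age must be exactly one of
    the anchors; with ``interpolate=True`` ages between anchors are
    linearly interpolated.  No extrapolation outside the anchor range.
    """
    if table is None:
        table = CessationGainTable()
    if not table.min_age <= quit_age <= table.max_age:
        raise QuitAgeError(
            f"quit age {quit_age} outside anchor range [{table.min_age}, {table.max_age}]"
        )
    for age, gain in table.anchors:
        if quit_age == age:
            return gain
    if not interpolate:
        raise QuitAgeError(
            f"quit age {quit_age} is not an anchor; pass interpolate=True for values between anchors"
        )
    for (a0, g0), (a1, g1) in zip(table.anchors, table.anchors[1:]):
        if a0 < quit_age < a1:
            return g0 + (g1 - g0) * (quit_age - a0) / (a1 - a0)
    raise QuitAgeError(f"quit age {quit_age} could not be bracketed")  # pragma: no cover


def percent_change(v_start: float, v_end: float, decimals: Optional[int] = None) -> float:
    """Relative change from ``v_start`` to ``v_end`` in percent.

    ``decimals`` applies the one-decimal reporting convention of
    published tables; ``None`` returns full precision.
    """
    if v_start == 0:
        raise ZeroDivisionError("percent change undefined for v_start == 0")
    pc = (v_end - v_start) / v_start * 100.0
    if decimals is not None:
        pc = round(pc, decimals)
    return pc
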