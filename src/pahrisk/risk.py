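"""Deterministic oral and dermal sediment-exposure cancer-risk equations.

The model follows standard US EPA Superfund risk-assessment practice for
incidental sediment contact.  Exposure is a chronic daily intake (oral) or a
dermal absorbed dose (dermal), in mg of contaminant per kg body weight per
day, averaged over a lifetime::

    CDI      = CS * IR_S * FI * EF * ED * CF / (BW * AT)
    DA_event = CS * CF * AF * ABSd
    DAD      = DA_event * EF * ED * EV * SA / (BW * AT)

Excess lifetime cancer risk is exposure times hazard, where the hazard of a
contaminant of concern is its route-specific cancer slope factor (CSF,
(mg/kg-day)^-1) scaled by the age-dependent adjustment factor (ADAF; 10 for
child receptors, 1 for adults).  For a mixture the per-compound hazards are
summed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Mapping

from .errors import RouteError, ValidationError

__all__ = [
    "Group",
    "Route",
    "ExposureScenario",
    "CancerSlopeSet",
    "compute_cdi",
    "compute_da_event",
    "compute_dad",
    "compute_exposure",
    "compute_risk",
]


class Group(str, enum.Enum):
    ADULT_TRESPASSER = "adult_trespasser"
    CHILD_TRESPASSER = "child_trespasser"
    ADULT_RECREATIONAL = "adult_recreational"
    CHILD_RECREATIONAL = "child_recreational"


class Route(str, enum.Enum):
    ORAL = "oral"
    DERMAL = "dermal"


#: Scenario fields required (and used) by each route, beyond the shared set.
_ORAL_FIELDS = ("CS", "IR_S", "FI", "EF", "ED", "CF", "BW", "AT")
_DERMAL_FIELDS = ("CS", "CF", "AF", "ABSd", "EF", "ED", "EV", "SA", "BW", "AT")


@dataclass(frozen=True)
class ExposureScenario:
    """One population group x exposure route with all exposure factors.

    Units: CS mg/kg sediment; IR_S mg sediment/day; EF days/year; ED years;
    BW kg; AT days; SA cm^2; AF mg/cm^2-day; CF kg/mg (1e-6); FI, EV, ABSd,
    ADAF unitless.  FI (fraction ingested) and EV (events/day) default to the
    conservative value 1.
    """

    group: Group
    route: Route
    CS: float
    EF: float
    ED: float
    BW: float
    AT: float = 25550.0
    ADAF: float = 1.0
    CF: float = 1e-6
    IR_S: float | None = None
    FI: float = 1.0
    SA: float | None = None
    AF: float | None = None
    ABSd: float = 0.13
    EV: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "route", Route(self.route))

    def replace(self, **changes) -> "ExposureScenario":
        return replace(self, **changes)

    def validate(self, strict: bool = True) -> None:
        """Check route-required factors are present and positive.

        With ``strict=False`` zeros are permitted (the equations are products,
        so zero factors are analytically well defined); negatives never are.
        """
        fields = _ORAL_FIELDS if self.route is Route.ORAL else _DERMAL_FIELDS
        for name in fields:
            value = getattr(self, name)
            if value is None:
                raise ValidationError(f"{self.route.value} scenario missing {name}")
            if value < 0 or (strict and value == 0):
                bound = "positive" if strict else "nonnegative"
                raise ValidationError(f"{name} must be {bound}, got {value}")
        for name, value in (("FI", self.FI), ("ABSd", self.ABSd)):
            if value > 1:
                raise ValidationError(f"{name} is a fraction, got {value} > 1")


@dataclass(frozen=True)
class CancerSlopeSet:
    """Route-specific cancer slope factors for the contaminants of concern."""

    route: Route
    slopes: Mapping[str, float]  # compound name -> CSF, (mg/kg-day)^-1

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))
        object.__setattr__(self, "slopes", dict(self.slopes))
        for name, csf in self.slopes.items():
            if csf <= 0:
                raise ValidationError(f"CSF for {name!r} must be positive, got {csf}")

    def __len__(self) -> int:
        return len(self.slopes)

    @property
    def total(self) -> float:
        return float(sum(self.slopes.values()))


def _require_route(s: ExposureScenario, route: Route) -> None:
    if s.route is not route:
        raise RouteError(f"expected a {route.value} scenario, got {s.route.value}")


def compute_cdi(s: ExposureScenario, strict: bool = True) -> float:
    """Chronic daily intake from incidental sediment ingestion, mg/kg-day."""
    _require_route(s, Route.ORAL)
    s.validate(strict=strict)
    return s.CS * s.IR_S * s.FI * s.EF * s.ED * s.CF / (s.BW * s.AT)


def compute_da_event(s: ExposureScenario, strict: bool = True) -> float:
    """Absorbed dose per dermal contact event, mg/cm^2-event."""
    _require_route(s, Route.DERMAL)
    s.validate(strict=strict)
    return s.CS * s.CF * s.AF * s.ABSd


def compute_dad(s: ExposureScenario, strict: bool = True) -> float:
    """Dermal absorbed dose averaged over lifetime, mg/kg-day."""
    _require_route(s, Route.DERMAL)
    s.validate(strict=strict)
    return compute_da_event(s, strict=strict) * s.EF * s.ED * s.EV * s.SA / (s.BW * s.AT)


def compute_exposure(s: ExposureScenario, strict: bool = True) -> float:
    """Route-appropriate exposure: CDI for oral, DAD for dermal."""
    if s.route is Route.ORAL:
        return compute_cdi(s, strict=strict)
    return compute_dad(s, strict=strict)


def compute_risk(
    s: ExposureScenario,
    slopes: CancerSlopeSet,
    concentrations: Mapping[str, float] | None = None,
    strict: bool = True,
) -> float:
    """Excess lifetime cancer risk for the scenario under a slope-factor set.

    Default (shared-concentration) mode: the scenario's single sediment
    concentration CS drives the exposure term and per-compound hazards
    (CSF * ADAF) are summed over it::

        risk = exposure(s) * ADAF * sum_i CSF_i

    Per-compound mode: pass ``concentrations`` mapping each slope-set
    compound to its own sediment concentration (mg/kg); exposure is then
    evaluated compound-wise and risks summed.
    """
    if s.route is not slopes.route:
        raise RouteError(
            f"slope set is for {slopes.route.value}, scenario is {s.route.value}"
        )
    if len(slopes) == 0:
        raise ValidationError("empty cancer slope set")
    if concentrations is None:
        return compute_exposure(s, strict=strict) * s.ADAF * slopes.total
    missing = sorted(set(slopes.slopes) - set(concentrations))
    if missing:
        raise ValidationError(f"no concentration for compounds: {missing}")
    total = 0.0
    for name, csf in slopes.slopes.items():
        si = s.replace(CS=concentrations[name])
        total += compute_exposure(si, strict=strict) * s.ADAF * csf
    return total
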