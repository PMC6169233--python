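"""Intake-fraction and health-effect characterization of a PAH mixture.

Life-cycle impact characterization records give, for each compound and each
environmental compartment it can be emitted into, the population intake
fraction (kg taken in per kg emitted) broken down by exposure route, and the
associated health effect factors (excess cancer cases and disability-adjusted
life years per kg emitted).  The module pools such records over the compounds
of a mixture, apportions compartment intake across exposure routes, and ranks
compartments by pooled health impact.  Characterization factors are inputs
(fate modeling itself is out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "DEFAULT_COMPARTMENTS",
    "DEFAULT_ROUTES",
    "CharacterizationRecord",
    "CharacterizationTable",
    "load_characterization",
    "pool_mixture",
    "route_apportionment",
    "effects_by_compartment",
]

DEFAULT_COMPARTMENTS = (
    "household_indoor_air",
    "fresh_water",
    "sea_water",
    "natural_soil",
    "agricultural_soil",
)
DEFAULT_ROUTES = ("inhalation", "drinking_water", "produce", "meat_dairy", "fish")

_COLUMNS = (
    "compound",
    "compartment",
    "route",
    "intake_fraction",
    "cancer_cases_per_kg",
    "daly_per_kg",
)


@dataclass(frozen=True)
class CharacterizationRecord:
    """One (compound, emission compartment, exposure route) record."""

    compound: str
    compartment: str
    route: str
    intake_fraction: float  # kg intake / kg emitted
    cancer_cases_per_kg: float  # cases / kg emitted
    daly_per_kg: float  # DALY / kg emitted

    def __post_init__(self) -> None:
        for name in ("intake_fraction", "cancer_cases_per_kg", "daly_per_kg"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{name} must be nonnegative for {self.compound}/{self.compartment}/{self.route}"
                )


class CharacterizationTable:
    """Collection of characterization records with unique (compound, compartment, route) keys."""

    def __init__(self, records) -> None:
        records = tuple(records)
        keys = [(r.compound, r.compartment, r.route) for r in records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate characterization keys: {dupes}")
        self.records = records

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(sorted({r.compound for r in self.records}))

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(sorted({r.compartment for r in self.records}))

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CharacterizationTable":
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"characterization table missing columns: {missing}")
        return cls(
            CharacterizationRecord(
                compound=str(row["compound"]),
                compartment=str(row["compartment"]),
                route=str(row["route"]),
                intake_fraction=float(row["intake_fraction"]),
                cancer_cases_per_kg=float(row["cancer_cases_per_kg"]),
                daly_per_kg=float(row["daly_per_kg"]),
            )
            for _, row in frame.iterrows()
        )


def load_characterization(path: str | Path) -> CharacterizationTable:
    return CharacterizationTable.from_frame(pd.read_csv(path))


def _check_compounds(table: CharacterizationTable, compounds) -> list[str]:
    compounds = list(compounds)
    missing = sorted(set(compounds) - set(table.compounds))
    if missing:
        raise ValidationError(f"compounds absent from characterization table: {missing}")
    return compounds


def pool_mixture(table: CharacterizationTable, compounds) -> CharacterizationTable:
    """Sum records over a compound set; the pooled compound is labelled ``mixture``.

    Intake fractions and effect factors are additive across the components of
    a mixture emitted together, so pooling is a per-(compartment, route) sum.
    """
    compounds = _check_compounds(table, compounds)
    frame = table.to_frame()
    pooled = (
        frame[frame["compound"].isin(compounds)]
        .groupby(["compartment", "route"], as_index=False)[
            ["intake_fraction", "cancer_cases_per_kg", "daly_per_kg"]
        ]
        .sum()
    )
    pooled.insert(0, "compound", "mixture")
    return CharacterizationTable.from_frame(pooled)


def route_apportionment(
    table: CharacterizationTable, compartment: str, compounds=None
) -> dict[str, float]:
    """Share of a compartment's total intake taken in through each route.

    Shares are normalized route intake fractions and sum to one.  When
    ``compounds`` is given the table is pooled over that mixture first.
    """
    if compounds is not None:
        table = pool_mixture(table, compounds)
    frame = table.to_frame()
    sub = frame[frame["compartment"] == compartment]
    if sub.empty:
        raise ValidationError(f"compartment not in table: {compartment!r}")
    by_route = sub.groupby("route")["intake_fraction"].sum()
    total = float(by_route.sum())
    if total <= 0:
        raise ValidationError(
            f"compartment {compartment!r} has zero total intake; shares undefined"
        )
    return {route: float(v) / total for route, v in by_route.items()}


def effects_by_compartment(table: CharacterizationTable, compounds) -> pd.DataFrame:
    """Pooled cancer-case and DALY factors per emission compartment.

    Returns one row per compartment with summed ``cancer_cases_per_kg`` and
    ``daly_per_kg`` over the mixture's compounds and all routes, sorted by
    descending cancer-case factor (ties by compartment name).
    """
    pooled = pool_mixture(table, compounds).to_frame()
    out = (
        pooled.groupby("compartment", as_index=False)[
            ["intake_fraction", "cancer_cases_per_kg", "daly_per_kg"]
        ]
        .sum()
        .sort_values(
            ["cancer_cases_per_kg", "compartment"],
            ascending=[False, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )
    return out
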