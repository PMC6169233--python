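"""Reverse dosimetry: daily PAH intake from urinary metabolite biomarkers.

A one-compartment, steady-state mass balance links the urinary concentration
of a PAH metabolite to the daily intake of its parent compound::

    intake (ug/kg-day) = (C_urine * V_urine * MW_parent)
                         / (f_excretion * BW * MW_metabolite)

where C_urine is the metabolite concentration (ug/L, unadjusted geometric
mean), V_urine the standardized daily adult urine output (L/day), BW the
adult body weight (kg), f_excretion the fraction of absorbed parent excreted
in urine as the measured metabolite, and the molecular-weight ratio converts
metabolite mass back to parent-equivalent mass.  Applied to biomarker tables
stratified by gender, race/ethnicity and smoking status, it ranks
subpopulations by exposure; absolute levels inherit the (large) uncertainty
of the excretion fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "GENDERS",
    "RACE_ETHNICITIES",
    "SMOKING_STATUSES",
    "Stratum",
    "PAHKinetics",
    "BiomarkerRecord",
    "PopulationConstants",
    "default_kinetics",
    "default_constants",
    "load_biomarkers",
    "load_kinetics",
    "estimate_intake",
    "estimate_population",
    "rank_strata",
]

GENDERS = ("male", "female", "all")
RACE_ETHNICITIES = (
    "non-Hispanic white",
    "non-Hispanic black",
    "Mexican American",
    "all",
)
SMOKING_STATUSES = ("smoker", "nonsmoker", "secondhand", "all")

STRATUM_AXES = ("gender", "race_ethnicity", "smoking_status")


@dataclass(frozen=True)
class Stratum:
    """Demographic cell; ``"all"`` marks an unstratified axis."""

    gender: str = "all"
    race_ethnicity: str = "all"
    smoking_status: str = "all"

    def __post_init__(self) -> None:
        for value, allowed, axis in (
            (self.gender, GENDERS, "gender"),
            (self.race_ethnicity, RACE_ETHNICITIES, "race_ethnicity"),
            (self.smoking_status, SMOKING_STATUSES, "smoking_status"),
        ):
            if value not in allowed:
                raise ValidationError(f"unknown {axis} value: {value!r}")


@dataclass(frozen=True)
class PAHKinetics:
    """Excretion kinetics and molecular weights linking parent and metabolite."""

    parent_name: str
    metabolite_name: str
    MW_parent: float  # g/mol
    MW_metabolite: float  # g/mol
    excretion_fraction: float  # unitless, (0, 1]

    def __post_init__(self) -> None:
        if self.MW_parent <= 0 or self.MW_metabolite <= 0:
            raise ValidationError("molecular weights must be positive")
        if not 0 < self.excretion_fraction <= 1:
            raise ValidationError(
                f"excretion_fraction must be in (0, 1], got {self.excretion_fraction}"
            )


@dataclass(frozen=True)
class BiomarkerRecord:
    """One urinary metabolite geometric-mean concentration for one stratum."""

    metabolite_name: str
    concentration: float  # ug/L urine
    stratum: Stratum = Stratum()

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError(
                f"negative urinary concentration for {self.metabolite_name!r}"
            )


@dataclass(frozen=True)
class PopulationConstants:
    daily_urine_output: float = 1.6  # L/day, standardized adult
    body_weight: float = 80.0  # kg, standardized adult

    def __post_init__(self) -> None:
        if self.daily_urine_output <= 0 or self.body_weight <= 0:
            raise ValidationError("urine output and body weight must be positive")


# Illustrative default kinetics for the four parent PAHs tracked in the
# packaged configuration (one metabolite each).  Molecular weights are the
# parent/metabolite formula weights; excretion fractions are
# order-of-magnitude literature-style values and are configuration inputs,
# not ground truth.
_DEFAULT_KINETICS = (
    PAHKinetics("naphthalene", "2-naphthol", 128.17, 144.17, 0.10),
    PAHKinetics("fluorene", "2-hydroxyfluorene", 166.22, 182.22, 0.25),
    PAHKinetics("phenanthrene", "1-hydroxyphenanthrene", 178.23, 194.23, 0.05),
    PAHKinetics("pyrene", "1-hydroxypyrene", 202.25, 218.25, 0.20),
)


def default_kinetics() -> dict[str, PAHKinetics]:
    """Packaged kinetics, keyed by metabolite name."""
    return {k.metabolite_name: k for k in _DEFAULT_KINETICS}


def default_constants() -> PopulationConstants:
    return PopulationConstants()


def load_kinetics(path: str | Path) -> dict[str, PAHKinetics]:
    """Read a kinetics CSV: parent,metabolite,mw_parent,mw_metabolite,excretion_fraction."""
    table = pd.read_csv(path)
    required = ("parent", "metabolite", "mw_parent", "mw_metabolite", "excretion_fraction")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"kinetics table missing columns: {missing}")
    out: dict[str, PAHKinetics] = {}
    for _, row in table.iterrows():
        k = PAHKinetics(
            parent_name=str(row["parent"]),
            metabolite_name=str(row["metabolite"]),
            MW_parent=float(row["mw_parent"]),
            MW_metabolite=float(row["mw_metabolite"]),
            excretion_fraction=float(row["excretion_fraction"]),
        )
        out[k.metabolite_name] = k
    return out


def load_biomarkers(path: str | Path) -> list[BiomarkerRecord]:
    """Read a biomarker CSV: metabolite,concentration_ug_L,gender,race_ethnicity,smoking_status."""
    table = pd.read_csv(path, keep_default_na=False, na_values=[])
    required = ("metabolite", "concentration_ug_L", "gender", "race_ethnicity", "smoking_status")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"biomarker table missing columns: {missing}")
    records = []
    for _, row in table.iterrows():
        records.append(
            BiomarkerRecord(
                metabolite_name=str(row["metabolite"]),
                concentration=float(row["concentration_ug_L"]),
                stratum=Stratum(
                    gender=str(row["gender"]) or "all",
                    race_ethnicity=str(row["race_ethnicity"]) or "all",
                    smoking_status=str(row["smoking_status"]) or "all",
                ),
            )
        )
    return records


def estimate_intake(
    record: BiomarkerRecord,
    kinetics: PAHKinetics,
    constants: PopulationConstants,
) -> float:
    """Back-calculated parent-compound intake, ug/kg-day."""
    if kinetics.metabolite_name != record.metabolite_name:
        raise ValidationError(
            f"kinetics are for {kinetics.metabolite_name!r}, "
            f"record is {record.metabolite_name!r}"
        )
    return (
        record.concentration * constants.daily_urine_output * kinetics.MW_parent
    ) / (kinetics.excretion_fraction * constants.body_weight * kinetics.MW_metabolite)


def estimate_population(
    records,
    kinetics_set: dict[str, PAHKinetics],
    constants: PopulationConstants,
) -> pd.DataFrame:
    """Intake table over (parent, stratum) cells, ug/kg-day.

    Replicate records in the same cell are combined by geometric mean,
    matching the geometric-mean convention of the source biomarker summaries
    (cells containing a zero concentration fall back to the arithmetic mean).
    """
    missing = sorted(
        {r.metabolite_name for r in records} - set(kinetics_set)
    )
    if missing:
        raise ValidationError(f"no kinetics for metabolites: {missing}")
    rows = []
    for r in records:
        k = kinetics_set[r.metabolite_name]
        rows.append(
            {
                "parent": k.parent_name,
                "gender": r.stratum.gender,
                "race_ethnicity": r.stratum.race_ethnicity,
                "smoking_status": r.stratum.smoking_status,
                "intake_ug_kg_day": estimate_intake(r, k, constants),
            }
        )
    frame = pd.DataFrame(rows)

    def _gmean(values: pd.Series) -> float:
        v = values.to_numpy(dtype=float)
        if np.any(v <= 0):
            return float(v.mean())
        return float(np.exp(np.log(v).mean()))

    keys = ["parent", *STRATUM_AXES]
    return (
        frame.groupby(keys, as_index=False)["intake_ug_kg_day"]
        .agg(_gmean)
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )


def rank_strata(intakes: pd.DataFrame, axis: str) -> list[tuple[str, float]]:
    """Rank the levels of one stratum axis by total intake across parents.

    Descending by summed intake; ties broken alphabetically.  The
    ``"all"`` placeholder level is excluded.
    """
    if axis not in STRATUM_AXES:
        raise ValidationError(f"unknown stratum axis: {axis!r}; use one of {STRATUM_AXES}")
    sub = intakes[intakes[axis] != "all"]
    totals = sub.groupby(axis)["intake_ug_kg_day"].sum()
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(total)) for name, total in ordered]
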