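"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data a full assessment consumes:

* sediment mixture profiles (log-uniform concentrations with configurable
  priority-flag and concern-level frequencies, or the packaged sediment
  fixture verbatim);
* stratified urinary-biomarker tables built by running the reverse-dosimetry
  mass balance *forward* from known true intakes, with multiplicative
  stratum effects and optional lognormal measurement noise — so the
  reverse-dosimetry stage can be tested as an exact (or statistically
  controlled) round trip;
* characterization-factor tables whose compartment ordering and
  fish-dominated route apportionment are built in by construction.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characterization import (
    DEFAULT_ROUTES,
    CharacterizationRecord,
    CharacterizationTable,
)
from .dosimetry import (
    STRATUM_AXES,
    BiomarkerRecord,
    PAHKinetics,
    PopulationConstants,
    Stratum,
)
from .errors import ValidationError
from .mixture import ConcernLevel, MixtureProfile, PAHCompound, paper_mixture

__all__ = [
    "SynthesisSpec",
    "generate_mixture",
    "generate_biomarkers",
    "generate_characterization",
]

#: Stratum multipliers encoding the qualitative exposure structure of the
#: emulated population: smokers well above nonsmokers, secondhand exposure in
#: between, non-Hispanic black subpopulations elevated, no gender difference.
DEFAULT_STRATUM_EFFECTS = {
    "smoking_status": {"smoker": 3.0, "secondhand": 1.5, "nonsmoker": 1.0},
    "gender": {"male": 1.0, "female": 1.0},
    "race_ethnicity": {
        "non-Hispanic black": 1.5,
        "non-Hispanic white": 1.0,
        "Mexican American": 1.0,
    },
}

#: True daily intakes (ug/kg-day) for the four tracked parents; naphthalene
#: dominates, as in the emulated biomarker surveys.
DEFAULT_TRUE_INTAKES = {
    "naphthalene": 0.50,
    "fluorene": 0.05,
    "phenanthrene": 0.08,
    "pyrene": 0.03,
}

#: Emission compartments ordered by decreasing pooled health effect.
DEFAULT_CF_ORDERING = ("fresh_water", "sea_water", "agricultural_soil", "natural_soil")

#: Route apportionment used for water/soil compartments: fish dominates.
FISH_DOMINATED_ROUTE_SHARES = {
    "fish": 0.60,
    "drinking_water": 0.15,
    "produce": 0.13,
    "meat_dairy": 0.07,
    "inhalation": 0.05,
}

_CONCERN_FREQUENCIES = {
    ConcernLevel.NONE: 0.45,
    ConcernLevel.LOW: 0.20,
    ConcernLevel.LOW_MODERATE: 0.15,
    ConcernLevel.MODERATE: 0.10,
    ConcernLevel.MODERATE_HIGH: 0.05,
    ConcernLevel.HIGH: 0.05,
}


@dataclass(frozen=True)
class SynthesisSpec:
    """Knobs for all three generators; defaults encode the study conditions."""

    seed: int = 0
    n_compounds: int = 30
    concentration_scale: float = 500.0  # ng/mL, upper end of log-uniform range
    true_intakes: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_INTAKES))
    stratum_effects: dict = field(
        default_factory=lambda: {a: dict(v) for a, v in DEFAULT_STRATUM_EFFECTS.items()}
    )
    cf_ordering: tuple = DEFAULT_CF_ORDERING
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration_scale <= 0:
            raise ValidationError("concentration_scale must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        for axis, levels in self.stratum_effects.items():
            for level, factor in levels.items():
                if factor <= 0:
                    raise ValidationError(
                        f"stratum effect {axis}/{level} must be positive"
                    )
        for intake in self.true_intakes.values():
            if intake <= 0:
                raise ValidationError("true intakes must be positive")


def generate_mixture(spec: SynthesisSpec, preset: str | None = None) -> MixtureProfile:
    """Random mixture profile, or the packaged sediment fixture (``preset="paper"``)."""
    if preset == "paper":
        return paper_mixture()
    if preset is not None:
        raise ValidationError(f"unknown mixture preset: {preset!r}")
    if spec.n_compounds < 1:
        raise ValidationError("n_compounds must be >= 1")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.concentration_scale / 100.0, spec.concentration_scale
    concentrations = np.exp(rng.uniform(math.log(lo), math.log(hi), spec.n_compounds))
    levels = list(_CONCERN_FREQUENCIES)
    probs = np.array(list(_CONCERN_FREQUENCIES.values()))
    compounds = []
    for i in range(spec.n_compounds):
        conc = float(concentrations[i])
        compounds.append(
            PAHCompound(
                name=f"PAH-{i:03d}",
                concentration=conc,
                concentration_sd=conc * float(rng.uniform(0.02, 0.3)),
                is_priority=bool(rng.random() < 0.45),
                concern_level=levels[int(rng.choice(len(levels), p=probs))],
            )
        )
    return MixtureProfile(tuple(compounds), source_label=f"synthetic-seed{spec.seed}")


def _forward_concentration(
    intake: float, kinetics: PAHKinetics, constants: PopulationConstants
) -> float:
    """Urinary metabolite concentration implied by a daily intake (ug/L)."""
    return (
        intake
        * kinetics.excretion_fraction
        * constants.body_weight
        * kinetics.MW_metabolite
    ) / (constants.daily_urine_output * kinetics.MW_parent)


def _strata_with_effects(spec: SynthesisSpec):
    """Marginal strata (one axis set, others 'all') plus the overall cell."""
    yield Stratum(), 1.0
    for axis in STRATUM_AXES:
        for level, factor in sorted(spec.stratum_effects.get(axis, {}).items()):
            yield Stratum(**{axis: level}), factor


def generate_biomarkers(
    spec: SynthesisSpec,
    kinetics_set: dict[str, PAHKinetics],
    constants: PopulationConstants,
    n_replicates: int = 1,
) -> tuple[list[BiomarkerRecord], pd.DataFrame]:
    """Forward-simulated biomarker records plus their ground-truth intake table.

    Concentrations are the exact forward images of ``spec.true_intakes`` per
    stratum (after multiplicative stratum effects).  With ``noise_cv > 0``
    each replicate is perturbed by a median-1 lognormal factor with the given
    coefficient of variation, so stratum geometric means stay centred on the
    noise-free values.
    """
    by_parent = {k.parent_name: k for k in kinetics_set.values()}
    missing = sorted(set(spec.true_intakes) - set(by_parent))
    if missing:
        raise ValidationError(f"no kinetics for parents: {missing}")
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0

    records: list[BiomarkerRecord] = []
    truth_rows = []
    for parent, base_intake in sorted(spec.true_intakes.items()):
        kin = by_parent[parent]
        for stratum, factor in _strata_with_effects(spec):
            true_intake = base_intake * factor
            conc = _forward_concentration(true_intake, kin, constants)
            truth_rows.append(
                {
                    "parent": parent,
                    "gender": stratum.gender,
                    "race_ethnicity": stratum.race_ethnicity,
                    "smoking_status": stratum.smoking_status,
                    "true_intake_ug_kg_day": true_intake,
                }
            )
            for _ in range(n_replicates):
                noisy = conc * math.exp(sigma * rng.standard_normal()) if sigma else conc
                records.append(
                    BiomarkerRecord(
                        metabolite_name=kin.metabolite_name,
                        concentration=noisy,
                        stratum=stratum,
                    )
                )
    return records, pd.DataFrame(truth_rows)


def generate_characterization(
    spec: SynthesisSpec,
    compounds: tuple[str, ...] = ("PAH-A", "PAH-B", "PAH-C", "PAH-D", "PAH-E", "PAH-F", "PAH-G"),
) -> CharacterizationTable:
    """Characterization table whose pooled effects decrease along ``cf_ordering``.

    Per compartment, a total intake fraction and effect factors are chosen
    strictly decreasing along the ordering (each compartment at 40% of the
    previous), split across compounds with random positive weights and across
    routes with the fish-dominated share profile.
    """
    ordering = tuple(spec.cf_ordering)
    if len(set(ordering)) != len(ordering):
        raise ValidationError(f"duplicate compartments in cf_ordering: {ordering}")
    if not ordering:
        raise ValidationError("cf_ordering must be non-empty")
    rng = np.random.default_rng(spec.seed)
    weights = rng.uniform(0.5, 1.5, len(compounds))
    weights = weights / weights.sum()

    route_shares = FISH_DOMINATED_ROUTE_SHARES
    records = []
    for rank, compartment in enumerate(ordering):
        decay = 0.4**rank
        total_if = 1e-4 * decay  # kg intake per kg emitted
        total_cases = 1e-6 * decay  # cancer cases per kg emitted
        total_daly = 1e-5 * decay  # DALY per kg emitted
        for compound, w in zip(compounds, weights):
            for route in DEFAULT_ROUTES:
                share = route_shares[route]
                records.append(
                    CharacterizationRecord(
                        compound=compound,
                        compartment=compartment,
                        route=route,
                        intake_fraction=total_if * w * share,
                        cancer_cases_per_kg=total_cases * w * share,
                        daly_per_kg=total_daly * w * share,
                    )
                )
    return CharacterizationTable(records)
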