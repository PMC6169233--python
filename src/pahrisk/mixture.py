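"""PAH mixture profiles and carcinogenicity annotation.

A :class:`MixtureProfile` holds the per-compound sediment concentrations of a
complex PAH mixture together with two carcinogenicity annotations per
compound: membership in the US EPA list of sixteen priority PAHs, and a
structure-activity ("OncoLogic"-style) carcinogenic concern level on an
ordered scale.  The module answers the screening questions a risk assessor
asks first: how many mixture components are priority pollutants, and how many
are of carcinogenic concern at or above a chosen level.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "ConcernLevel",
    "PAHCompound",
    "MixtureProfile",
    "load_mixture",
    "write_mixture",
    "paper_mixture",
    "count_priority",
    "count_concern",
    "summarize_mixture",
]

#: Default screening threshold: compounds ranked low-moderate or higher are
#: treated as "of carcinogenic concern".
DEFAULT_CONCERN_THRESHOLD = "low-moderate"

REQUIRED_COLUMNS = (
    "name",
    "concentration_ng_ml",
    "sd_ng_ml",
    "epa_priority",
    "oncologic_level",
)

_TRUTHY = {"+", "true", "yes", "1", "x"}


class ConcernLevel(enum.IntEnum):
    """Ordered carcinogenic-concern scale.

    The integer order encodes the ranking
    none < marginal < low < low-moderate < moderate < moderate-high < high,
    so comparisons like ``level >= ConcernLevel.LOW_MODERATE`` express
    "at least low-moderate concern".  Marginal/negligible rankings are kept
    distinct from blank annotations (``NONE``) even though neither counts as
    carcinogenic concern under the default threshold.
    """

    NONE = 0
    MARGINAL = 1
    LOW = 2
    LOW_MODERATE = 3
    MODERATE = 4
    MODERATE_HIGH = 5
    HIGH = 6

    @property
    def label(self) -> str:
        return self.name.lower().replace("_", "-")

    @classmethod
    def from_label(cls, label: object) -> "ConcernLevel":
        """Parse a textual level; blank / missing cells map to ``NONE``."""
        if label is None or (isinstance(label, float) and pd.isna(label)):
            return cls.NONE
        text = str(label).strip().lower().replace(" ", "-").replace("_", "-")
        if text == "":
            return cls.NONE
        for member in cls:
            if member.label == text:
                return member
        raise ValidationError(f"unknown concern level: {label!r}")


@dataclass(frozen=True)
class PAHCompound:
    """One mixture component: concentration plus carcinogenicity annotations."""

    name: str
    concentration: float  # ng/mL sediment extract
    concentration_sd: float = 0.0  # ng/mL
    is_priority: bool = False
    concern_level: ConcernLevel = ConcernLevel.NONE

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("compound name must be non-empty")
        if self.concentration < 0:
            raise ValidationError(
                f"negative concentration for {self.name!r}: {self.concentration}"
            )
        if self.concentration_sd < 0:
            raise ValidationError(
                f"negative concentration SD for {self.name!r}: {self.concentration_sd}"
            )
        if not isinstance(self.concern_level, ConcernLevel):
            object.__setattr__(
                self, "concern_level", ConcernLevel.from_label(self.concern_level)
            )


@dataclass(frozen=True)
class MixtureProfile:
    """An ordered, name-unique collection of PAH compounds."""

    compounds: tuple[PAHCompound, ...]
    source_label: str = "unlabelled"

    def __post_init__(self) -> None:
        if len(self.compounds) == 0:
            raise ValidationError("a mixture profile needs at least one compound")
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate compound names: {dupes}")
        object.__setattr__(self, "compounds", tuple(self.compounds))

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [c.name for c in self.compounds],
                "concentration_ng_ml": [c.concentration for c in self.compounds],
                "sd_ng_ml": [c.concentration_sd for c in self.compounds],
                "epa_priority": ["+" if c.is_priority else "" for c in self.compounds],
                "oncologic_level": [
                    "" if c.concern_level is ConcernLevel.NONE else c.concern_level.label
                    for c in self.compounds
                ],
            }
        )


def _parse_priority(cell: object) -> bool:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return False
    return str(cell).strip().lower() in _TRUTHY


def load_mixture(path: str | Path, source_label: str | None = None) -> MixtureProfile:
    """Read a mixture profile from CSV.

    Expected header: ``name,concentration_ng_ml,sd_ng_ml,epa_priority,
    oncologic_level``.  Blank priority cells mean "not on the priority list";
    blank concern cells mean no (or negligible) ranked concern.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"name": str}, keep_default_na=False, na_values=[])
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"mixture table {path} is missing columns: {missing}")

    compounds = []
    for i, row in table.iterrows():
        try:
            conc = float(row["concentration_ng_ml"])
            sd = float(row["sd_ng_ml"]) if str(row["sd_ng_ml"]).strip() else 0.0
        except ValueError as exc:
            raise ValidationError(f"row {i} ({row['name']!r}): {exc}") from exc
        if conc < 0:
            raise ValidationError(
                f"row {i} ({row['name']!r}): negative concentration {conc}"
            )
        compounds.append(
            PAHCompound(
                name=str(row["name"]).strip(),
                concentration=conc,
                concentration_sd=sd,
                is_priority=_parse_priority(row["epa_priority"]),
                concern_level=ConcernLevel.from_label(row["oncologic_level"]),
            )
        )
    return MixtureProfile(tuple(compounds), source_label or path.stem)


def write_mixture(profile: MixtureProfile, path: str | Path) -> None:
    """Write a profile back to the CSV schema read by :func:`load_mixture`."""
    profile.to_frame().to_csv(path, index=False)


def paper_mixture() -> MixtureProfile:
    """The packaged Superfund-sediment mixture fixture (35 compounds)."""
    with resources.as_file(
        resources.files("pahrisk.data").joinpath("table2_mixture.csv")
    ) as p:
        return load_mixture(p, source_label="superfund-sediment")


def count_priority(profile: MixtureProfile) -> int:
    """Number of compounds on the US EPA 16-priority-PAH list."""
    return sum(1 for c in profile if c.is_priority)


def count_concern(
    profile: MixtureProfile,
    threshold: ConcernLevel | str = DEFAULT_CONCERN_THRESHOLD,
) -> int:
    """Number of compounds at or above ``threshold`` carcinogenic concern."""
    if not isinstance(threshold, ConcernLevel):
        threshold = ConcernLevel.from_label(threshold)
    return sum(1 for c in profile if c.concern_level >= threshold)


def summarize_mixture(profile: MixtureProfile, top_k: int = 5) -> dict:
    """Totals, top-k compounds by concentration, and per-level concern counts.

    Top-k ties are broken alphabetically by compound name.
    """
    ranked = sorted(profile, key=lambda c: (-c.concentration, c.name))
    per_level = {
        level.label: sum(1 for c in profile if c.concern_level is level)
        for level in ConcernLevel
    }
    return {
        "source": profile.source_label,
        "n_compounds": len(profile),
        "total_concentration_ng_ml": float(sum(c.concentration for c in profile)),
        "top_compounds": [
            {"name": c.name, "concentration_ng_ml": c.concentration}
            for c in ranked[:top_k]
        ],
        "n_priority": count_priority(profile),
        "n_concern_at_default_threshold": count_concern(profile),
        "concern_level_counts": per_level,
    }


def summary_to_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
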