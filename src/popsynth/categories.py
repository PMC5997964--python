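"""Category declarations for household and person attributes.

The default schema mirrors the South African Census 2011 variable set used
throughout the package: five household variables (6/13/20/5/13 categories)
and six person variables (18/2/5/2/8/9 categories).  All categorical values
are exchanged as strings; a :class:`Schema` can be loaded from a JSON or
YAML file mapping variable names to ordered category lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import SchemaError

HOUSING = [
    "House",
    "Hostel",
    "Hotel",
    "OldAgeHome",
    "Other",
    "NotApplicable",
]

DWELLING = [
    "FormalHouse",
    "TraditionalDwelling",
    "Apartment",
    "Cluster",
    "Townhouse",
    "SemiDetachedHouse",
    "FormalBackyard",
    "InformalBackyard",
    "Informal",
    "CaravanTent",
    "Other",
    "Unknown",
    "NotApplicable",
]

ROOMS = [str(i) for i in range(1, 21)]

TENURE = [
    "Rented",
    "OwnedNotPaidOff",
    "OccupiedRentFree",
    "OwnedPaidOff",
    "Other",
]

# Gross annual household income bands, 2011 ZAR; 13th level is households
# that did not specify an income.
INCOME = [
    "0",
    "1-4800",
    "4801-9600",
    "9601-19200",
    "19201-38400",
    "38401-76800",
    "76801-153600",
    "153601-307200",
    "307201-614400",
    "614401-1228800",
    "1228801-2457600",
    "2457601+",
    "Unspecified",
]

# Upper value of each income band in 2011 ZAR.  The open-ended top band
# continues the doubling progression of the published bands; "Unspecified"
# has no numeric value.
INCOME_UPPER_ZAR: dict[str, float | None] = {
    "0": 0.0,
    "1-4800": 4800.0,
    "4801-9600": 9600.0,
    "9601-19200": 19200.0,
    "19201-38400": 38400.0,
    "38401-76800": 76800.0,
    "76801-153600": 153600.0,
    "153601-307200": 307200.0,
    "307201-614400": 614400.0,
    "614401-1228800": 1228800.0,
    "1228801-2457600": 2457600.0,
    "2457601+": 4915200.0,
    "Unspecified": None,
}

AGE = [
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85+",
]

GENDER = ["Male", "Female"]

RACE = ["BlackAfrican", "Coloured", "IndianAsian", "White", "Other"]

EMPLOY = ["Yes", "No"]

EDU = [
    "None",
    "SomePrimary",
    "Primary",
    "SomeSecondary",
    "Secondary",
    "Tertiary",
    "Other",
    "Unspecified",
]

STUDY = [
    "None",
    "Preschool",
    "School",
    "Tertiary",
    "AdultEducation",
    "HomeSchooling",
    "Unknown",
    "NotApplicable",
    "Unspecified",
]

HOUSEHOLD_VARS = ["housing", "dwelling", "rooms", "tenure", "income"]
PERSON_VARS = ["age", "gender", "race", "employ", "edu", "study"]

#: gender x race person cells in gender-major order (10 cells)
PERSON_CELLS = [(g, r) for g in GENDER for r in RACE]

ROLES = ["head", "spouse", "other"]


@dataclass(frozen=True)
class Schema:
    """Ordered category declarations for every categorical variable."""

    household: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "housing": HOUSING,
            "dwelling": DWELLING,
            "rooms": ROOMS,
            "tenure": TENURE,
            "income": INCOME,
        }
    )
    person: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "age": AGE,
            "gender": GENDER,
            "race": RACE,
            "employ": EMPLOY,
            "edu": EDU,
            "study": STUDY,
        }
    )

    def categories(self, var: str) -> list[str]:
        if var in self.household:
            return list(self.household[var])
        if var in self.person:
            return list(self.person[var])
        raise SchemaError(f"unknown variable {var!r}")

    @property
    def variables(self) -> list[str]:
        return list(self.household) + list(self.person)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        doc = {
            "household": {k: list(v) for k, v in self.household.items()},
            "person": {k: list(v) for k, v in self.person.items()},
        }
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "Schema":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        try:
            return cls(household=doc["household"], person=doc["person"])
        except KeyError as exc:  # pragma: no cover - malformed files
            raise SchemaError(f"schema file missing section {exc}") from exc


DEFAULT_SCHEMA = Schema()
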