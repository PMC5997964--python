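"""Data model for census micro-samples and zone control totals.

A micro-sample is a table with one row per person; persons are grouped into
households by ``household_id`` and carry a sequential ``member_no`` where 1
is the household head, plus a ``role`` column (head / spouse / other).
Households are classified into three mutually exclusive types:

* ``single_member`` -- exactly one person;
* ``dual_role``     -- a head and a spouse (plus any other members);
* ``single_role``   -- a head but no spouse.

Control totals give, per zone, the number of households in each of 13
income bands and the number of persons in each of 10 gender x race cells.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import DEFAULT_SCHEMA, PERSON_CELLS, ROLES, Schema
from .errors import SchemaError, ValidationError

PERSON_COLUMNS = ["household_id", "member_no", "role"]
INCOME_PREFIX = "hh_income_"
PERSON_PREFIX = "pp_"


class HouseholdType(enum.Enum):
    SINGLE_MEMBER = "single_member"
    DUAL_ROLE = "dual_role"
    SINGLE_ROLE = "single_role"


@dataclass(frozen=True)
class PersonRecord:
    household_id: str
    member_no: int
    role: str
    age: str
    gender: str
    race: str
    employ: str
    edu: str
    study: str


@dataclass(frozen=True)
class HouseholdRecord:
    household_id: str
    housing: str
    dwelling: str
    rooms: int
    tenure: str
    income: str
    members: tuple[PersonRecord, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def head(self) -> PersonRecord:
        return next(p for p in self.members if p.role == "head")

    @property
    def spouse(self) -> PersonRecord | None:
        return next((p for p in self.members if p.role == "spouse"), None)

    @property
    def others(self) -> tuple[PersonRecord, ...]:
        return tuple(p for p in self.members if p.role == "other")


def micro_sample_columns(schema: Schema = DEFAULT_SCHEMA) -> list[str]:
    """Column order of the one-row-per-person exchange CSV."""
    return PERSON_COLUMNS + list(schema.household) + list(schema.person)


def _validate_categories(df: pd.DataFrame, schema: Schema) -> None:
    for var in schema.variables:
        allowed = set(schema.categories(var))
        bad = set(df[var].unique()) - allowed
        if bad:
            raise ValidationError(
                f"column {var!r} contains undeclared categories: {sorted(bad)}"
            )
    bad_roles = set(df["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"column 'role' contains invalid values: {sorted(bad_roles)}")


def read_micro_sample(
    source, schema: Schema = DEFAULT_SCHEMA
) -> list[HouseholdRecord]:
    """Read a one-row-per-person CSV into validated household records.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ValidationError
        if categories fall outside the declared sets, member numbers are
        not unique within a household, or a household has no head or more
        than one head/spouse.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = micro_sample_columns(schema)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"micro-sample is missing required column(s): {missing}")
    if len(df) == 0:
        return []
    _validate_categories(df, schema)
    try:
        df["member_no"] = df["member_no"].astype(int)
        df["rooms"] = df["rooms"].astype(int)
    except ValueError as exc:
        raise ValidationError(f"non-integer member_no or rooms value: {exc}") from exc
    return records_from_frame(df, schema)


def records_from_frame(df: pd.DataFrame, schema: Schema = DEFAULT_SCHEMA) -> list[HouseholdRecord]:
    """Group a validated per-person frame into household records."""
    person_vars = list(schema.person)
    household_vars = list(schema.household)
    bad_heads: list[str] = []
    bad_members: list[str] = []
    records: list[HouseholdRecord] = []
    for hh_id, grp in df.groupby("household_id", sort=True):
        grp = grp.sort_values("member_no")
        member_nos = grp["member_no"].to_numpy()
        if len(np.unique(member_nos)) != len(member_nos):
            bad_members.append(str(hh_id))
            continue
        roles = grp["role"].tolist()
        n_heads = roles.count("head")
        n_spouse = roles.count("spouse")
        head_first = n_heads == 1 and roles[grp["member_no"].tolist().index(1)] == "head" if 1 in set(member_nos) else False
        if n_heads != 1 or n_spouse > 1 or not head_first:
            bad_heads.append(str(hh_id))
            continue
        for var in household_vars:
            if grp[var].nunique() != 1:
                raise ValidationError(
                    f"household {hh_id!r} has inconsistent values for {var!r}"
                )
        first = grp.iloc[0]
        members = tuple(
            PersonRecord(
                household_id=str(hh_id),
                member_no=int(row["member_no"]),
                role=row["role"],
                **{v: row[v] for v in person_vars},
            )
            for _, row in grp.iterrows()
        )
        records.append(
            HouseholdRecord(
                household_id=str(hh_id),
                housing=first["housing"],
                dwelling=first["dwelling"],
                rooms=int(first["rooms"]),
                tenure=first["tenure"],
                income=first["income"],
                members=members,
            )
        )
    if bad_members:
        raise ValidationError(f"duplicate member_no within household(s): {bad_members}")
    if bad_heads:
        raise ValidationError(
            f"household(s) without exactly one head (member 1) or with multiple "
            f"spouses: {bad_heads}"
        )
    return records


def records_to_frame(
    records: Iterable[HouseholdRecord], schema: Schema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Flatten household records into the one-row-per-person exchange frame."""
    rows = []
    for h in records:
        for p in h.members:
            rows.append(
                {
                    "household_id": h.household_id,
                    "member_no": p.member_no,
                    "role": p.role,
                    "housing": h.housing,
                    "dwelling": h.dwelling,
                    "rooms": h.rooms,
                    "tenure": h.tenure,
                    "income": h.income,
                    **{v: getattr(p, v) for v in schema.person},
                }
            )
    return pd.DataFrame(rows, columns=micro_sample_columns(schema))


def write_micro_sample(
    records: Iterable[HouseholdRecord], sink, schema: Schema = DEFAULT_SCHEMA
) -> None:
    records_to_frame(records, schema).to_csv(sink, index=False)


def classify_household(h: HouseholdRecord) -> HouseholdType:
    """Classify a valid household into one of the three types."""
    if h.n == 1:
        return HouseholdType.SINGLE_MEMBER
    if any(p.role == "spouse" for p in h.members):
        return HouseholdType.DUAL_ROLE
    return HouseholdType.SINGLE_ROLE


def type_fractions(
    households: Sequence[HouseholdRecord], weight: str = "households"
) -> dict[HouseholdType, float]:
    """Share of each household type.

    ``weight="households"`` counts households; ``weight="individuals"``
    counts the persons they contain.
    """
    if len(households) == 0:
        raise ValidationError("cannot compute type fractions of an empty collection")
    if weight not in {"households", "individuals"}:
        raise ValueError(f"unknown weight {weight!r}")
    counts = {t: 0 for t in HouseholdType}
    for h in households:
        counts[classify_household(h)] += 1 if weight == "households" else h.n
    total = sum(counts.values())
    return {t: c / total for t, c in counts.items()}


# ---------------------------------------------------------------------------
# Control totals
# ---------------------------------------------------------------------------


def control_columns(schema: Schema = DEFAULT_SCHEMA) -> list[str]:
    income = [INCOME_PREFIX + band for band in schema.household["income"]]
    person = [f"{PERSON_PREFIX}{g}_{r}" for g, r in PERSON_CELLS]
    return income + person


@dataclass
class ControlTable:
    """Per-zone calibration targets: 13 household-income counts and 10
    person gender x race counts per zone."""

    df: pd.DataFrame  # indexed by zone_id
    schema: Schema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self):
        cols = control_columns(self.schema)
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise SchemaError(f"control table missing column(s): {missing}")
        self.df = self.df[cols]
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated zone_id(s): {dups}")
        if (self.df.to_numpy() < 0).any():
            raise ValidationError("control table contains negative counts")

    @property
    def zones(self) -> list[str]:
        return [str(z) for z in self.df.index]

    @property
    def income_columns(self) -> list[str]:
        return [INCOME_PREFIX + band for band in self.schema.household["income"]]

    @property
    def person_columns(self) -> list[str]:
        return [f"{PERSON_PREFIX}{g}_{r}" for g, r in PERSON_CELLS]

    def income_totals(self, zone_id: str) -> np.ndarray:
        return self.df.loc[zone_id, self.income_columns].to_numpy(dtype=float)

    def person_totals(self, zone_id: str) -> np.ndarray:
        return self.df.loc[zone_id, self.person_columns].to_numpy(dtype=float)

    def targets(self, zone_id: str) -> np.ndarray:
        """The full 23-vector of targets in design-matrix column order."""
        return self.df.loc[zone_id].to_numpy(dtype=float)

    def household_target(self, zone_id: str) -> float:
        return float(self.income_totals(zone_id).sum())

    def person_target(self, zone_id: str) -> float:
        return float(self.person_totals(zone_id).sum())

    def to_csv(self, sink) -> None:
        self.df.rename_axis("zone_id").to_csv(sink)

    @classmethod
    def read(cls, source, schema: Schema = DEFAULT_SCHEMA) -> "ControlTable":
        df = pd.read_csv(source, dtype={"zone_id": str})
        if "zone_id" not in df.columns:
            raise SchemaError("control table missing column(s): ['zone_id']")
        df = df.set_index("zone_id")
        return cls(df=df, schema=schema)


def read_control_table(source, schema: Schema = DEFAULT_SCHEMA) -> ControlTable:
    return ControlTable.read(source, schema)
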