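"""The five household networks and the pool-generation stage.

Three household types are modelled:

* single-member households -- one network, ``g1``, over the household
  attributes plus the person attributes of the sole member;
* dual-role households (head + spouse) -- ``g21`` over household
  attributes, head and spouse attributes and the household size ``n``;
  ``g22`` over (head, spouse, member) attributes for the remaining
  members, with only head/spouse -> member edges allowed;
* single-role households (head, no spouse) -- ``g31`` and ``g32``
  analogously.

Blacklist semantics: nothing may point into Age, Gender or Race --
demographics cannot be *caused* by housing or socioeconomics -- except
that in ``g21`` the head's and spouse's Age/Gender/Race may influence
each other (partner choice).  No whitelists are used.

Generation draws a pool of households to quota: ``s1 = f1 * P``
single-member individuals, then whole dual-role households until their
individuals reach ``s2 = f2 * P``, then whole single-role households
until the pool holds at least ``P`` individuals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bn as bnlib
from .bn import Bn, EdgeConstraints, fit_cpts, hill_climb, sample, sample_given
from .categories import DEFAULT_SCHEMA, HOUSEHOLD_VARS, PERSON_VARS, Schema
from .errors import ConstraintError, ValidationError
from .reference_data import (
    HouseholdRecord,
    HouseholdType,
    classify_household,
    type_fractions,
)

AGR = ("age", "gender", "race")  # demographic variables shielded by blacklists

NETWORKS = ("g1", "g21", "g22", "g31", "g32")


def head_col(v: str) -> str:
    return f"head_{v}"


def spouse_col(v: str) -> str:
    return f"spouse_{v}"


def member_col(v: str) -> str:
    return f"member_{v}"


def network_groups(network: str, schema: Schema = DEFAULT_SCHEMA) -> dict[str, list[str]]:
    """The named variable groups making up each network's node set."""
    hh = list(schema.household)
    pp = list(schema.person)
    if network == "g1":
        return {"household": hh, "person": pp}
    if network == "g21":
        return {
            "household": hh,
            "head": [head_col(v) for v in pp],
            "spouse": [spouse_col(v) for v in pp],
            "n": ["n"],
        }
    if network == "g22":
        return {
            "head": [head_col(v) for v in pp],
            "spouse": [spouse_col(v) for v in pp],
            "member": [member_col(v) for v in pp],
        }
    if network == "g31":
        return {
            "household": hh,
            "head": [head_col(v) for v in pp],
            "n": ["n"],
        }
    if network == "g32":
        return {
            "head": [head_col(v) for v in pp],
            "member": [member_col(v) for v in pp],
        }
    raise ValidationError(f"unknown network {network!r}")


def build_blacklists(
    variable_sets: Mapping[str, Sequence[str]], network: str
) -> EdgeConstraints:
    """Edge constraints for one of the five networks.

    ``variable_sets`` maps group names (``household``, ``person``,
    ``head``, ``spouse``, ``member``, ``n``) to node-name lists; unknown
    group names raise.  The whitelist is always empty.
    """
    known = {"household", "person", "head", "spouse", "member", "n"}
    unknown = set(variable_sets) - known
    if unknown:
        raise ValidationError(f"unknown variable group(s): {sorted(unknown)}")
    groups = {k: list(v) for k, v in variable_sets.items()}
    all_nodes = [v for vs in groups.values() for v in vs]

    def is_agr(col: str) -> bool:
        base = col.split("_", 1)[-1] if "_" in col else col
        return base in AGR

    blacklist: set[tuple[str, str]] = set()
    if network == "g1":
        protected = [v for v in groups.get("person", []) if is_agr(v)]
        for v in protected:
            for u in all_nodes:
                if u != v:
                    blacklist.add((u, v))
    elif network in {"g21", "g31"}:
        head = groups.get("head", [])
        spouse = groups.get("spouse", [])
        protected = [v for v in head + spouse if is_agr(v)]
        for v in protected:
            partner = spouse if v in head else head
            allowed_sources = {u for u in partner if is_agr(u)} if network == "g21" else set()
            for u in all_nodes:
                if u != v and u not in allowed_sources:
                    blacklist.add((u, v))
    elif network in {"g22", "g32"}:
        sources = groups.get("head", []) + groups.get("spouse", [])
        members = groups.get("member", [])
        for u in all_nodes:
            for v in all_nodes:
                if u == v:
                    continue
                if u in sources and v in members:
                    continue
                blacklist.add((u, v))
    else:
        raise ValidationError(f"unknown network {network!r}")
    return EdgeConstraints.make(blacklist=blacklist)


def network_levels(
    network: str, schema: Schema = DEFAULT_SCHEMA, n_support: Sequence[int] | None = None
) -> dict[str, list[str]]:
    """Declared category order for every node of a network."""
    groups = network_groups(network, schema)
    levels: dict[str, list[str]] = {}
    for group, cols in groups.items():
        for col in cols:
            if col == "n":
                if n_support is None:
                    raise ValidationError(f"{network} needs an n_support declaration")
                levels["n"] = [str(int(k)) for k in sorted(n_support)]
            else:
                base = col.split("_", 1)[-1] if group in {"head", "spouse", "member"} else col
                levels[col] = schema.categories(base)
    return levels


# ---------------------------------------------------------------------------
# Training tables
# ---------------------------------------------------------------------------


def training_tables(
    records: Sequence[HouseholdRecord], schema: Schema = DEFAULT_SCHEMA
) -> dict[str, pd.DataFrame]:
    """Per-network training frames extracted from classified households.

    A dual-role household of size n contributes one row to g21 and n-2
    rows to g22 (one per non-head non-spouse member), each carrying the
    head's and spouse's person attributes alongside the member's own.
    """
    rows: dict[str, list[dict]] = {g: [] for g in NETWORKS}
    pp = list(schema.person)
    for h in records:
        htype = classify_household(h)
        hh_vals = {v: str(getattr(h, v)) for v in schema.household}
        if htype is HouseholdType.SINGLE_MEMBER:
            p = h.members[0]
            rows["g1"].append({**hh_vals, **{v: getattr(p, v) for v in pp}})
        elif htype is HouseholdType.DUAL_ROLE:
            head, spouse = h.head, h.spouse
            hvals = {head_col(v): getattr(head, v) for v in pp}
            svals = {spouse_col(v): getattr(spouse, v) for v in pp}
            rows["g21"].append({**hh_vals, **hvals, **svals, "n": str(h.n)})
            for m in h.others:
                rows["g22"].append(
                    {**hvals, **svals, **{member_col(v): getattr(m, v) for v in pp}}
                )
        else:
            head = h.head
            hvals = {head_col(v): getattr(head, v) for v in pp}
            rows["g31"].append({**hh_vals, **hvals, "n": str(h.n)})
            for m in h.others:
                rows["g32"].append(
                    {**hvals, **{member_col(v): getattr(m, v) for v in pp}}
                )
    return {g: pd.DataFrame(r) for g, r in rows.items()}


@dataclass
class FittedModels:
    """The five fitted networks plus the household-type mix."""

    g1: Bn | None = None
    g21: Bn | None = None
    g22: Bn | None = None
    g31: Bn | None = None
    g32: Bn | None = None
    fractions: dict[HouseholdType, float] = field(default_factory=dict)
    schema: Schema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def require(self, name: str) -> Bn:
        model = getattr(self, name)
        if model is None:
            raise ValidationError(f"network {name} was not fitted (empty training subset)")
        return model

    def to_json(self) -> str:
        doc = {
            "networks": {
                g: json.loads(getattr(self, g).to_json())
                for g in NETWORKS
                if getattr(self, g) is not None
            },
            "fractions": {t.value: f for t, f in self.fractions.items()},
        }
        return json.dumps(doc)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str, schema: Schema = DEFAULT_SCHEMA) -> "FittedModels":
        doc = json.loads(text)
        kwargs = {
            g: Bn.from_json(json.dumps(net)) for g, net in doc["networks"].items()
        }
        fractions = {HouseholdType(k): v for k, v in doc.get("fractions", {}).items()}
        return cls(fractions=fractions, schema=schema, **kwargs)

    @classmethod
    def load(cls, path: str | Path, schema: Schema = DEFAULT_SCHEMA) -> "FittedModels":
        return cls.from_json(Path(path).read_text(), schema)


def fit_models(
    records: Sequence[HouseholdRecord],
    schema: Schema = DEFAULT_SCHEMA,
    smoothing: float = 1.0,
    max_parents: int | None = None,
    required: Sequence[str] | None = None,
) -> FittedModels:
    """Fit every network with a nonempty training subset.

    ``required`` names networks that must be fittable; an empty training
    subset for a required network raises naming the household type.
    """
    if len(records) == 0:
        raise ValidationError("cannot fit models on an empty micro-sample")
    tables = training_tables(records, schema)
    required = list(required) if required is not None else []
    type_of = {"g1": "single_member", "g21": "dual_role", "g22": "dual_role",
               "g31": "single_role", "g32": "single_role"}
    fitted: dict[str, Bn] = {}
    for g in NETWORKS:
        table = tables[g]
        if len(table) == 0:
            if g in required:
                raise ValidationError(
                    f"no training records for network {g} (household type "
                    f"{type_of[g]})"
                )
            continue
        n_support = None
        if g in {"g21", "g31"}:
            n_support = sorted({int(v) for v in table["n"].unique()})
        levels = network_levels(g, schema, n_support)
        constraints = build_blacklists(network_groups(g, schema), g)
        dag = hill_climb(table, levels, constraints, max_parents=max_parents)
        fitted[g] = fit_cpts(dag, table, levels, smoothing=smoothing)
    return FittedModels(
        fractions=type_fractions(records), schema=schema, **fitted
    )


# ---------------------------------------------------------------------------
# Quotas and pool generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolConfig:
    """Pool size P (individuals), type fractions (f1, f2, f3) and seed."""

    pool_size: int
    fractions: tuple[float, float, float]
    seed: int = 0

    def __post_init__(self):
        if self.pool_size <= 0:
            raise ValidationError("pool_size must be positive")
        if any(f < 0 for f in self.fractions):
            raise ValidationError("fractions must be nonnegative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1")


@dataclass(frozen=True)
class Quotas:
    """Individual-level quotas: s1 exact, s2 and total are >= thresholds."""

    s1: int
    s2: float
    total: int


def compute_quotas(cfg: PoolConfig) -> Quotas:
    """Quota arithmetic: s1 = round(f1*P) (half-up), s2 = f2*P, total = P."""
    f1, f2, _ = cfg.fractions
    s1 = int(math.floor(f1 * cfg.pool_size + 0.5))
    return Quotas(s1=s1, s2=f2 * cfg.pool_size, total=cfg.pool_size)


@dataclass
class HouseholdPool:
    """Synthesized households (pre-calibration) as a frame pair.

    ``households`` has one row per household (id, htype, household
    attributes, n); ``persons`` one row per member (household_id,
    member_no, role, person attributes).
    """

    households: pd.DataFrame
    persons: pd.DataFrame
    schema: Schema = field(default_factory=lambda: DEFAULT_SCHEMA)

    @property
    def counts(self) -> dict[str, int]:
        sizes = self.persons.groupby("household_id").size()
        by_type = self.households.set_index("household_id")["htype"]
        ind = sizes.groupby(by_type).sum().to_dict()
        return {
            "s1_actual": int(ind.get("single_member", 0)),
            "s2_actual": int(ind.get("dual_role", 0)),
            "s3_actual": int(ind.get("single_role", 0)),
            "total_individuals": int(len(self.persons)),
            "total_households": int(len(self.households)),
        }

    def to_csv(self, households_path, persons_path) -> None:
        self.households.to_csv(households_path, index=False)
        self.persons.to_csv(persons_path, index=False)

    @classmethod
    def from_csv(cls, households_path, persons_path, schema: Schema = DEFAULT_SCHEMA):
        hh = pd.read_csv(households_path, dtype=str, keep_default_na=False)
        hh["n"] = hh["n"].astype(int)
        pp = pd.read_csv(persons_path, dtype=str, keep_default_na=False)
        pp["member_no"] = pp["member_no"].astype(int)
        return cls(households=hh, persons=pp, schema=schema)


def _strip_prefix(df: pd.DataFrame, prefix: str, cols: Sequence[str]) -> pd.DataFrame:
    return df[[f"{prefix}{c}" for c in cols]].rename(
        columns={f"{prefix}{c}": c for c in cols}
    )


def _draw_valid(
    bn: Bn, n_min: int, need: int, rng: np.random.Generator, batch: int = 4096,
    max_consecutive_invalid: int = 1000,
) -> pd.DataFrame:
    """Draw at least ``need`` rows with household size >= n_min, rejecting
    invalid draws; errors after 1000 consecutive rejections."""
    chunks: list[pd.DataFrame] = []
    got = 0
    consecutive_invalid = 0
    while got < need:
        draw = sample(bn, batch, rng)
        valid = draw[draw["n"].astype(int) >= n_min]
        if len(valid) == 0:
            consecutive_invalid += batch
            if consecutive_invalid >= max_consecutive_invalid:
                raise ValidationError(
                    f"household-size rejection did not find n >= {n_min} in "
                    f"{consecutive_invalid} draws"
                )
            continue
        consecutive_invalid = 0
        chunks.append(valid)
        got += len(valid)
    return pd.concat(chunks, ignore_index=True)


def generate_pool(
    models: FittedModels,
    cfg: PoolConfig,
    rng: np.random.Generator | None = None,
) -> HouseholdPool:
    """Generate the household pool to the configured quotas.

    Reproducible for a fixed ``cfg.seed``; whole households are appended,
    so the dual-role and total individual counts may overshoot their
    thresholds by strictly less than one maximum household size.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    schema = models.schema
    quotas = compute_quotas(cfg)
    pp = list(schema.person)
    hh_vars = list(schema.household)

    hh_rows: list[pd.DataFrame] = []
    person_rows: list[pd.DataFrame] = []
    hh_counter = 0

    def hh_ids(k: int, tag: str) -> np.ndarray:
        nonlocal hh_counter
        ids = np.array([f"pool_{tag}_{hh_counter + i}" for i in range(k)])
        hh_counter += k
        return ids

    # --- single-member households -------------------------------------
    if quotas.s1 > 0:
        g1 = models.require("g1")
        draw = sample(g1, quotas.s1, rng)
        ids = hh_ids(quotas.s1, "s")
        hh_rows.append(
            pd.DataFrame(
                {"household_id": ids, "htype": "single_member",
                 **{v: draw[v] for v in hh_vars}, "n": 1}
            )
        )
        person_rows.append(
            pd.DataFrame(
                {"household_id": ids, "member_no": 1, "role": "head",
                 **{v: draw[v] for v in pp}}
            )
        )

    def _append_type(main: Bn, member: Bn | None, tag: str, htype: str,
                     n_min: int, target: float, running: int) -> int:
        """Append whole households of one multi-member type until the
        cumulative individual count reaches ``target``; returns the count."""
        while running < target:
            remaining = target - running
            need = max(1, int(math.ceil(remaining / max(n_min, 1))))
            draws = _draw_valid(main, n_min, min(need, 20000), rng)
            ns = draws["n"].astype(int).to_numpy()
            cum = running + np.cumsum(ns)
            take = int(np.searchsorted(cum, target) + 1)
            take = min(take, len(draws))
            draws = draws.iloc[:take]
            ns = ns[:take]
            running = int(cum[take - 1])
            ids = hh_ids(take, tag)
            hh_rows.append(
                pd.DataFrame(
                    {"household_id": ids, "htype": htype,
                     **({v: draws[v].to_numpy() for v in hh_vars}
                        if hh_vars[0] in draws.columns else
                        {v: draws[v].to_numpy() for v in hh_vars}),
                     "n": ns}
                )
            )
            # head (and spouse) persons
            head = _strip_prefix(draws, "head_", pp)
            person_rows.append(
                pd.DataFrame({"household_id": ids, "member_no": 1, "role": "head",
                              **{v: head[v].to_numpy() for v in pp}})
            )
            has_spouse = f"spouse_{pp[0]}" in draws.columns
            if has_spouse:
                spouse = _strip_prefix(draws, "spouse_", pp)
                person_rows.append(
                    pd.DataFrame({"household_id": ids, "member_no": 2, "role": "spouse",
                                  **{v: spouse[v].to_numpy() for v in pp}})
                )
            # remaining members, conditional on head (and spouse)
            base = 2 if has_spouse else 1
            extra = ns - base
            if member is not None and (extra > 0).any():
                reps = np.repeat(np.arange(take), extra)
                ev_cols = [c for c in draws.columns
                           if c.startswith("head_") or c.startswith("spouse_")]
                ev_cols = [c for c in ev_cols if c in member.dag.nodes]
                evidence = draws.iloc[reps][ev_cols].reset_index(drop=True)
                mem = sample_given(member, evidence, rng)
                mem_attrs = _strip_prefix(mem, "member_", pp)
                member_no = np.concatenate(
                    [np.arange(base + 1, base + 1 + e) for e in extra if e > 0]
                ) if (extra > 0).any() else np.array([], dtype=int)
                person_rows.append(
                    pd.DataFrame({"household_id": np.repeat(ids, extra),
                                  "member_no": member_no, "role": "other",
                                  **{v: mem_attrs[v].to_numpy() for v in pp}})
                )
            elif (extra > 0).any() and member is None:
                raise ValidationError(
                    f"{htype} households of size > {base} need the member network"
                )
        return running

    # --- dual-role households -----------------------------------------
    f2 = cfg.fractions[1]
    s2_actual = 0
    if f2 > 0 and quotas.s2 > 0:
        s2_actual = _append_type(
            models.require("g21"), models.g22, "d", "dual_role", 2, quotas.s2, 0
        )

    # --- single-role households to fill the pool ----------------------
    total_so_far = quotas.s1 + s2_actual
    f3 = cfg.fractions[2]
    if f3 > 0 and total_so_far < quotas.total:
        _append_type(
            models.require("g31"), models.g32, "r", "single_role", 1,
            quotas.total, total_so_far,
        )

    households = (
        pd.concat(hh_rows, ignore_index=True)
        if hh_rows
        else pd.DataFrame(columns=["household_id", "htype", *hh_vars, "n"])
    )
    persons = (
        pd.concat(person_rows, ignore_index=True)
        if person_rows
        else pd.DataFrame(columns=["household_id", "member_no", "role", *pp])
    )
    persons = persons.sort_values(["household_id", "member_no"], kind="stable")
    persons = persons.reset_index(drop=True)
    return HouseholdPool(households=households, persons=persons, schema=schema)
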