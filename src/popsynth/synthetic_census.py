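"""Synthetic census fixtures with known ground truth.

Emulates the two real inputs the pipeline is designed for -- a household
micro-sample and per-zone control totals aggregated from a full
population -- by simulating every household of every zone from
hand-specified generating networks that honour the package's blacklist
semantics (no edges into Age/Gender/Race anywhere; in the dual-role
household network the head's and spouse's demographics may influence each
other).  Control totals are exact recounts of the simulated population,
so calibration targets are attainable by construction.

Two complexity levels are provided: ``small`` networks cover 4-6
variables per household type (unmodelled attributes are filled with a
constant default so records remain schema-complete), ``medium`` networks
cover the full variable set.  Child CPTs are sharp (a dominant category
per parent configuration, rotated so marginals stay spread) to make
structure and parameters recoverable from realistic sample sizes;
household-size distributions are kept moderate with support capped at 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn import Bn, Dag, sample, sample_given
from .categories import DEFAULT_SCHEMA, PERSON_CELLS, Schema
from .errors import ValidationError
from .household_models import (
    FittedModels,
    head_col,
    member_col,
    network_levels,
    spouse_col,
)
from .reference_data import (
    ControlTable,
    HouseholdRecord,
    HouseholdType,
    control_columns,
    records_from_frame,
)

DEFAULT_FILL = {
    "housing": "House",
    "dwelling": "FormalHouse",
    "rooms": "1",
    "tenure": "Rented",
    "income": "0",
    "age": "20-24",
    "gender": "Male",
    "race": "BlackAfrican",
    "employ": "No",
    "edu": "None",
    "study": "None",
}


def _root_probs(rng: np.random.Generator, r: int) -> np.ndarray:
    """A spread marginal: every category keeps at least 0.5/r mass."""
    return 0.5 / r + 0.5 * rng.dirichlet(np.full(r, 2.0))


def _sharp_cpt(
    rng: np.random.Generator, parent_cards: tuple[int, ...], r: int,
    dominant: float = 0.98,
) -> np.ndarray:
    """One dominant category per parent configuration, rotated through the
    categories so the child's marginal stays spread."""
    q = int(np.prod(parent_cards)) if parent_cards else 1
    rows = np.full((q, r), (1.0 - dominant) / (r - 1))
    perm = rng.permutation(r)
    for j in range(q):
        rows[j, perm[j % r]] = dominant
    return rows.reshape(*parent_cards, r)


def _moderate_cpt(
    rng: np.random.Generator, parent_cards: tuple[int, ...], r: int
) -> np.ndarray:
    """Spread rows for the household-size node (sizes should vary)."""
    q = int(np.prod(parent_cards)) if parent_cards else 1
    rows = np.stack([_root_probs(rng, r) for _ in range(q)])
    return rows.reshape(*parent_cards, r)


def _build_bn(
    levels: dict[str, list[str]],
    edges: list[tuple[str, str]],
    rng: np.random.Generator,
    moderate_nodes: tuple[str, ...] = ("n",),
) -> Bn:
    cards = {v: len(c) for v, c in levels.items()}
    dag = Dag(list(levels), cards, edges)
    cpts: dict[str, np.ndarray] = {}
    for v in dag.nodes:
        parents = dag.parents(v)
        pcards = tuple(cards[p] for p in parents)
        if not parents:
            cpts[v] = (
                _root_probs(rng, cards[v])
                if v not in moderate_nodes
                else _root_probs(rng, cards[v])
            )
        elif v in moderate_nodes:
            cpts[v] = _moderate_cpt(rng, pcards, cards[v])
        else:
            cpts[v] = _sharp_cpt(rng, pcards, cards[v])
    return Bn(dag=dag, levels=levels, cpts=cpts)


@dataclass
class GroundTruth:
    """Generating models, type mix, and bookkeeping for a fixture."""

    models: FittedModels
    mix: dict[HouseholdType, float]
    schema: Schema
    complexity: str
    seed: int
    fill: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FILL))

    def generating_edges(self) -> dict[str, set]:
        out = {}
        for g in ("g1", "g21", "g22", "g31", "g32"):
            bn = getattr(self.models, g)
            if bn is not None:
                out[g] = set(bn.dag.edges)
        return out


def _medium_networks(schema: Schema, rng: np.random.Generator) -> dict[str, Bn]:
    pp = list(schema.person)
    h, s, m = head_col, spouse_col, member_col
    nets = {}
    nets["g1"] = _build_bn(
        network_levels("g1", schema),
        [("gender", "employ"), ("employ", "income"),
         ("gender", "edu"), ("employ", "study")],
        rng,
    )
    g21_levels = network_levels("g21", schema, n_support=range(2, 7))
    nets["g21"] = _build_bn(
        g21_levels,
        [(h("age"), s("age")), (h("gender"), s("gender")), (h("race"), s("race")),
         (h("gender"), h("employ")), (s("gender"), s("employ")),
         (h("employ"), "income"), (h("race"), "tenure"),
         (h("employ"), h("edu")), (s("employ"), s("edu")), (h("employ"), "n")],
        rng,
    )
    nets["g22"] = _build_bn(
        network_levels("g22", schema),
        [(h("race"), m("edu")), (s("race"), m("employ")), (h("age"), m("study"))],
        rng,
    )
    # single-role sizes start at 2: a size-1 household with only a head is by
    # definition a single-member household, so the designed mix stays exact
    g31_levels = network_levels("g31", schema, n_support=range(2, 7))
    nets["g31"] = _build_bn(
        g31_levels,
        [(h("gender"), h("employ")), (h("employ"), "income"),
         (h("race"), "tenure"), (h("employ"), h("edu")), (h("employ"), "n")],
        rng,
    )
    nets["g32"] = _build_bn(
        network_levels("g32", schema),
        [(h("race"), m("edu")), (h("age"), m("study"))],
        rng,
    )
    assert pp  # person variables exist by construction
    return nets


def _small_networks(schema: Schema, rng: np.random.Generator) -> dict[str, Bn]:
    """4-6 modelled variables per type; the rest are filled constants."""
    hc = schema.categories
    h, s, m = head_col, spouse_col, member_col

    def lv(pairs):
        return {k: list(v) for k, v in pairs}

    nets = {}
    nets["g1"] = _build_bn(
        lv([("income", hc("income")), ("tenure", hc("tenure")),
            ("age", hc("age")), ("gender", hc("gender")), ("race", hc("race"))]),
        [("gender", "income"), ("race", "tenure")],
        rng,
    )
    nets["g21"] = _build_bn(
        lv([("income", hc("income")),
            (h("gender"), hc("gender")), (h("race"), hc("race")),
            (s("gender"), hc("gender")), (s("race"), hc("race")),
            ("n", [str(k) for k in range(2, 6)])]),
        [(h("gender"), s("gender")), (h("race"), s("race")),
         (h("race"), "income"), (h("gender"), "n")],
        rng,
    )
    nets["g22"] = _build_bn(
        lv([(h("gender"), hc("gender")), (h("race"), hc("race")),
            (s("gender"), hc("gender")), (s("race"), hc("race")),
            (m("gender"), hc("gender")), (m("race"), hc("race"))]),
        [(h("race"), m("race"))],
        rng,
    )
    nets["g31"] = _build_bn(
        lv([("income", hc("income")),
            (h("gender"), hc("gender")), (h("race"), hc("race")),
            ("n", [str(k) for k in range(2, 6)])]),
        [(h("race"), "income")],
        rng,
    )
    nets["g32"] = _build_bn(
        lv([(h("gender"), hc("gender")), (h("race"), hc("race")),
            (m("gender"), hc("gender")), (m("race"), hc("race"))]),
        [(h("race"), m("race"))],
        rng,
    )
    return nets


def make_ground_truth(
    complexity: str = "small", seed: int = 0, schema: Schema = DEFAULT_SCHEMA
) -> GroundTruth:
    """Build deterministic generating networks for a fixture.

    ``small``: 4-6 variables per household type; ``medium``: the full
    variable set (cardinalities 6/13/20/5/13 and 18/2/5/2/8/9).
    """
    rng = np.random.default_rng(seed)
    if complexity == "medium":
        nets = _medium_networks(schema, rng)
    elif complexity == "small":
        nets = _small_networks(schema, rng)
    else:
        raise ValidationError(f"unknown complexity {complexity!r}")
    mix = {
        HouseholdType.SINGLE_MEMBER: 0.10,
        HouseholdType.DUAL_ROLE: 0.60,
        HouseholdType.SINGLE_ROLE: 0.30,
    }
    models = FittedModels(
        fractions=dict(mix), schema=schema,
        **{g: bn for g, bn in nets.items()},
    )
    return GroundTruth(
        models=models, mix=mix, schema=schema, complexity=complexity, seed=seed
    )


# ---------------------------------------------------------------------------
# Full-population simulation
# ---------------------------------------------------------------------------


def _fill_missing(df: pd.DataFrame, cols: list[str], fill: dict[str, str]) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for c in cols:
        out[c] = df[c].to_numpy() if c in df.columns else fill[c]
    return out


@dataclass
class FullPopulation:
    """Every household of every zone, with exact counts recoverable."""

    households: pd.DataFrame  # household_id, zone_id, household vars, n
    persons: pd.DataFrame  # household_id, member_no, role, person vars
    schema: Schema = field(default_factory=lambda: DEFAULT_SCHEMA)

    @property
    def n_households(self) -> int:
        return len(self.households)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def to_micro_frame(self) -> pd.DataFrame:
        merged = self.persons.merge(
            self.households.drop(columns=["n"]), on="household_id", how="left"
        )
        merged["rooms"] = merged["rooms"].astype(int)
        return merged

    def to_records(self) -> list[HouseholdRecord]:
        return records_from_frame(self.to_micro_frame(), self.schema)

    def control_table(self) -> ControlTable:
        return control_table_from_frames(self.households, self.persons, self.schema)


def control_table_from_frames(
    households: pd.DataFrame, persons: pd.DataFrame, schema: Schema = DEFAULT_SCHEMA
) -> ControlTable:
    """Exact per-zone control totals by recounting a population."""
    income_cats = list(schema.household["income"])
    zones = sorted(households["zone_id"].unique())
    cols = control_columns(schema)
    table = pd.DataFrame(0.0, index=pd.Index(zones, name="zone_id"), columns=cols)
    inc = (
        households.groupby(["zone_id", "income"], sort=True).size().unstack(fill_value=0)
    )
    for band in income_cats:
        if band in inc.columns:
            table.loc[inc.index, f"hh_income_{band}"] = inc[band].to_numpy(dtype=float)
    pz = persons.merge(households[["household_id", "zone_id"]], on="household_id")
    per = pz.groupby(["zone_id", "gender", "race"], sort=True).size()
    for (g, r) in PERSON_CELLS:
        key = f"pp_{g}_{r}"
        for zone in zones:
            try:
                table.loc[zone, key] = float(per.loc[(zone, g, r)])
            except KeyError:
                pass
    return ControlTable(df=table, schema=schema)


def _simulate_type(
    gt: GroundTruth,
    htype: HouseholdType,
    count: int,
    rng: np.random.Generator,
    start_id: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``count`` households of one type from the generating models."""
    schema = gt.schema
    hh_vars = list(schema.household)
    pp = list(schema.person)
    fill = gt.fill
    ids = np.array([f"hh{start_id + i:08d}" for i in range(count)])
    if htype is HouseholdType.SINGLE_MEMBER:
        draw = sample(gt.models.require("g1"), count, rng)
        hh = _fill_missing(draw, hh_vars, fill)
        hh.insert(0, "household_id", ids)
        hh["n"] = 1
        per = _fill_missing(draw, pp, fill)
        per.insert(0, "household_id", ids)
        per.insert(1, "member_no", 1)
        per.insert(2, "role", "head")
        return hh, per

    main = gt.models.require("g21" if htype is HouseholdType.DUAL_ROLE else "g31")
    member_net = gt.models.require(
        "g22" if htype is HouseholdType.DUAL_ROLE else "g32"
    )
    draw = sample(main, count, rng)
    ns = draw["n"].astype(int).to_numpy()
    hh = _fill_missing(draw, hh_vars, fill)
    hh.insert(0, "household_id", ids)
    hh["n"] = ns

    head_df = draw[[c for c in draw.columns if c.startswith("head_")]].rename(
        columns=lambda c: c[len("head_"):]
    )
    head = _fill_missing(head_df, pp, fill)
    head.insert(0, "household_id", ids)
    head.insert(1, "member_no", 1)
    head.insert(2, "role", "head")
    frames = [head]
    base = 1
    if htype is HouseholdType.DUAL_ROLE:
        spouse_df = draw[[c for c in draw.columns if c.startswith("spouse_")]].rename(
            columns=lambda c: c[len("spouse_"):]
        )
        spouse = _fill_missing(spouse_df, pp, fill)
        spouse.insert(0, "household_id", ids)
        spouse.insert(1, "member_no", 2)
        spouse.insert(2, "role", "spouse")
        frames.append(spouse)
        base = 2
    extra = ns - base
    if (extra > 0).any():
        reps = np.repeat(np.arange(count), extra)
        ev_cols = [c for c in draw.columns if c in member_net.dag.nodes]
        evidence = draw.iloc[reps][ev_cols].reset_index(drop=True)
        mem_draw = sample_given(member_net, evidence, rng)
        mem_df = mem_draw[
            [c for c in mem_draw.columns if c.startswith("member_")]
        ].rename(columns=lambda c: c[len("member_"):])
        mem = _fill_missing(mem_df, pp, fill)
        mem.insert(0, "household_id", np.repeat(ids, extra))
        mem.insert(
            1,
            "member_no",
            np.concatenate([np.arange(base + 1, base + 1 + e) for e in extra if e > 0]),
        )
        mem.insert(2, "role", "other")
        frames.append(mem)
    return hh, pd.concat(frames, ignore_index=True)


def simulate_full_population(
    gt: GroundTruth,
    zones: int,
    households_per_zone: int,
    rng: np.random.Generator | None = None,
) -> tuple[FullPopulation, ControlTable]:
    """Simulate every household of every zone; returns the population and
    its exact control table."""
    if rng is None:
        rng = np.random.default_rng(gt.seed + 1)
    total = zones * households_per_zone
    types = [HouseholdType.SINGLE_MEMBER, HouseholdType.DUAL_ROLE,
             HouseholdType.SINGLE_ROLE]
    probs = np.array([gt.mix[t] for t in types])
    type_draw = rng.choice(len(types), size=total, p=probs / probs.sum())
    hh_frames = []
    per_frames = []
    start = 0
    for k, t in enumerate(types):
        count = int((type_draw == k).sum())
        if count == 0:
            continue
        hh, per = _simulate_type(gt, t, count, rng, start)
        start += count
        hh_frames.append(hh)
        per_frames.append(per)
    households = pd.concat(hh_frames, ignore_index=True)
    persons = pd.concat(per_frames, ignore_index=True)
    # shuffle households across zones, equal counts per zone
    zone_ids = np.repeat(
        [f"zone{z:03d}" for z in range(zones)], households_per_zone
    )
    households = households.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1)
    )).reset_index(drop=True)
    households.insert(1, "zone_id", zone_ids[: len(households)])
    pop = FullPopulation(households=households, persons=persons, schema=gt.schema)
    return pop, pop.control_table()


def draw_micro_sample(
    pop: FullPopulation, rate: float, rng: np.random.Generator
) -> list[HouseholdRecord]:
    """Household-level simple random sample (whole households kept)."""
    if not (0 < rate <= 1):
        raise ValidationError("rate must be in (0, 1]")
    keep = rng.random(pop.n_households) < rate
    kept_ids = set(pop.households.loc[keep, "household_id"])
    hh = pop.households[pop.households["household_id"].isin(kept_ids)]
    per = pop.persons[pop.persons["household_id"].isin(kept_ids)]
    sub = FullPopulation(households=hh.reset_index(drop=True),
                         persons=per.reset_index(drop=True), schema=pop.schema)
    return sub.to_records()


def make_zone_geometries(zone_ids: list[str]) -> dict:
    """Simple rectangular polygons, one unit square per zone."""
    from shapely.geometry import box

    from .assembly import ZoneGeometry

    return {
        z: ZoneGeometry(zone_id=z, polygon=box(2.0 * i, 0.0, 2.0 * i + 1.0, 1.0))
        for i, z in enumerate(sorted(zone_ids))
    }
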