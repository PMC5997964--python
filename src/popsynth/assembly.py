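"""Zone-level household selection, coordinate placement and ID assignment.

Each zone draws ``sum(income_totals)`` households from the calibrated
pool with replacement, probability proportional to the raking weights
(the pool is only ~20% of the population, so households are reused).
Every selected household copy is placed at a uniform random point inside
the zone polygon (WGS84 decimal degrees, bounding-box rejection
sampling), households are renumbered consecutively from zero across all
zones (zone order lexicographic, then draw order) and persons receive
consecutive unique IDs with a back-pointer to their household.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .categories import DEFAULT_SCHEMA, INCOME_UPPER_ZAR, Schema
from .errors import ValidationError
from .household_models import HouseholdPool
from .raking import ZoneWeights
from .reference_data import ControlTable


@dataclass
class ZoneGeometry:
    """A zone polygon in WGS84 longitude/latitude decimal degrees."""

    zone_id: str
    polygon: BaseGeometry

    def __post_init__(self):
        if self.polygon.is_empty or not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValidationError(f"zone {self.zone_id!r}: invalid or empty polygon")


def load_geometries(source: str | Path) -> dict[str, ZoneGeometry]:
    """Read zone polygons from a GeoJSON FeatureCollection.

    Each feature needs a ``zone_id`` property and a (Multi)Polygon
    geometry.
    """
    doc = json.loads(Path(source).read_text())
    out: dict[str, ZoneGeometry] = {}
    for feat in doc.get("features", []):
        zid = str(feat.get("properties", {}).get("zone_id", ""))
        if not zid:
            raise ValidationError("GeoJSON feature without a zone_id property")
        out[zid] = ZoneGeometry(zone_id=zid, polygon=shape(feat["geometry"]))
    return out


def save_geometries(geoms: Mapping[str, ZoneGeometry], sink: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"zone_id": g.zone_id},
                "geometry": g.polygon.__geo_interface__,
            }
            for g in geoms.values()
        ],
    }
    Path(sink).write_text(json.dumps(doc))


def sample_zone(
    pool: HouseholdPool,
    weights: ZoneWeights,
    targets_row: np.ndarray | float,
    rng: np.random.Generator,
) -> list[str]:
    """Draw the zone's households (pool household ids, with multiplicity).

    ``targets_row`` is the 23-vector of zone targets or the household
    total directly; the number of draws is the zone's household total.
    """
    arr = np.atleast_1d(np.asarray(targets_row, dtype=float))
    h_z = int(round(arr[:13].sum())) if arr.size > 1 else int(round(arr[0]))
    if h_z == 0:
        return []
    w = weights.weights
    if w.sum() <= 0:
        raise ValidationError(f"zone {weights.zone_id!r}: nonpositive weight total")
    p = w / w.sum()
    idx = rng.choice(len(w), size=h_z, replace=True, p=p)
    return [weights.household_ids[i] for i in idx]


def place_household(
    zone: ZoneGeometry, rng: np.random.Generator, max_rejections: int = 10000
) -> tuple[float, float]:
    """Uniform random point strictly inside the zone polygon."""
    minx, miny, maxx, maxy = zone.polygon.bounds
    for _ in range(max_rejections):
        x = minx + (maxx - minx) * rng.random()
        y = miny + (maxy - miny) * rng.random()
        if zone.polygon.contains(Point(x, y)):
            return (x, y)
    raise ValidationError(
        f"zone {zone.zone_id!r}: no interior point found in {max_rejections} draws"
    )


@dataclass
class SyntheticPopulation:
    """A zone-assigned, coordinate-placed population ready for XML output.

    ``households``: one row per household -- hid (0..H-1), zone_id,
    household attributes, income band and numeric upper value (NaN for
    unspecified), home longitude/latitude, size n.
    ``persons``: one row per person -- pid (0..N-1), hid back-pointer,
    person attributes.
    """

    households: pd.DataFrame
    persons: pd.DataFrame
    schema: Schema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def validate(self) -> None:
        h = self.households
        p = self.persons
        hids = h["hid"].to_numpy()
        if len(hids) and not np.array_equal(np.sort(hids), np.arange(len(hids))):
            raise ValidationError("household ids are not consecutive from 0")
        if p["pid"].duplicated().any():
            raise ValidationError("duplicate person ids")
        if len(p) and not set(p["hid"]).issubset(set(hids)):
            raise ValidationError("person back-pointer to unknown household")

    def members_of(self, hid: int) -> list[int]:
        return self.persons.loc[self.persons["hid"] == hid, "pid"].tolist()


def assemble(
    selections: Mapping[str, Sequence[str]],
    pool: HouseholdPool,
    geometries: Mapping[str, ZoneGeometry],
    rng: np.random.Generator,
    schema: Schema | None = None,
) -> SyntheticPopulation:
    """Copy selected pool households into a numbered, placed population.

    Zones are processed in lexicographic order; within a zone the draw
    order is kept.  Household income carries the upper value of its band
    (no numeric value for "Unspecified").
    """
    schema = schema or pool.schema
    missing = [z for z in selections if z not in geometries]
    if missing:
        raise ValidationError(f"zone(s) without geometry: {sorted(missing)}")
    hh_pool = pool.households.set_index("household_id")
    persons_by_hh = dict(tuple(pool.persons.groupby("household_id", sort=False)))

    hh_out: list[dict] = []
    person_out: list[dict] = []
    hid = 0
    pid = 0
    for zone in sorted(selections):
        geom = geometries[zone]
        for pool_hid in selections[zone]:
            row = hh_pool.loc[pool_hid]
            lon, lat = place_household(geom, rng)
            band = str(row["income"])
            hh_out.append(
                {
                    "hid": hid,
                    "zone_id": zone,
                    "housing": row["housing"],
                    "dwelling": row["dwelling"],
                    "rooms": int(row["rooms"]),
                    "tenure": row["tenure"],
                    "income": band,
                    "income_value": INCOME_UPPER_ZAR.get(band, None),
                    "lon": lon,
                    "lat": lat,
                    "n": int(row["n"]),
                }
            )
            members = persons_by_hh[pool_hid]
            for _, m in members.iterrows():
                person_out.append(
                    {
                        "pid": pid,
                        "hid": hid,
                        **{v: m[v] for v in schema.person},
                    }
                )
                pid += 1
            hid += 1
    households = pd.DataFrame(
        hh_out,
        columns=["hid", "zone_id", "housing", "dwelling", "rooms", "tenure",
                 "income", "income_value", "lon", "lat", "n"],
    )
    persons = pd.DataFrame(person_out, columns=["pid", "hid", *schema.person])
    pop = SyntheticPopulation(households=households, persons=persons, schema=schema)
    pop.validate()
    return pop


def draw_population(
    pool: HouseholdPool,
    weights: Mapping[str, ZoneWeights],
    controls: ControlTable,
    geometries: Mapping[str, ZoneGeometry],
    seed: int,
) -> SyntheticPopulation:
    """One full population draw: per-zone selection then assembly."""
    rng = np.random.default_rng(seed)
    selections = {
        zone: sample_zone(pool, weights[zone], controls.targets(zone), rng)
        for zone in sorted(weights)
    }
    return assemble(selections, pool, geometries, rng)


def replicate(
    pool: HouseholdPool,
    weights: Mapping[str, ZoneWeights],
    controls: ControlTable,
    geometries: Mapping[str, ZoneGeometry],
    n_replicates: int = 100,
    base_seed: int = 0,
):
    """Yield ``(r, population)`` for r = 0..n_replicates-1.

    Replicate r uses seed ``base_seed + r``; the calibrated weights are
    shared across replicates and never recomputed.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    for r in range(n_replicates):
        yield r, draw_population(pool, weights, controls, geometries, base_seed + r)
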