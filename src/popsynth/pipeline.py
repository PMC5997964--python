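"""End-to-end orchestration: fit -> pool -> rake -> assemble -> write.

A run is described by a YAML config (see :class:`RunConfig`); all
randomness flows from ``base_seed`` through named per-stage substreams so
every stage is independently reproducible, and replicate ``r`` draws its
zones with seed ``base_seed + r`` while sharing one calibrated weight set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .assembly import draw_population, load_geometries
from .categories import DEFAULT_SCHEMA, Schema
from .errors import PopsynthError, ValidationError
from .household_models import PoolConfig, generate_pool
from .io_matsim import write_households, write_population
from .model import HouseholdSynthesis
from .raking import rake_all_zones, weights_to_csv
from .reference_data import HouseholdType, read_control_table, read_micro_sample

log = logging.getLogger("popsynth")

POOL_STREAM = 1_000_003  # offset separating the pool substream from zone draws


@dataclass
class RunConfig:
    micro_sample: str
    control_table: str
    geometries: str
    output_dir: str
    pool_size: int
    fractions: tuple[float, float, float] | None = None  # None: from micro-sample
    n_replicates: int = 100
    base_seed: int = 0
    smoothing: float = 1.0
    max_parents: int | None = None
    rake_tol: float = 1e-6
    rake_max_iter: int = 100
    schema_file: str | None = None
    compress: bool = True

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.fractions is not None:
            self.fractions = tuple(float(f) for f in self.fractions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def load_schema(self) -> Schema:
        return Schema.from_file(self.schema_file) if self.schema_file else DEFAULT_SCHEMA


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the machine-readable report.

    Writes per-replicate household/population XML pairs, the weights CSV,
    the fitted-model JSON and ``report.json`` into ``output_dir``.
    Deterministic (byte-identical outputs) for a fixed config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = config.load_schema()
    report: dict = {"config": {"pool_size": config.pool_size,
                               "n_replicates": config.n_replicates,
                               "base_seed": config.base_seed},
                    "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        stage("fit")
        records = read_micro_sample(config.micro_sample, schema)
        model = HouseholdSynthesis(records, schema)
        results = model.fit(smoothing=config.smoothing, max_parents=config.max_parents)
        results.models.save(out / "models.json")
        report["stages"]["fit"] = {
            "households": len(records),
            "persons": sum(h.n for h in records),
            "fractions": {t.value: f for t, f in results.fractions.items()},
        }

        stage("pool")
        fractions = config.fractions
        if fractions is None:
            f = results.fractions
            fractions = (
                f.get(HouseholdType.SINGLE_MEMBER, 0.0),
                f.get(HouseholdType.DUAL_ROLE, 0.0),
                f.get(HouseholdType.SINGLE_ROLE, 0.0),
            )
        pool_seed = config.base_seed + POOL_STREAM
        cfg = PoolConfig(pool_size=config.pool_size, fractions=fractions,
                         seed=pool_seed)
        pool = generate_pool(results.models, cfg)
        pool.to_csv(out / "pool_households.csv", out / "pool_persons.csv")
        report["stages"]["pool"] = {**pool.counts, "seed": pool_seed}

        stage("rake")
        controls = read_control_table(config.control_table, schema)
        weights, preflight = rake_all_zones(
            pool, controls, tol=config.rake_tol, max_iter=config.rake_max_iter
        )
        weights_to_csv(weights, out / "weights.csv")
        report["stages"]["rake"] = {
            "zones": len(weights),
            "max_rel_violation": max(
                zw.diagnostics.max_rel_violation for zw in weights.values()
            ),
            "iterations": {z: zw.diagnostics.iterations for z, zw in weights.items()},
            "excluded_households": {r.zone_id: r.n_excluded for r in preflight},
        }
        for zone, zw in weights.items():
            log.info(
                "zone %s: %d iterations, max relative violation %.2e, %d retained",
                zone, zw.diagnostics.iterations, zw.diagnostics.max_rel_violation,
                len(zw.household_ids),
            )

        stage("assemble")
        geometries = load_geometries(config.geometries)
        suffix = ".xml.gz" if config.compress else ".xml"
        rep_counts = []
        seeds = []
        for r in range(config.n_replicates):
            seed = config.base_seed + r
            seeds.append(seed)
            pop = draw_population(pool, weights, controls, geometries, seed)
            write_households(pop, out / f"households.{r:03d}{suffix}")
            write_population(pop, out / f"population.{r:03d}{suffix}")
            rep_counts.append(
                {"replicate": r, "seed": seed,
                 "households": int(len(pop.households)),
                 "persons": int(len(pop.persons))}
            )
        report["stages"]["assemble"] = {"replicates": rep_counts, "seeds": seeds}
    except PopsynthError as exc:
        report["error"] = {"stage": list(report["stages"].keys())[-1:] or ["fit"],
                           "message": str(exc)}
        (out / "report.json").write_text(json.dumps(report, indent=1))
        raise

    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
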