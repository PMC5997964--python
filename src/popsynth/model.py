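"""statsmodels-style front end: a model built from micro-sample data whose
``fit()`` returns a results object carrying the five networks, the
household-type mix, diagnostics and a ``summary()`` table, with pool
generation, calibration and assembly hanging off the results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import SyntheticPopulation, ZoneGeometry, draw_population, replicate
from .bn import bic_score
from .categories import DEFAULT_SCHEMA, Schema
from .errors import ValidationError
from .household_models import (
    NETWORKS,
    FittedModels,
    HouseholdPool,
    PoolConfig,
    compute_quotas,
    fit_models,
    generate_pool,
    training_tables,
)
from .raking import PreflightReport, ZoneWeights, rake_all_zones
from .reference_data import (
    ControlTable,
    HouseholdRecord,
    HouseholdType,
    records_from_frame,
    type_fractions,
)


class HouseholdSynthesis:
    """Synthetic-population model over a census micro-sample.

    Parameters
    ----------
    micro_sample
        Validated household records (see
        :func:`popsynth.reference_data.read_micro_sample`).
    schema
        Category declarations; defaults to the full census variable set.

    Examples
    --------
    >>> model = HouseholdSynthesis(records)            # doctest: +SKIP
    >>> res = model.fit()                              # doctest: +SKIP
    >>> print(res.summary())                           # doctest: +SKIP
    >>> pool = res.generate_pool(pool_size=120_000, seed=1)  # doctest: +SKIP
    """

    def __init__(
        self,
        micro_sample: Sequence[HouseholdRecord],
        schema: Schema = DEFAULT_SCHEMA,
    ):
        if len(micro_sample) == 0:
            raise ValidationError("micro_sample is empty")
        self.micro_sample = list(micro_sample)
        self.schema = schema

    @classmethod
    def from_dataframe(
        cls, persons: pd.DataFrame, schema: Schema = DEFAULT_SCHEMA
    ) -> "HouseholdSynthesis":
        """Build from a one-row-per-person frame (micro-sample layout)."""
        return cls(records_from_frame(persons, schema), schema)

    def fit(
        self,
        smoothing: float = 1.0,
        max_parents: int | None = None,
        required: Sequence[str] | None = None,
    ) -> "HouseholdSynthesisResults":
        """Learn the five network structures and estimate their CPTs."""
        models = fit_models(
            self.micro_sample,
            schema=self.schema,
            smoothing=smoothing,
            max_parents=max_parents,
            required=required,
        )
        return HouseholdSynthesisResults(model=self, models=models)


@dataclass
class HouseholdSynthesisResults:
    """Fitted networks plus generation, calibration and assembly methods."""

    model: HouseholdSynthesis
    models: FittedModels
    rake_reports: list[PreflightReport] = field(default_factory=list)

    @property
    def fractions(self) -> dict[HouseholdType, float]:
        return self.models.fractions

    def summary(self) -> str:
        """Plain-text summary of the fitted networks and type mix."""
        records = self.model.micro_sample
        tables = training_tables(records, self.model.schema)
        lines = ["Household synthesis model", "=" * 60]
        lines.append(f"{'households in micro-sample':38s}{len(records):>10d}")
        n_persons = sum(h.n for h in records)
        lines.append(f"{'persons in micro-sample':38s}{n_persons:>10d}")
        lines.append("")
        lines.append(f"{'type':15s}{'share':>8s}")
        for t, frac in self.fractions.items():
            lines.append(f"{t.value:15s}{frac:8.3f}")
        lines.append("")
        lines.append(f"{'network':8s}{'rows':>8s}{'nodes':>7s}{'edges':>7s}{'BIC':>16s}")
        for g in NETWORKS:
            bn = getattr(self.models, g)
            if bn is None:
                lines.append(f"{g:8s}{'-':>8s}{'-':>7s}{'-':>7s}{'-':>16s}")
                continue
            table = tables[g]
            bic = bic_score(bn.dag, table, bn.levels)
            lines.append(
                f"{g:8s}{len(table):>8d}{len(bn.dag.nodes):>7d}"
                f"{len(bn.dag.edges):>7d}{bic:>16.1f}"
            )
        return "\n".join(lines)

    # -- generation stage ------------------------------------------------

    def generate_pool(
        self,
        pool_size: int,
        seed: int = 0,
        fractions: tuple[float, float, float] | None = None,
    ) -> HouseholdPool:
        """Sample the household pool to quota (~20% of the population)."""
        if fractions is None:
            f = self.fractions
            fractions = (
                f.get(HouseholdType.SINGLE_MEMBER, 0.0),
                f.get(HouseholdType.DUAL_ROLE, 0.0),
                f.get(HouseholdType.SINGLE_ROLE, 0.0),
            )
        cfg = PoolConfig(pool_size=pool_size, fractions=fractions, seed=seed)
        return generate_pool(self.models, cfg)

    def quotas(self, pool_size: int, fractions=None):
        if fractions is None:
            f = self.fractions
            fractions = (
                f.get(HouseholdType.SINGLE_MEMBER, 0.0),
                f.get(HouseholdType.DUAL_ROLE, 0.0),
                f.get(HouseholdType.SINGLE_ROLE, 0.0),
            )
        return compute_quotas(PoolConfig(pool_size=pool_size, fractions=fractions))

    def calibrate(
        self, pool: HouseholdPool, controls: ControlTable, tol: float = 1e-6
    ) -> dict[str, ZoneWeights]:
        """Rake pool-household weights to every zone's control totals."""
        weights, reports = rake_all_zones(pool, controls, tol=tol)
        self.rake_reports = reports
        return weights

    def assemble(
        self,
        pool: HouseholdPool,
        weights: Mapping[str, ZoneWeights],
        controls: ControlTable,
        geometries: Mapping[str, ZoneGeometry],
        seed: int = 0,
    ) -> SyntheticPopulation:
        return draw_population(pool, weights, controls, geometries, seed)

    def replicate(
        self,
        pool: HouseholdPool,
        weights: Mapping[str, ZoneWeights],
        controls: ControlTable,
        geometries: Mapping[str, ZoneGeometry],
        n_replicates: int = 100,
        base_seed: int = 0,
    ):
        return replicate(pool, weights, controls, geometries, n_replicates, base_seed)
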