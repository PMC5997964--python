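"""Generalized raking of household weights to zone control totals.

Each pool household i contributes a 23-entry design vector x_i: a one-hot
over the 13 income bands followed by the counts of its members in each of
the 10 gender x race cells (gender-major).  Calibration finds weights

    w_i = d_i * exp(x_i' lambda)

with lambda chosen so that sum_i w_i x_i equals the zone's control totals;
this is the exponential-tilting (raking) calibration distance of survey
sampling, solved here by Newton iterations on lambda with step halving
and a least-squares step when the Jacobian is rank-deficient.  Because
exponential tilting cannot produce exact zeros, households holding any
category whose zone target is zero are excluded up front (preflight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import DEFAULT_SCHEMA, PERSON_CELLS, Schema
from .errors import ConvergenceError, InfeasibleError, ValidationError
from .household_models import HouseholdPool
from .reference_data import ControlTable, control_columns


def build_design_matrix(
    pool: HouseholdPool, schema: Schema | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """One design row per pool household.

    Returns ``(matrix, column_names, household_ids)`` with 23 columns in
    control-table order: 13 income indicators then 10 gender x race
    member counts.
    """
    schema = schema or pool.schema
    if len(pool.households) == 0:
        raise ValidationError("cannot build a design matrix for an empty pool")
    income_cats = list(schema.household["income"])
    hh = pool.households.reset_index(drop=True)
    ids = hh["household_id"].astype(str).tolist()
    idx_of = {h: i for i, h in enumerate(ids)}

    n = len(hh)
    X = np.zeros((n, 13 + 10))
    inc_codes = pd.Categorical(hh["income"], categories=income_cats).codes
    if (inc_codes < 0).any():
        bad = sorted(set(hh["income"][inc_codes < 0]))
        raise ValidationError(f"undeclared income categor(ies): {bad}")
    X[np.arange(n), inc_codes] = 1.0

    cell_of = {cell: 13 + j for j, cell in enumerate(PERSON_CELLS)}
    pp = pool.persons
    genders = pp["gender"].to_numpy()
    races = pp["race"].to_numpy()
    hidx = np.array([idx_of.get(str(h), -1) for h in pp["household_id"]])
    if (hidx < 0).any():
        raise ValidationError("persons reference unknown pool households")
    for k in range(len(pp)):
        cell = (genders[k], races[k])
        if cell not in cell_of:
            raise ValidationError(f"undeclared gender x race cell {cell}")
        X[hidx[k], cell_of[cell]] += 1.0
    return X, control_columns(schema), ids


@dataclass
class RakeDiagnostics:
    iterations: int = 0
    max_rel_violation: float = np.inf
    converged: bool = False


@dataclass
class ZoneWeights:
    """Calibrated weights for the households retained in one zone."""

    zone_id: str
    household_ids: list[str]
    weights: np.ndarray
    diagnostics: RakeDiagnostics = field(default_factory=RakeDiagnostics)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"zone_id": self.zone_id, "household_id": self.household_ids,
             "weight": self.weights}
        )


def _rel_violation(achieved: np.ndarray, targets: np.ndarray) -> float:
    denom = np.maximum(targets, 1.0)
    return float(np.max(np.abs(achieved - targets) / denom))


def rake(
    design: np.ndarray,
    initial_weights: np.ndarray,
    targets: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    column_names: list[str] | None = None,
) -> tuple[np.ndarray, RakeDiagnostics]:
    """Solve the raking calibration problem for one zone.

    Raises :class:`InfeasibleError` if a positive target has no support in
    the design, or if a zero target faces positive design mass (run
    :func:`preflight_zone` first); :class:`ConvergenceError` carries the
    diagnostics if Newton fails to reach ``tol`` in ``max_iter`` steps.
    """
    X = np.asarray(design, dtype=float)
    d = np.asarray(initial_weights, dtype=float)
    t = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] != d.shape[0] or X.shape[1] != t.shape[0]:
        raise ValidationError("design, weights and targets have inconsistent shapes")
    if (d <= 0).any():
        raise ValidationError("initial weights must be positive")
    names = column_names or [f"col{j}" for j in range(X.shape[1])]

    col_mass = X.sum(axis=0)
    for j in range(X.shape[1]):
        if t[j] > 0 and col_mass[j] == 0:
            raise InfeasibleError(
                f"target category {names[j]!r} is positive but unrepresented in the pool"
            )
        if t[j] == 0 and col_mass[j] > 0:
            raise InfeasibleError(
                f"target category {names[j]!r} is zero but present in the pool; "
                "apply preflight exclusion first"
            )
    active = t > 0
    Xa = X[:, active]
    ta = t[active]

    lam = np.zeros(Xa.shape[1])
    w = d.copy()
    viol = _rel_violation(X.T @ w, t)
    it = 0
    while viol > tol and it < max_iter:
        it += 1
        F = Xa.T @ w - ta
        J = (Xa * w[:, None]).T @ Xa
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -F, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            step = np.linalg.lstsq(J, -F, rcond=None)[0]
        # step halving on the violation
        alpha = 1.0
        for _ in range(40):
            lam_new = lam + alpha * step
            w_new = d * np.exp(Xa @ lam_new)
            viol_new = _rel_violation(X.T @ w_new, t)
            if np.isfinite(viol_new) and viol_new < viol:
                break
            alpha *= 0.5
        else:
            break
        lam, w, viol = lam_new, w_new, viol_new
    diag = RakeDiagnostics(iterations=it, max_rel_violation=viol, converged=viol <= tol)
    if not diag.converged:
        raise ConvergenceError(
            f"raking did not converge: max relative violation {viol:.3e} after "
            f"{it} iterations",
            diagnostics={"iterations": it, "max_rel_violation": viol},
        )
    return w, diag


@dataclass
class PreflightReport:
    zone_id: str
    zero_target_columns: list[str]
    excluded_household_ids: list[str]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_household_ids)


def preflight_zone(
    design: np.ndarray,
    household_ids: list[str],
    targets: np.ndarray,
    column_names: list[str],
    zone_id: str = "",
) -> tuple[np.ndarray, PreflightReport]:
    """Mask out households with mass in zero-target categories.

    Returns the boolean retention mask and a report; targets are left
    unchanged (the zero-target constraints become trivially satisfied).
    """
    t = np.asarray(targets, dtype=float)
    zero_cols = np.where(t == 0)[0]
    bad = (np.asarray(design)[:, zero_cols] > 0).any(axis=1)
    report = PreflightReport(
        zone_id=zone_id,
        zero_target_columns=[column_names[j] for j in zero_cols],
        excluded_household_ids=[household_ids[i] for i in np.where(bad)[0]],
    )
    return ~bad, report


def rake_zone(
    pool: HouseholdPool,
    controls: ControlTable,
    zone_id: str,
    tol: float = 1e-6,
    max_iter: int = 100,
    design: tuple[np.ndarray, list[str], list[str]] | None = None,
) -> tuple[ZoneWeights, PreflightReport]:
    """Preflight + rake for one zone; initial weights are 1."""
    X, names, ids = design if design is not None else build_design_matrix(pool)
    targets = controls.targets(zone_id)
    keep, report = preflight_zone(X, ids, targets, names, zone_id)
    Xk = X[keep]
    if Xk.shape[0] == 0:
        raise InfeasibleError(f"zone {zone_id!r}: no pool household survives preflight")
    w, diag = rake(Xk, np.ones(Xk.shape[0]), targets, tol, max_iter, names)
    zw = ZoneWeights(
        zone_id=zone_id,
        household_ids=[i for i, k in zip(ids, keep) if k],
        weights=w,
        diagnostics=diag,
    )
    return zw, report


def rake_all_zones(
    pool: HouseholdPool, controls: ControlTable, tol: float = 1e-6, max_iter: int = 100
) -> tuple[dict[str, ZoneWeights], list[PreflightReport]]:
    design = build_design_matrix(pool)
    weights: dict[str, ZoneWeights] = {}
    reports: list[PreflightReport] = []
    for zone in controls.zones:
        zw, rep = rake_zone(pool, controls, zone, tol, max_iter, design=design)
        weights[zone] = zw
        reports.append(rep)
    return weights, reports


def weights_to_csv(weights: dict[str, ZoneWeights], sink) -> None:
    pd.concat([zw.to_frame() for zw in weights.values()], ignore_index=True).to_csv(
        sink, index=False
    )


def weights_from_csv(source) -> dict[str, ZoneWeights]:
    df = pd.read_csv(source, dtype={"zone_id": str, "household_id": str})
    out: dict[str, ZoneWeights] = {}
    for zone, grp in df.groupby("zone_id", sort=True):
        out[str(zone)] = ZoneWeights(
            zone_id=str(zone),
            household_ids=grp["household_id"].tolist(),
            weights=grp["weight"].to_numpy(dtype=float),
            diagnostics=RakeDiagnostics(converged=True, max_rel_violation=np.nan),
        )
    return out
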