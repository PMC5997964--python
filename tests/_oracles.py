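"""Independent oracles used to cross-check the implementation.

These deliberately use brute force: exhaustive enumeration over all DAGs
(via per-node parent-set assignments), exact joint distributions by
enumerating every configuration, and classical IPF on contingency
tables.  None of them share code with the hill-climbing search, the
ancestral sampler, or the raking Newton solver they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from popsynth.bn import Bn, Dag, EdgeConstraints, family_score, encode_data


def _acyclic(parent_sets: dict[str, frozenset]) -> bool:
    # Kahn's algorithm on the parent-set assignment
    remaining = dict(parent_sets)
    while remaining:
        leaves = [v for v, ps in remaining.items() if not (ps & set(remaining))]
        if not leaves:
            return False
        for v in leaves:
            del remaining[v]
    return True


def exhaustive_search(data, levels, constraints: EdgeConstraints | None = None):
    """Globally optimal BIC score and one optimal DAG, by enumerating every
    acyclic assignment of parent sets (feasible for <= 4 nodes)."""
    constraints = constraints or EdgeConstraints()
    nodes = list(levels)
    cards = {v: len(levels[v]) for v in nodes}
    codes = encode_data(data, levels)

    choices: dict[str, list[tuple[frozenset, float]]] = {}
    for v in nodes:
        candidates = [u for u in nodes if u != v and constraints.allows(u, v)]
        opts = []
        for k in range(len(candidates) + 1):
            for ps in itertools.combinations(candidates, k):
                opts.append((frozenset(ps), family_score(v, sorted(ps), codes, cards)))
        choices[v] = opts

    best_score = -np.inf
    best_dag = None
    for combo in itertools.product(*[choices[v] for v in nodes]):
        parent_sets = {v: combo[i][0] for i, v in enumerate(nodes)}
        edges = {(u, v) for v, ps in parent_sets.items() for u in ps}
        required_ok = all(
            (tuple(sorted(link))[0], tuple(sorted(link))[1]) in edges
            or (tuple(sorted(link))[1], tuple(sorted(link))[0]) in edges
            for link in constraints.whitelist
        )
        if not required_ok or not _acyclic(parent_sets):
            continue
        score = sum(c[1] for c in combo)
        if score > best_score:
            best_score = score
            best_dag = Dag(nodes, cards, edges)
    return best_score, best_dag


def enumerate_joint(bn: Bn) -> dict[tuple, float]:
    """Exact joint probability of every configuration, by enumeration."""
    order = bn.dag.topological_order()
    nodes = bn.dag.nodes
    joint: dict[tuple, float] = {}
    for combo in itertools.product(*[range(len(bn.levels[v])) for v in nodes]):
        assign = dict(zip(nodes, combo))
        p = 1.0
        for v in order:
            parents = bn.dag.parents(v)
            idx = tuple(assign[q] for q in parents) + (assign[v],)
            p *= float(bn.cpts[v][idx])
        joint[combo] = p
    return joint


def conditional_joint(bn: Bn, evidence: dict[str, str]) -> dict[tuple, float]:
    """Exact conditional joint given evidence, from the enumerated joint."""
    ev_codes = {v: bn.levels[v].index(val) for v, val in evidence.items()}
    nodes = bn.dag.nodes
    joint = enumerate_joint(bn)
    sel = {
        cfg: p
        for cfg, p in joint.items()
        if all(cfg[nodes.index(v)] == c for v, c in ev_codes.items())
    }
    z = sum(sel.values())
    return {cfg: p / z for cfg, p in sel.items()}


def ipf(table: np.ndarray, row_targets: np.ndarray, col_targets: np.ndarray,
        iters: int = 200) -> np.ndarray:
    """Classical iterative proportional fitting on a two-way table."""
    t = table.astype(float).copy()
    for _ in range(iters):
        rs = t.sum(axis=1, keepdims=True)
        t *= np.where(rs > 0, row_targets[:, None] / np.where(rs > 0, rs, 1), 0)
        cs = t.sum(axis=0, keepdims=True)
        t *= np.where(cs > 0, col_targets[None, :] / np.where(cs > 0, cs, 1), 0)
    return t
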