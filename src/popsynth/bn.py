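"""Categorical Bayesian networks: constrained structure learning, CPT
estimation, and ancestral sampling.

Structure is learnt by greedy hill-climbing on the BIC score with
single-edge moves (add / delete / reverse), best improvement first and a
deterministic lexicographic tie-break, under directed *blacklists*
(forbidden edges) and undirected *whitelists* (required links whose
orientation the search is free to choose).  The BIC of a DAG ``G`` for
``N`` complete categorical rows is

    BIC(G) = sum_v [ max log-likelihood of v given Pa(v) ]
             - (log N / 2) * sum_v (r_v - 1) * q_v

where ``r_v`` is the cardinality of ``v`` and ``q_v`` the number of parent
configurations (a product over the declared cardinalities of ``Pa(v)``,
counting unobserved configurations).  The score decomposes over node
families, which the search exploits through a family-score cache.

Sampling is ancestral (topological order); conditional sampling clamps
*root* evidence nodes only — conditioning on a non-root would require
posterior inference, which is deliberately out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConstraintError, ValidationError

Edge = tuple[str, str]


class Dag:
    """A directed acyclic graph over named categorical variables."""

    def __init__(
        self,
        nodes: Sequence[str],
        cardinalities: Mapping[str, int],
        edges: Iterable[Edge] = (),
    ):
        self.nodes: list[str] = list(nodes)
        missing = [v for v in self.nodes if v not in cardinalities]
        if missing:
            raise ValidationError(f"cardinality missing for node(s) {missing}")
        self.cardinalities: dict[str, int] = {v: int(cardinalities[v]) for v in self.nodes}
        self.edges: set[Edge] = set()
        self._g = nx.DiGraph()
        self._g.add_nodes_from(self.nodes)
        for u, v in edges:
            self.add_edge(u, v)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValidationError(f"self-loop {u!r}")
        if u not in self.cardinalities or v not in self.cardinalities:
            raise ValidationError(f"edge ({u!r}, {v!r}) references unknown node")
        self._g.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(self._g):
            self._g.remove_edge(u, v)
            raise ValidationError(f"edge ({u!r}, {v!r}) would create a cycle")
        self.edges.add((u, v))

    def remove_edge(self, u: str, v: str) -> None:
        self.edges.discard((u, v))
        if self._g.has_edge(u, v):
            self._g.remove_edge(u, v)

    def creates_cycle(self, u: str, v: str) -> bool:
        """Would adding u -> v create a cycle?"""
        return u == v or nx.has_path(self._g, v, u)

    def parents(self, v: str) -> list[str]:
        return sorted(self._g.predecessors(v))

    def roots(self) -> list[str]:
        return [v for v in self.nodes if self._g.in_degree(v) == 0]

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._g))

    def copy(self) -> "Dag":
        return Dag(self.nodes, self.cardinalities, self.edges)

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}

    def __eq__(self, other):
        return (
            isinstance(other, Dag)
            and self.nodes == other.nodes
            and self.cardinalities == other.cardinalities
            and self.edges == other.edges
        )

    def __repr__(self):  # pragma: no cover
        return f"Dag({len(self.nodes)} nodes, {len(self.edges)} edges)"


@dataclass(frozen=True)
class EdgeConstraints:
    """Forbidden directed edges and required undirected links."""

    blacklist: frozenset = frozenset()
    whitelist: frozenset = frozenset()  # of frozenset({u, v}) undirected links

    def __post_init__(self):
        for link in self.whitelist:
            u, v = sorted(link)
            if (u, v) in self.blacklist and (v, u) in self.blacklist:
                raise ConstraintError(
                    f"whitelisted link {u!r}--{v!r} is blacklisted in both orientations"
                )

    @classmethod
    def make(
        cls,
        blacklist: Iterable[Edge] = (),
        whitelist: Iterable[tuple[str, str]] = (),
    ) -> "EdgeConstraints":
        return cls(
            blacklist=frozenset((u, v) for u, v in blacklist),
            whitelist=frozenset(frozenset(l) for l in whitelist),
        )

    def allows(self, u: str, v: str) -> bool:
        return (u, v) not in self.blacklist

    def requires(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.whitelist


# ---------------------------------------------------------------------------
# Encoding and scoring
# ---------------------------------------------------------------------------


def encode_data(
    data: pd.DataFrame, levels: Mapping[str, Sequence[str]]
) -> dict[str, np.ndarray]:
    """Map string columns to integer codes in declared category order."""
    codes: dict[str, np.ndarray] = {}
    for var, cats in levels.items():
        if var not in data.columns:
            raise ValidationError(f"data is missing column {var!r}")
        cat = pd.Categorical(data[var], categories=list(cats))
        arr = np.asarray(cat.codes, dtype=np.int64)
        if (arr < 0).any():
            bad = sorted(set(data[var][arr < 0]))
            raise ValidationError(f"column {var!r} has values outside declared levels: {bad}")
        codes[var] = arr
    return codes


def _config_index(
    parents: Sequence[str], codes: Mapping[str, np.ndarray], cards: Mapping[str, int]
) -> tuple[np.ndarray, int]:
    """Flat parent-configuration index per row and the config count q."""
    if not parents:
        n = len(next(iter(codes.values())))
        return np.zeros(n, dtype=np.int64), 1
    q = 1
    idx = np.zeros_like(codes[parents[0]])
    for p in parents:
        idx = idx * cards[p] + codes[p]
        q *= cards[p]
    return idx, q


def family_counts(
    child: str,
    parents: Sequence[str],
    codes: Mapping[str, np.ndarray],
    cards: Mapping[str, int],
) -> np.ndarray:
    """(q, r) contingency counts of child categories per parent config."""
    r = cards[child]
    idx, q = _config_index(parents, codes, cards)
    flat = idx * r + codes[child]
    return np.bincount(flat, minlength=q * r).reshape(q, r)


def family_score(
    child: str,
    parents: Sequence[str],
    codes: Mapping[str, np.ndarray],
    cards: Mapping[str, int],
) -> float:
    """BIC contribution of one node family (log-likelihood minus penalty)."""
    counts = family_counts(child, parents, codes, cards)
    n = counts.sum()
    if n == 0:
        raise ValidationError("cannot score an empty data set")
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * (np.log(counts) - np.log(row_tot)), 0.0).sum()
    q, r = counts.shape
    penalty = 0.5 * math.log(n) * (r - 1) * q
    return float(ll - penalty)


def bic_score(
    dag: Dag, data: pd.DataFrame, levels: Mapping[str, Sequence[str]] | None = None
) -> float:
    """BIC of a DAG for complete categorical data (natural logarithms)."""
    if levels is None:
        raise ValidationError("levels must declare the category order of every node")
    codes = encode_data(data, {v: levels[v] for v in dag.nodes})
    return sum(
        family_score(v, dag.parents(v), codes, dag.cardinalities) for v in dag.nodes
    )


# ---------------------------------------------------------------------------
# Hill-climbing search
# ---------------------------------------------------------------------------


def hill_climb(
    data: pd.DataFrame,
    levels: Mapping[str, Sequence[str]],
    constraints: EdgeConstraints | None = None,
    max_parents: int | None = None,
    tol: float = 1e-9,
) -> Dag:
    """Greedy BIC hill-climbing over DAGs under edge constraints.

    Starts from the graph containing only the whitelisted links (oriented
    lexicographically where both orientations are legal) and repeatedly
    applies the single-edge move (add / delete / reverse) with the largest
    score improvement; ties break on the lexicographically first
    ``(child, parent)`` pair.  Deterministic for fixed inputs.
    """
    if len(data) == 0:
        raise ValidationError("cannot learn structure from an empty data set")
    constraints = constraints or EdgeConstraints()
    nodes = list(levels)
    cards = {v: len(levels[v]) for v in nodes}
    codes = encode_data(data, levels)

    dag = Dag(nodes, cards)
    for link in sorted(constraints.whitelist, key=sorted):
        u, v = sorted(link)
        if not constraints.allows(u, v):
            u, v = v, u
        try:
            dag.add_edge(u, v)
        except ValidationError as exc:
            raise ConstraintError(f"whitelist forces a cycle: {exc}") from exc

    cache: dict[tuple[str, frozenset], float] = {}

    def fam(child: str, parents: Iterable[str]) -> float:
        key = (child, frozenset(parents))
        if key not in cache:
            cache[key] = family_score(child, sorted(key[1]), codes, cards)
        return cache[key]

    current = {v: fam(v, dag.parents(v)) for v in nodes}

    while True:
        best_delta = tol
        best_move = None
        for v in nodes:  # child-major iteration fixes the tie-break order
            for u in nodes:
                if u == v:
                    continue
                if (u, v) not in dag.edges:
                    # add u -> v
                    if not constraints.allows(u, v):
                        continue
                    pa = dag.parents(v)
                    if max_parents is not None and len(pa) >= max_parents:
                        continue
                    if dag.creates_cycle(u, v):
                        continue
                    delta = fam(v, pa + [u]) - current[v]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", u, v)
                else:
                    pa_v = dag.parents(v)
                    pa_wo = [p for p in pa_v if p != u]
                    if not constraints.requires(u, v):
                        # delete u -> v
                        delta = fam(v, pa_wo) - current[v]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("delete", u, v)
                    # reverse u -> v  (becomes v -> u)
                    if constraints.allows(v, u):
                        pa_u = dag.parents(u)
                        if max_parents is not None and len(pa_u) >= max_parents:
                            continue
                        dag.remove_edge(u, v)
                        cyc = dag.creates_cycle(v, u)
                        dag.add_edge(u, v)
                        if cyc:
                            continue
                        delta = (
                            fam(v, pa_wo) - current[v] + fam(u, pa_u + [v]) - current[u]
                        )
                        if delta > best_delta:
                            best_delta, best_move = delta, ("reverse", u, v)
        if best_move is None:
            return dag
        op, u, v = best_move
        if op == "add":
            dag.add_edge(u, v)
        elif op == "delete":
            dag.remove_edge(u, v)
        else:
            dag.remove_edge(u, v)
            dag.add_edge(v, u)
            current[u] = fam(u, dag.parents(u))
        current[v] = fam(v, dag.parents(v))


# ---------------------------------------------------------------------------
# CPTs and sampling
# ---------------------------------------------------------------------------


@dataclass
class Bn:
    """A DAG plus one conditional probability table per node.

    The CPT of a node with parents ``p1 < p2 < ...`` (lexicographic) has
    shape ``(card(p1), card(p2), ..., card(node))``; each trailing-axis
    slice is a probability distribution.
    """

    dag: Dag
    levels: dict[str, list[str]]
    cpts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for v in self.dag.nodes:
            if v not in self.cpts:
                continue
            t = self.cpts[v]
            expected = tuple(self.dag.cardinalities[p] for p in self.dag.parents(v))
            expected += (self.dag.cardinalities[v],)
            if t.shape != expected:
                raise ValidationError(
                    f"CPT of {v!r} has shape {t.shape}, expected {expected}"
                )
            if (t < 0).any() or not np.allclose(t.sum(axis=-1), 1.0, atol=1e-9):
                raise ValidationError(f"CPT of {v!r} is not a stochastic table")

    @property
    def nodes(self) -> list[str]:
        return self.dag.nodes

    def to_json(self) -> str:
        doc = {
            "nodes": self.dag.nodes,
            "levels": {v: list(self.levels[v]) for v in self.dag.nodes},
            "edges": sorted(self.dag.edges),
            "cpts": {v: self.cpts[v].tolist() for v in self.dag.nodes},
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Bn":
        doc = json.loads(text)
        levels = {v: list(c) for v, c in doc["levels"].items()}
        cards = {v: len(c) for v, c in levels.items()}
        dag = Dag(doc["nodes"], cards, [tuple(e) for e in doc["edges"]])
        cpts = {v: np.asarray(doc["cpts"][v], dtype=float) for v in doc["nodes"]}
        return cls(dag=dag, levels=levels, cpts=cpts)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Bn":
        return cls.from_json(Path(path).read_text())


def fit_cpts(
    dag: Dag,
    data: pd.DataFrame,
    levels: Mapping[str, Sequence[str]],
    smoothing: float = 1.0,
) -> Bn:
    """Estimate CPTs by (smoothed) relative frequencies.

    Each conditional probability is ``(count + smoothing) /
    (config_count + smoothing * cardinality)``; with ``smoothing=0`` this
    is the MLE and unobserved parent configurations yield NaN rows, with
    ``smoothing>0`` they yield the uniform distribution.
    """
    if smoothing < 0:
        raise ValidationError("smoothing must be nonnegative")
    codes = encode_data(data, {v: levels[v] for v in dag.nodes})
    cpts: dict[str, np.ndarray] = {}
    for v in dag.nodes:
        parents = dag.parents(v)
        counts = family_counts(v, parents, codes, dag.cardinalities).astype(float)
        r = dag.cardinalities[v]
        num = counts + smoothing
        den = counts.sum(axis=1, keepdims=True) + smoothing * r
        with np.errstate(invalid="ignore"):
            probs = num / den
        shape = tuple(dag.cardinalities[p] for p in parents) + (r,)
        cpts[v] = probs.reshape(shape)
    bn = Bn(dag=dag.copy(), levels={v: list(levels[v]) for v in dag.nodes}, cpts={})
    bn.cpts = cpts  # assigned after construction; NaN rows allowed for MLE
    return bn


def _draw_node(
    bn: Bn, v: str, drawn: dict[str, np.ndarray], n: int, rng: np.random.Generator
) -> np.ndarray:
    parents = bn.dag.parents(v)
    r = bn.dag.cardinalities[v]
    table = bn.cpts[v].reshape(-1, r)
    if parents:
        idx = np.zeros(n, dtype=np.int64)
        for p in parents:
            idx = idx * bn.dag.cardinalities[p] + drawn[p]
        rows = table[idx]
    else:
        rows = np.broadcast_to(table[0], (n, r))
    if np.isnan(rows).any():
        raise ValidationError(
            f"node {v!r} hit an unobserved parent configuration; refit the CPTs "
            "with smoothing > 0"
        )
    cum = np.cumsum(rows, axis=1)
    u = rng.random(n)
    return (u[:, None] > cum).sum(axis=1).clip(0, r - 1).astype(np.int64)


def sample_given(
    bn: Bn, evidence: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Ancestral sampling with per-row evidence clamped on root nodes.

    ``evidence`` has one row per draw and one column per evidence node;
    every evidence node must be a root of the DAG.
    """
    for v in evidence.columns:
        if v not in bn.dag.nodes:
            raise ConstraintError(f"evidence node {v!r} is not in the network")
        if bn.dag.parents(v):
            raise ConstraintError(
                f"evidence node {v!r} has parents; conditioning on non-roots "
                "would require inference"
            )
    n = len(evidence)
    drawn = encode_data(evidence, {v: bn.levels[v] for v in evidence.columns})
    for v in bn.dag.topological_order():
        if v in drawn:
            continue
        drawn[v] = _draw_node(bn, v, drawn, n, rng)
    out = {
        v: pd.Categorical.from_codes(drawn[v], categories=bn.levels[v]).astype(str)
        for v in bn.dag.nodes
    }
    return pd.DataFrame(out, columns=bn.dag.nodes)


def sample(bn: Bn, n_draws: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n_draws`` joint configurations by ancestral sampling."""
    if n_draws < 0:
        raise ValidationError("n_draws must be nonnegative")
    return sample_given(bn, pd.DataFrame(index=range(n_draws)), rng)


def sample_conditional(
    bn: Bn,
    evidence: Mapping[str, str],
    n_draws: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw from the network with fixed values on (root) evidence nodes."""
    ev = pd.DataFrame({v: [val] * n_draws for v, val in evidence.items()})
    if not evidence:
        ev = pd.DataFrame(index=range(n_draws))
    return sample_given(bn, ev, rng)
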