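"""Bayesian-network scoring, constrained search, CPTs and sampling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popsynth.bn import (
    Bn,
    Dag,
    EdgeConstraints,
    bic_score,
    fit_cpts,
    hill_climb,
    sample,
    sample_conditional,
    sample_given,
)
from popsynth.errors import ConstraintError, ValidationError

from _oracles import conditional_joint, enumerate_joint, exhaustive_search

B = ["no", "yes"]


def _bern_df(n, cols):
    rng = np.random.default_rng(0)
    return pd.DataFrame({c: np.array(B)[rng.integers(0, 2, n)] for c in cols})


class TestBicScore:
    def test_closed_form_single_binary_node(self):
        data = pd.DataFrame({"x": [B[0]] * 50 + [B[1]] * 50})
        dag = Dag(["x"], {"x": 2})
        expected = 100 * math.log(0.5) - math.log(100) / 2
        assert bic_score(dag, data, {"x": B}) == pytest.approx(expected)

    def test_edge_between_independent_variables_never_helps(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            {"a": np.array(B)[rng.integers(0, 2, 5000)],
             "b": np.array(B)[rng.integers(0, 2, 5000)]}
        )
        levels = {"a": B, "b": B}
        empty = bic_score(Dag(["a", "b"], {"a": 2, "b": 2}), data, levels)
        with_edge = bic_score(
            Dag(["a", "b"], {"a": 2, "b": 2}, [("a", "b")]), data, levels
        )
        assert with_edge <= empty

    def test_decomposes_over_families(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(
            {c: np.array(B)[rng.integers(0, 2, 300)] for c in "xyz"}
        )
        levels = {c: B for c in "xyz"}
        dag = Dag(list("xyz"), {c: 2 for c in "xyz"}, [("x", "y"), ("y", "z")])
        whole = bic_score(dag, data, levels)
        parts = sum(
            bic_score(
                Dag([c] + dag.parents(c), {k: 2 for k in "xyz"},
                    [(p, c) for p in dag.parents(c)]),
                data, levels,
            )
            - sum(
                bic_score(Dag([p], {p: 2}), data, levels) for p in dag.parents(c)
            )
            for c in "xyz"
        )
        assert whole == pytest.approx(parts)

    def test_empty_data_errors(self):
        with pytest.raises(ValidationError):
            bic_score(Dag(["x"], {"x": 2}), pd.DataFrame({"x": []}), {"x": B})


class TestHillClimb:
    def test_strong_dependence_yields_one_edge(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 2000)
        b = np.where(rng.random(2000) < 0.9, a, 1 - a)
        data = pd.DataFrame({"a": np.array(B)[a], "b": np.array(B)[b]})
        levels = {"a": B, "b": B}
        dag = hill_climb(data, levels)
        assert dag.skeleton() == {frozenset(("a", "b"))}
        best, _ = exhaustive_search(data, levels)
        assert bic_score(dag, data, levels) == pytest.approx(best)

    def test_blacklisting_both_orientations_forces_empty_graph(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 2000)
        b = np.where(rng.random(2000) < 0.9, a, 1 - a)
        data = pd.DataFrame({"a": np.array(B)[a], "b": np.array(B)[b]})
        constraints = EdgeConstraints.make(blacklist=[("a", "b"), ("b", "a")])
        dag = hill_climb(data, {"a": B, "b": B}, constraints)
        assert dag.edges == set()

    def test_chain_recovers_skeleton_without_shortcut(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, 5000)
        y = np.where(rng.random(5000) < 0.9, x, 1 - x)
        z = np.where(rng.random(5000) < 0.9, y, 1 - y)
        data = pd.DataFrame({"x": np.array(B)[x], "y": np.array(B)[y],
                             "z": np.array(B)[z]})
        levels = {c: B for c in "xyz"}
        dag = hill_climb(data, levels)
        assert dag.skeleton() == {frozenset(("x", "y")), frozenset(("y", "z"))}
        best, best_dag = exhaustive_search(data, levels)
        assert bic_score(dag, data, levels) == pytest.approx(best)
        assert best_dag.skeleton() == dag.skeleton()

    def test_whitelist_link_always_present(self):
        data = _bern_df(500, "ab")
        constraints = EdgeConstraints.make(whitelist=[("a", "b")])
        dag = hill_climb(data, {"a": B, "b": B}, constraints)
        assert frozenset(("a", "b")) in dag.skeleton()

    def test_whitelist_cycle_raises(self):
        data = _bern_df(100, "ab")
        constraints = EdgeConstraints.make(
            blacklist=[("a", "b")], whitelist=[("a", "b")]
        )
        # forced into orientation b->a; add a second link forcing a->b
        constraints2 = EdgeConstraints.make(
            blacklist=[("a", "b"), ("b", "a")]
        )
        with pytest.raises(ConstraintError):
            EdgeConstraints.make(
                blacklist=[("a", "b"), ("b", "a")], whitelist=[("a", "b")]
            )
        dag = hill_climb(data, {"a": B, "b": B}, constraints)
        assert ("b", "a") in dag.edges
        assert constraints2.whitelist == frozenset()

    def test_never_beats_nor_trails_reachable_optimum(self):
        """Greedy score is bounded by the exhaustive optimum and reaches it
        in nearly every random <=4-variable fixture."""
        rng = np.random.default_rng(42)
        hits = 0
        trials = 30
        for _ in range(trials):
            k = rng.integers(2, 5)
            cards = rng.integers(2, 4, size=k)
            nodes = [f"v{i}" for i in range(k)]
            levels = {v: [str(j) for j in range(c)] for v, c in zip(nodes, cards)}
            n = 200
            cols = {}
            base = rng.integers(0, cards[0], n)
            for i, v in enumerate(nodes):
                if i == 0 or rng.random() < 0.4:
                    col = rng.integers(0, cards[i], n)
                else:
                    col = np.where(rng.random(n) < 0.8, base % cards[i],
                                   rng.integers(0, cards[i], n))
                cols[v] = np.array(levels[v])[col]
            data = pd.DataFrame(cols)
            learned = hill_climb(data, levels)
            score = bic_score(learned, data, levels)
            best, _ = exhaustive_search(data, levels)
            assert score <= best + 1e-9
            empty = bic_score(Dag(nodes, {v: len(levels[v]) for v in nodes}),
                              data, levels)
            assert score >= empty - 1e-9
            if score >= best - 1e-9:
                hits += 1
        assert hits / trials >= 0.9

    def test_deterministic(self):
        data = _bern_df(400, "abc")
        levels = {c: B for c in "abc"}
        assert hill_climb(data, levels).edges == hill_climb(data, levels).edges


class TestCpts:
    def test_mle_marginal(self):
        data = pd.DataFrame({"x": [B[0]] * 30 + [B[1]] * 70})
        bn = fit_cpts(Dag(["x"], {"x": 2}), data, {"x": B}, smoothing=0)
        assert bn.cpts["x"] == pytest.approx([0.3, 0.7])

    def test_unseen_config_is_uniform_with_laplace(self):
        data = pd.DataFrame({"p": [B[0]] * 10, "c": [B[0]] * 5 + [B[1]] * 5})
        dag = Dag(["p", "c"], {"p": 2, "c": 2}, [("p", "c")])
        bn = fit_cpts(dag, data, {"p": B, "c": B}, smoothing=1)
        assert bn.cpts["c"][1] == pytest.approx([0.5, 0.5])  # p=yes never seen

    def test_parameter_recovery_round_trip(self):
        """fit -> sample (100k) -> fit recovers CPTs within 0.02 sup-norm."""
        levels = {"a": B, "b": B, "c": ["u", "v", "w"]}
        dag = Dag(["a", "b", "c"], {"a": 2, "b": 2, "c": 3},
                  [("a", "b"), ("a", "c")])
        rng = np.random.default_rng(10)
        cpts = {
            "a": np.array([0.35, 0.65]),
            "b": np.array([[0.8, 0.2], [0.3, 0.7]]),
            "c": np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]]),
        }
        bn = Bn(dag=dag, levels={k: list(v) for k, v in levels.items()}, cpts=cpts)
        draws = sample(bn, 100_000, rng)
        refit = fit_cpts(dag, draws, levels, smoothing=0)
        for v in dag.nodes:
            assert np.abs(refit.cpts[v] - cpts[v]).max() < 0.02

    def test_json_round_trip(self, fitted):
        bn = fitted.models.g21
        back = Bn.from_json(bn.to_json())
        assert back.dag == bn.dag
        for v in bn.dag.nodes:
            assert np.allclose(back.cpts[v], bn.cpts[v])


class TestSampling:
    def _toy(self):
        dag = Dag(["a", "b", "c"], {"a": 2, "b": 2, "c": 2},
                  [("a", "c"), ("b", "c")])
        cpts = {
            "a": np.array([0.3, 0.7]),
            "b": np.array([0.6, 0.4]),
            "c": np.array([[[0.9, 0.1], [0.5, 0.5]], [[0.2, 0.8], [0.7, 0.3]]]),
        }
        return Bn(dag=dag, levels={v: list(B) for v in "abc"}, cpts=cpts)

    def test_degenerate_cpt_forces_category(self):
        bn = Bn(dag=Dag(["x"], {"x": 2}), levels={"x": list(B)},
                cpts={"x": np.array([0.0, 1.0])})
        draws = sample(bn, 50, np.random.default_rng(1))
        assert (draws["x"] == "yes").all()

    def test_same_seed_reproduces(self):
        bn = self._toy()
        d1 = sample(bn, 500, np.random.default_rng(5))
        d2 = sample(bn, 500, np.random.default_rng(5))
        pd.testing.assert_frame_equal(d1, d2)

    def test_empirical_joint_matches_enumeration(self):
        bn = self._toy()
        joint = enumerate_joint(bn)
        draws = sample(bn, 50_000, np.random.default_rng(6))
        codes = draws.apply(lambda col: (col == "yes").astype(int))
        observed = np.zeros(len(joint))
        keys = sorted(joint)
        key_index = {k: i for i, k in enumerate(keys)}
        for cfg, cnt in codes.value_counts().items():
            observed[key_index[tuple(cfg)]] = cnt
        expected = np.array([joint[k] for k in keys]) * 50_000
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001

    def test_evidence_fixing_all_parents_draws_from_cpt_row(self):
        bn = self._toy()
        draws = sample_conditional(
            bn, {"a": "yes", "b": "no"}, 30_000, np.random.default_rng(7)
        )
        assert (draws["a"] == "yes").all() and (draws["b"] == "no").all()
        p_yes = (draws["c"] == "yes").mean()
        assert p_yes == pytest.approx(0.8, abs=0.01)

    def test_conditional_matches_enumeration_in_total_variation(self):
        dag = Dag(["e", "x", "y", "z"], {v: 2 for v in "exyz"},
                  [("e", "x"), ("x", "y"), ("e", "z")])
        rng = np.random.default_rng(9)
        cpts = {
            "e": np.array([0.5, 0.5]),
            "x": np.array([[0.8, 0.2], [0.3, 0.7]]),
            "y": np.array([[0.6, 0.4], [0.1, 0.9]]),
            "z": np.array([[0.25, 0.75], [0.9, 0.1]]),
        }
        bn = Bn(dag=dag, levels={v: list(B) for v in "exyz"}, cpts=cpts)
        exact = conditional_joint(bn, {"e": "yes"})
        draws = sample_conditional(bn, {"e": "yes"}, 20_000, rng)
        counts = {}
        for _, row in draws.iterrows():
            cfg = tuple(int(row[v] == "yes") for v in bn.dag.nodes)
            counts[cfg] = counts.get(cfg, 0) + 1
        tv = 0.5 * sum(
            abs(counts.get(cfg, 0) / 20_000 - p) for cfg, p in exact.items()
        )
        assert tv < 0.02

    def test_evidence_on_non_root_rejected(self):
        bn = self._toy()
        with pytest.raises(ConstraintError, match="parents"):
            sample_conditional(bn, {"c": "yes"}, 10, np.random.default_rng(0))

    def test_vectorized_evidence_rows_are_respected(self):
        bn = self._toy()
        ev = pd.DataFrame({"a": ["yes"] * 100 + ["no"] * 100})
        draws = sample_given(bn, ev, np.random.default_rng(3))
        assert (draws["a"][:100] == "yes").all()
        assert (draws["a"][100:] == "no").all()
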