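"""Blacklist construction, the five-network fit, quotas and pool generation."""

import numpy as np
import pandas as pd
import pytest

from popsynth.categories import DEFAULT_SCHEMA
from popsynth.errors import ValidationError
from popsynth.household_models import (
    HouseholdPool,
    PoolConfig,
    Quotas,
    build_blacklists,
    compute_quotas,
    fit_models,
    generate_pool,
    network_groups,
    training_tables,
)
from popsynth.reference_data import HouseholdRecord, PersonRecord


def _person(hh, no, role, **over):
    base = dict(age="30-34", gender="Female", race="BlackAfrican",
                employ="Yes", edu="Secondary", study="None")
    base.update(over)
    return PersonRecord(household_id=hh, member_no=no, role=role, **base)


def _household(hh, members, **over):
    base = dict(housing="House", dwelling="FormalHouse", rooms=3,
                tenure="Rented", income="4801-9600")
    base.update(over)
    return HouseholdRecord(household_id=hh, members=tuple(members), **base)


class TestBlacklists:
    def test_g1_shields_demographics(self):
        c = build_blacklists(network_groups("g1"), "g1")
        assert ("dwelling", "race") in c.blacklist
        assert ("income", "age") in c.blacklist
        assert ("age", "gender") in c.blacklist  # demographics shield each other
        assert ("age", "employ") not in c.blacklist
        assert c.whitelist == frozenset()

    def test_g21_allows_partner_demographics_only(self):
        c = build_blacklists(network_groups("g21"), "g21")
        assert ("head_age", "spouse_age") not in c.blacklist
        assert ("spouse_race", "head_race") not in c.blacklist
        assert ("head_age", "head_gender") in c.blacklist  # within-person barred
        assert ("income", "head_age") in c.blacklist
        assert ("n", "spouse_gender") in c.blacklist
        assert ("head_employ", "n") not in c.blacklist

    def test_g31_has_no_partner_exception(self):
        c = build_blacklists(network_groups("g31"), "g31")
        assert all(("income", v) in c.blacklist
                   for v in ("head_age", "head_gender", "head_race"))

    def test_g22_leaves_exactly_head_spouse_to_member_edges(self):
        groups = {"head": ["h1", "h2"], "spouse": ["s1", "s2"],
                  "member": ["m1", "m2"]}
        c = build_blacklists(groups, "g22")
        allowed = [
            (u, v)
            for u in "h1 h2 s1 s2 m1 m2".split()
            for v in "h1 h2 s1 s2 m1 m2".split()
            if u != v and (u, v) not in c.blacklist
        ]
        assert len(allowed) == 8
        assert all(u in {"h1", "h2", "s1", "s2"} and v in {"m1", "m2"}
                   for u, v in allowed)

    def test_whitelist_empty_for_every_network(self):
        for g in ("g1", "g21", "g22", "g31", "g32"):
            assert build_blacklists(network_groups(g), g).whitelist == frozenset()

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError, match="pets"):
            build_blacklists({"pets": ["cat"]}, "g22")


class TestTrainingTables:
    def test_dual_household_of_five_contributes_one_plus_three_rows(self):
        members = [
            _person("d1", 1, "head"),
            _person("d1", 2, "spouse", gender="Male"),
            _person("d1", 3, "other", age="5-9"),
            _person("d1", 4, "other", age="5-9"),
            _person("d1", 5, "other", age="0-4"),
        ]
        tables = training_tables([_household("d1", members)])
        assert len(tables["g21"]) == 1
        assert len(tables["g22"]) == 3
        assert tables["g21"].iloc[0]["n"] == "5"
        assert (tables["g22"]["head_age"] == "30-34").all()

    def test_single_member_only_fixture_fits_only_g1(self):
        records = [_household(f"s{i}", [_person(f"s{i}", 1, "head")])
                   for i in range(30)]
        models = fit_models(records)
        assert models.g1 is not None and models.g21 is None
        with pytest.raises(ValidationError, match="dual_role"):
            fit_models(records, required=["g21"])
        with pytest.raises(ValidationError, match="g21"):
            models.require("g21")

    def test_fitted_structures_respect_blacklists(self, fitted):
        for g in ("g1", "g21", "g22", "g31", "g32"):
            bn = getattr(fitted.models, g)
            groups = network_groups(g)
            c = build_blacklists(
                {k: [v for v in vs if v in bn.dag.nodes] for k, vs in groups.items()},
                g,
            )
            assert not (bn.dag.edges & c.blacklist)

    def test_g22_roots_are_head_and_spouse(self, fitted):
        bn = fitted.models.g22
        for v in bn.dag.nodes:
            if v.startswith(("head_", "spouse_")):
                assert bn.dag.parents(v) == []

    def test_structure_recovery_on_fixture(self, fitted, small_gt):
        """The learned dual-role skeleton contains most generating edges."""
        true_edges = small_gt.generating_edges()["g21"]
        learned = fitted.models.g21.dag.skeleton()
        hits = sum(frozenset(e) in learned for e in true_edges)
        assert hits / len(true_edges) >= 0.8


class TestQuotas:
    def test_worked_example_buffalo_city(self):
        q = compute_quotas(PoolConfig(120_000, (0.07, 0.469, 0.461)))
        assert q == Quotas(s1=8400, s2=56280.0, total=120_000)

    def test_zero_single_fraction(self):
        q = compute_quotas(PoolConfig(999, (0.0, 0.5, 0.5)))
        assert q.s1 == 0

    def test_half_up_rounding(self):
        q = compute_quotas(PoolConfig(1001, (0.0005, 0.4995, 0.5)))
        assert q.s1 == 1  # 0.5005 rounds up

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError):
            PoolConfig(100, (0.5, 0.6, 0.2))


class TestGeneratePool:
    def test_degenerate_all_single(self, fitted):
        cfg = PoolConfig(pool_size=100, fractions=(1.0, 0.0, 0.0), seed=1)
        pool = generate_pool(fitted.models, cfg)
        c = pool.counts
        assert c["total_households"] == 100 and c["s1_actual"] == 100
        assert (pool.households["n"] == 1).all()

    def test_structure_invariants(self, small_pool):
        hh = small_pool.households.set_index("household_id")
        roles = small_pool.persons.groupby("household_id")["role"].agg(list)
        sizes = small_pool.persons.groupby("household_id").size()
        assert (sizes.reindex(hh.index) == hh["n"]).all()
        for hid, rs in roles.items():
            t = hh.loc[hid, "htype"]
            assert rs.count("head") == 1
            if t == "single_member":
                assert len(rs) == 1
            elif t == "dual_role":
                assert rs.count("spouse") == 1 and len(rs) >= 2
            else:
                assert rs.count("spouse") == 0 and len(rs) >= 1

    def test_quota_overshoot_bounds(self, fitted):
        cfg = PoolConfig(pool_size=6000, fractions=(0.1, 0.5, 0.4), seed=3)
        pool = generate_pool(fitted.models, cfg)
        q = compute_quotas(cfg)
        c = pool.counts
        max_n = int(pool.households["n"].max())
        assert c["s1_actual"] == q.s1
        assert q.s2 <= c["s2_actual"] < q.s2 + max_n
        assert q.total <= c["total_individuals"] < q.total + max_n

    def test_seed_determinism_and_variation(self, fitted):
        cfg = PoolConfig(pool_size=600, fractions=(0.1, 0.5, 0.4), seed=5)
        p1 = generate_pool(fitted.models, cfg)
        p2 = generate_pool(fitted.models, cfg)
        pd.testing.assert_frame_equal(p1.households, p2.households)
        pd.testing.assert_frame_equal(p1.persons, p2.persons)
        for other_seed in (6, 7, 8, 9, 10):
            cfg2 = PoolConfig(pool_size=600, fractions=(0.1, 0.5, 0.4),
                              seed=other_seed)
            p3 = generate_pool(fitted.models, cfg2)
            assert not p1.households.drop(columns="household_id").equals(
                p3.households.drop(columns="household_id")
            )

    def test_pool_marginals_follow_g1(self, fitted):
        """Single-member attributes in a large pool converge to the g1 law."""
        from scipy import stats

        cfg = PoolConfig(pool_size=50_000, fractions=(1.0, 0.0, 0.0), seed=11)
        pool = generate_pool(fitted.models, cfg)
        g1 = fitted.models.g1
        # the marginal of a root node equals its CPT
        root = next(v for v in g1.dag.nodes if not g1.dag.parents(v))
        probs = g1.cpts[root]
        frame = (pool.households if root in pool.households.columns
                 else pool.persons)
        counts = frame[root].value_counts()
        obs = np.array([counts.get(c, 0) for c in g1.levels[root]], dtype=float)
        _, p = stats.chisquare(obs, probs * obs.sum())
        assert p > 0.001

    def test_csv_round_trip(self, small_pool, tmp_path):
        small_pool.to_csv(tmp_path / "h.csv", tmp_path / "p.csv")
        back = HouseholdPool.from_csv(tmp_path / "h.csv", tmp_path / "p.csv")
        assert back.counts == small_pool.counts
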