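"""The locality-constrained backtracking matcher and the query pipeline."""

import random

import pytest

from sing import (
    GraphDB,
    IndexParams,
    LabeledGraph,
    MatchStats,
    UnsupportedQueryError,
    brute_force_matches,
    build_index,
    first_step_filter,
    label_compatibility_map,
    locality_vf2,
    match_order,
    query_features,
    run_query,
    sample_query_bfs,
    second_step_filter,
)

from conftest import random_graph


class TestLocalityVF2:
    def test_single_vertex(self):
        q = LabeledGraph("q", ["A"])
        g = LabeledGraph("g", ["A"])
        assert list(locality_vf2(q, g, [0b1])) == [(0,)]

    def test_triangle_in_k4_has_24_embeddings(self):
        q = LabeledGraph("q", ["A"] * 3, [(0, 1), (1, 2), (0, 2)])
        k4 = LabeledGraph(
            "k4", ["A"] * 4, [(i, j) for i in range(4) for j in range(i + 1, 4)]
        )
        m = label_compatibility_map(q, k4)
        got = set(locality_vf2(q, k4, m, mode="all"))
        assert len(got) == 24
        assert got == brute_force_matches(q, k4)

    def test_label_only_map_agrees_with_oracle_zero(self, locality_scenario):
        db, q = locality_scenario
        g2 = db["g2"]
        m = label_compatibility_map(q, g2)
        assert list(locality_vf2(q, g2, m, mode="all")) == []

    def test_disconnected_query_rejected(self):
        q = LabeledGraph("q", ["A", "A"])  # two isolated vertices
        g = LabeledGraph("g", ["A", "A"], [(0, 1)])
        with pytest.raises(UnsupportedQueryError):
            list(locality_vf2(q, g, label_compatibility_map(q, g)))

    def test_deterministic_enumeration_order(self):
        rng = random.Random(2)
        g = random_graph(rng, n_min=6, n_max=9, gid="g", connected=True)
        q = sample_query_bfs(g, 4, seed=3)
        m = label_compatibility_map(q, g)
        a = list(locality_vf2(q, g, m, mode="all"))
        b = list(locality_vf2(q, g, m, mode="all"))
        assert a == b

    def test_first_mode_is_prefix_of_all_mode(self):
        rng = random.Random(4)
        for i in range(20):
            g = random_graph(rng, n_min=4, n_max=9, gid=f"g{i}",
                             connected=True)
            q = sample_query_bfs(g, min(3, g.n_edges), seed=i)
            m = label_compatibility_map(q, g)
            all_matches = list(locality_vf2(q, g, m, mode="all"))
            first = list(locality_vf2(q, g, m, mode="first"))
            if all_matches:
                assert first == [all_matches[0]]
            else:
                assert first == []


class TestOracleEquivalence:
    def test_match_sets_equal_brute_force(self):
        rng = random.Random(17)
        for i in range(60):
            if i % 2:
                g = random_graph(rng, n_min=3, n_max=10, edge_p=0.35,
                                 gid=f"g{i}")
                q = random_graph(rng, n_min=1, n_max=5, edge_p=0.5,
                                 gid=f"q{i}", connected=True)
            else:
                g = random_graph(rng, n_min=3, n_max=10, edge_p=0.35,
                                 gid=f"g{i}", connected=True)
                q = sample_query_bfs(g, min(4, g.n_edges), seed=i)
            m = label_compatibility_map(q, g)
            got = set(locality_vf2(q, g, m, mode="all"))
            assert got == brute_force_matches(q, g)


class TestStatePruning:
    def test_locality_never_explores_more_than_label_only(self):
        # With the same vertex ordering, the locality candidate sets are
        # subsets of the label-only ones, so the search tree nests.
        rng = random.Random(55)
        checked = 0
        for i in range(40):
            g = random_graph(rng, n_min=4, n_max=10, edge_p=0.35,
                             gid=f"g{i}", connected=True)
            if g.n_edges < 3:
                continue
            q = sample_query_bfs(g, 3, seed=i)
            db = GraphDB([g])
            idx = build_index(db, IndexParams(lp=3))
            qf = query_features(q, 3)
            c2, m = second_step_filter(
                idx, qf.fvq, first_step_filter(idx, qf.fq)
            )
            if not c2:
                continue
            m_loc = m[g.graph_id]
            m_lab = label_compatibility_map(q, g)
            order = match_order(q, m_loc)
            s_loc, s_lab = MatchStats(), MatchStats()
            got_loc = set(
                locality_vf2(q, g, m_loc, "all", order=order, stats=s_loc)
            )
            got_lab = set(
                locality_vf2(q, g, m_lab, "all", order=order, stats=s_lab)
            )
            assert got_loc == got_lab
            assert s_loc.states <= s_lab.states
            checked += 1
        assert checked >= 20


class TestRunQuery:
    def test_member_graph_query_reports_itself(self):
        rng = random.Random(8)
        graphs = [
            random_graph(rng, n_min=2, n_max=8, gid=f"g{i}", connected=True)
            for i in range(10)
        ]
        db = GraphDB(graphs)
        idx = build_index(db, IndexParams(lp=4))
        for g in graphs:
            res = run_query(idx, db, g, mode="first")
            assert g.graph_id in res.matches
            assert len(res.matches[g.graph_id]) == 1

    def test_locality_scenario_reports_only_g1(self, locality_scenario):
        db, q = locality_scenario
        idx = build_index(db, IndexParams(lp=2))
        res = run_query(idx, db, q, mode="all")
        assert list(res.matches) == ["g1"]
        assert res.c1 == ["g1", "g2"]
        assert res.c2 == ["g1"]

    def test_counts_match_oracle_over_random_workload(self):
        rng = random.Random(99)
        graphs = [
            random_graph(rng, n_min=3, n_max=12, edge_p=0.3, gid=f"g{i}")
            for i in range(50)
        ]
        db = GraphDB(graphs)
        idx = build_index(db, IndexParams(lp=4))
        for j in range(50):
            q = random_graph(rng, n_min=1, n_max=5, edge_p=0.5,
                             gid=f"q{j}", connected=True)
            res = run_query(idx, db, q, mode="all")
            for g in db:
                oracle = brute_force_matches(q, g)
                got = set(res.matches.get(g.graph_id, []))
                assert got == oracle

    def test_max_matches_caps_enumeration(self):
        k4 = LabeledGraph(
            "k4", ["A"] * 4, [(i, j) for i in range(4) for j in range(i + 1, 4)]
        )
        q = LabeledGraph("q", ["A"] * 3, [(0, 1), (1, 2), (0, 2)])
        db = GraphDB([k4])
        idx = build_index(db, IndexParams(lp=3))
        res = run_query(idx, db, q, mode="all", max_matches=5)
        assert len(res.matches["k4"]) == 5

    def test_empty_query_matches_everything_with_empty_mapping(self):
        db = GraphDB([LabeledGraph("g", ["A"], [])])
        idx = build_index(db, IndexParams(lp=2))
        res = run_query(idx, db, LabeledGraph("q", []), mode="all")
        assert res.matches == {"g": [()]}

    def test_index_db_mismatch_rejected(self):
        db = GraphDB([LabeledGraph("g", ["A"])])
        other = GraphDB([LabeledGraph("x", ["A"])])
        idx = build_index(db, IndexParams(lp=2))
        with pytest.raises(ValueError, match="does not match"):
            run_query(idx, other, LabeledGraph("q", ["A"]))
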