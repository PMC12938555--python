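"""Typed graphs, metapath enumeration, HeteSim, score normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from multimorbid import (
    HetGraph,
    Metapath,
    SchemaError,
    aggregate_scores,
    enumerate_metapaths,
    hetesim_path,
    normalize_scores,
)
from conftest import make_table, oracle_hetesim, random_typed_graph


@pytest.fixture
def chain_graph():
    return HetGraph(
        [("s", "DSYN"), ("a", "AAPP"), ("t", "TARGET")],
        [("s", "affects", "a"), ("a", "assoc", "t")],
    )


CHAIN_PATH = Metapath(("DSYN", "AAPP", "TARGET"), ("affects", "assoc"))


class TestEnumerateMetapaths:
    def test_single_relation_gives_single_pattern(self):
        g = HetGraph(
            [("d", "DSYN"), ("t", "TARGET")], [("d", "affects", "t")]
        )
        paths = enumerate_metapaths(g, "DSYN", "t", max_length=3)
        assert paths == [Metapath(("DSYN", "TARGET"), ("affects",))]

    def test_empty_edge_set_gives_no_patterns(self):
        g = HetGraph([("d", "DSYN"), ("t", "TARGET")], [])
        assert enumerate_metapaths(g, "DSYN", "t", max_length=3) == []

    def test_matches_exhaustive_walk_enumeration(self):
        # 3-type schema, two predicates, including a self-loop relation on B
        g = HetGraph(
            [("a", "A"), ("b", "B"), ("c", "C")],
            [("a", "p", "b"), ("b", "q", "b"), ("b", "p", "c")],
        )

        def brute(max_len):
            found = set()
            schema = {("A", "p", "B"), ("B", "q", "B"), ("B", "p", "C")}

            def rec(types, preds):
                if preds and types[-1] == "C":
                    found.add((types, preds))
                if len(preds) == max_len:
                    return
                for s, p, d in schema:
                    if s == types[-1]:
                        rec(types + (d,), preds + (p,))

            rec(("A",), ())
            return found

        got = {(m.node_types, m.predicates) for m in enumerate_metapaths(g, "A", "c", 3)}
        assert got == brute(3)

    def test_deterministic_lexicographic_order(self):
        g = HetGraph(
            [("a", "A"), ("b", "B"), ("c", "C")],
            [("a", "p", "b"), ("a", "q", "b"), ("b", "p", "c")],
        )
        paths = enumerate_metapaths(g, "A", "c", 3)
        assert [str(p) for p in paths] == sorted(str(p) for p in paths)
        assert paths == enumerate_metapaths(g, "A", "c", 3)

    def test_unknown_identifiers_raise(self, chain_graph):
        with pytest.raises(SchemaError, match="nope"):
            enumerate_metapaths(chain_graph, "DSYN", "nope", 3)
        with pytest.raises(SchemaError, match="NOPE"):
            enumerate_metapaths(chain_graph, "NOPE", "t", 3)


class TestHeteSim:
    def test_unique_chain_scores_one(self, chain_graph):
        assert hetesim_path(chain_graph, "s", "t", CHAIN_PATH) == 1.0

    def test_disconnected_scores_zero(self):
        g = HetGraph(
            [("s", "DSYN"), ("a", "AAPP"), ("b", "AAPP"), ("t", "TARGET")],
            [("s", "affects", "a"), ("b", "assoc", "t")],
        )
        assert hetesim_path(g, "s", "t", CHAIN_PATH) == 0.0

    def test_undeclared_relation_raises(self, chain_graph):
        bad = Metapath(("DSYN", "AAPP", "TARGET"), ("treats", "assoc"))
        with pytest.raises(SchemaError, match="not declared"):
            hetesim_path(chain_graph, "s", "t", bad)

    def test_dangling_node_scores_zero_not_error(self):
        g = HetGraph(
            [("s", "DSYN"), ("a", "AAPP"), ("t", "TARGET")],
            [("a", "assoc", "t")],
            schema=[("DSYN", "affects", "AAPP"), ("AAPP", "assoc", "TARGET")],
        )
        assert hetesim_path(g, "s", "t", CHAIN_PATH) == 0.0

    def test_odd_length_path_agrees_with_oracle(self):
        # single-edge path: midpoint space is the edge instances
        g = HetGraph(
            [("s", "DSYN"), ("u", "DSYN"), ("t", "TARGET"), ("v", "TARGET")],
            [("s", "affects", "t"), ("s", "affects", "v"), ("u", "affects", "t")],
        )
        p = Metapath(("DSYN", "TARGET"), ("affects",))
        got = hetesim_path(g, "s", "t", p)
        assert got == pytest.approx(oracle_hetesim(g, "s", "t", p), abs=1e-12)
        # s splits its mass over two out-edges, t receives over two in-edges
        assert got == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_typed_graph(rng)
        paths = [
            Metapath(("A", "B"), ("r1",)),
            Metapath(("A", "B", "C"), ("r1", "r2")),
        ]
        for path in paths:
            for s in g.nodes_of_type(path.node_types[0]):
                for t in g.nodes_of_type(path.node_types[-1]):
                    got = hetesim_path(g, s, t, path)
                    want = oracle_hetesim(g, s, t, path)
                    assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_symmetric_under_reversal(self, seed):
        """HeteSim(s, t | P) == HeteSim(t, s | P reversed) on the reversed graph."""
        rng = np.random.default_rng(1000 + seed)
        g = random_typed_graph(rng, max_nodes=10)
        rev = g.reverse()
        path = Metapath(("A", "B", "C"), ("r1", "r2"))
        for s in g.nodes_of_type("A"):
            for t in g.nodes_of_type("C"):
                fwd = hetesim_path(g, s, t, path)
                bwd = hetesim_path(rev, t, s, path.reverse())
                assert fwd == pytest.approx(bwd, abs=1e-12)

    def test_scores_stay_in_unit_interval(self):
        rng = np.random.default_rng(42)
        path = Metapath(("A", "B", "C"), ("r1", "r2"))
        for seed in range(20):
            g = random_typed_graph(np.random.default_rng(seed))
            for s in g.nodes_of_type("A"):
                for t in g.nodes_of_type("C"):
                    assert 0.0 <= hetesim_path(g, s, t, path) <= 1.0


class TestAggregateScores:
    @pytest.mark.parametrize(
        "scores,expected", [([0.5], 0.5), ([0.2, 0.4, 0.6], 0.4)]
    )
    def test_mean_aggregation(self, scores, expected):
        assert aggregate_scores(scores) == pytest.approx(expected)

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(3)
        scores = rng.random(10)
        assert aggregate_scores(scores) == pytest.approx(scores.sum() / 10)

    def test_empty_list_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert aggregate_scores([]) == 0.0
        assert "unreachable" in caplog.text

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, derandomize=True)
    def test_bounded_by_inputs(self, scores):
        agg = aggregate_scores(scores)
        assert min(scores) - 1e-12 <= agg <= max(scores) + 1e-12


class TestNormalizeScores:
    def test_constant_scores_standardize_to_zero_full_tie_percentile(self):
        table = normalize_scores(make_table("X", {f"n{i}": 0.7 for i in range(5)}, normalize=False))
        assert (table.frame["standardized_score"] == 0).all()
        assert (table.frame["percentile"] == 0.6).all()  # mid-rank 3 of 5

    def test_strictly_increasing_scores_give_monotone_percentiles(self):
        table = normalize_scores(
            make_table("X", {f"n{i}": 0.1 * i for i in range(1, 8)}, normalize=False)
        )
        pct = table.frame["percentile"].to_numpy()
        assert (np.diff(pct) > 0).all()
        assert pct[-1] == 1.0

    def test_midrank_tie_handling(self):
        table = normalize_scores(
            make_table("X", {"a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0}, normalize=False)
        )
        assert table.frame["percentile"].tolist() == [0.25, 0.625, 0.625, 1.0]

    def test_zero_mean_unit_variance(self):
        rng = np.random.default_rng(9)
        table = normalize_scores(
            make_table("X", {f"n{i}": s for i, s in enumerate(rng.random(40))}, normalize=False)
        )
        z = table.frame["standardized_score"].to_numpy()
        assert abs(z.mean()) < 1e-9
        assert abs(z.var() - 1.0) < 1e-9

    def test_renormalizing_percentiles_preserves_order(self):
        rng = np.random.default_rng(10)
        t1 = normalize_scores(
            make_table("X", {f"n{i}": s for i, s in enumerate(rng.random(30))}, normalize=False)
        )
        t2 = t1.copy()
        t2.frame["raw_score"] = t2.frame["percentile"]
        t2 = normalize_scores(t2)
        assert (
            t1.frame["percentile"].rank().tolist()
            == t2.frame["percentile"].rank().tolist()
        )

    def test_preserves_row_identity_and_order(self):
        table = make_table("X", {"z": 0.9, "a": 0.1, "m": 0.5})
        assert table.frame["node_id"].tolist() == ["z", "a", "m"]
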