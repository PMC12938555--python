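"""Shared fixtures and independent oracles.

The HeteSim oracle here enumerates path instances explicitly with
dictionary-based probability propagation — independent of the matrix
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from multimorbid import HetGraph, Metapath, RankedNodeTable, normalize_scores
from multimorbid.ontology import CATEGORIES


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def make_table(entity, node_scores, categories=None, normalize=True):
    """RankedNodeTable from {node_id: raw_score}; optionally normalised."""
    frame = pd.DataFrame(
        {
            "node_id": list(node_scores),
            "name": [f"node {n}" for n in node_scores],
            "source_type": "DSYN",
            "raw_score": list(node_scores.values()),
        }
    )
    table = RankedNodeTable(entity, frame)
    if normalize:
        table = normalize_scores(table)
    if categories is not None:
        table.frame["category"] = [categories[n] for n in node_scores]
    return table


@pytest.fixture
def mapping_factory(tmp_path):
    """Write a mapping TSV and return its path."""

    def _write(rows, header_lines=()):
        path = tmp_path / "mapping.tsv"
        lines = list(header_lines) + [f"{n}\t{c}" for n, c in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


# ---------------------------------------------------------------------------
# Random typed graphs (<= 8 nodes, <= 2 relations)
# ---------------------------------------------------------------------------

def random_typed_graph(rng, max_nodes=8, edge_prob=0.5):
    """Random 3-type graph over a 2-relation chain schema A-r1->B-r2->C."""
    sizes = rng.integers(1, 4, size=3)
    while sizes.sum() > max_nodes:
        sizes[rng.integers(0, 3)] = max(1, sizes[rng.integers(0, 3)] - 1)
    types = ("A", "B", "C")
    nodes = [(f"{t}{i}", t) for t, k in zip(types, sizes) for i in range(k)]
    schema = [("A", "r1", "B"), ("B", "r2", "C")]
    edges = []
    for src_t, pred, dst_t in schema:
        n_src = sizes[types.index(src_t)]
        n_dst = sizes[types.index(dst_t)]
        for i in range(n_src):
            for j in range(n_dst):
                if rng.random() < edge_prob:
                    edges.append((f"{src_t}{i}", pred, f"{dst_t}{j}"))
    return HetGraph(nodes, edges, schema=schema)


# ---------------------------------------------------------------------------
# Brute-force HeteSim oracle
# ---------------------------------------------------------------------------

def _out_edges(graph, node, rel):
    src_t, pred, dst_t = rel
    return sorted(
        d
        for s, p, d in graph.edges
        if s == node
        and p == pred
        and graph.node_type(s) == src_t
        and graph.node_type(d) == dst_t
    )


def _in_edges(graph, node, rel):
    src_t, pred, dst_t = rel
    return sorted(
        s
        for s, p, d in graph.edges
        if d == node
        and p == pred
        and graph.node_type(s) == src_t
        and graph.node_type(d) == dst_t
    )


def _walk_forward(graph, start, rels):
    dist = {start: 1.0}
    for rel in rels:
        nxt: dict[str, float] = {}
        for u, pr in dist.items():
            outs = _out_edges(graph, u, rel)
            for v in outs:
                nxt[v] = nxt.get(v, 0.0) + pr / len(outs)
        dist = nxt
    return dist


def _walk_backward(graph, start, rels):
    dist = {start: 1.0}
    for rel in reversed(rels):
        nxt: dict[str, float] = {}
        for v, pr in dist.items():
            ins = _in_edges(graph, v, rel)
            for u in ins:
                nxt[u] = nxt.get(u, 0.0) + pr / len(ins)
        dist = nxt
    return dist


def _dict_cosine(a, b):
    keys = set(a) | set(b)
    va = np.array([a.get(k, 0.0) for k in sorted(keys)])
    vb = np.array([b.get(k, 0.0) for k in sorted(keys)])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


def oracle_hetesim(graph, source, target, path: Metapath):
    """Exhaustive path-instance midpoint-cosine HeteSim."""
    rels = list(zip(path.node_types[:-1], path.predicates, path.node_types[1:]))
    length = len(rels)
    half = length // 2
    fwd = _walk_forward(graph, source, rels[:half])
    if length % 2 == 0:
        bwd = _walk_backward(graph, target, rels[half:])
        return _dict_cosine(fwd, bwd)
    mid = rels[half]
    bwd_nodes = _walk_backward(graph, target, rels[half + 1:])
    f_edges: dict[tuple, float] = {}
    for u, pr in fwd.items():
        outs = _out_edges(graph, u, mid)
        for v in outs:
            f_edges[(u, v)] = f_edges.get((u, v), 0.0) + pr / len(outs)
    b_edges: dict[tuple, float] = {}
    for v, pr in bwd_nodes.items():
        ins = _in_edges(graph, v, mid)
        for u in ins:
            b_edges[(u, v)] = b_edges.get((u, v), 0.0) + pr / len(ins)
    return _dict_cosine(f_edges, b_edges)
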