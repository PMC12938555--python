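"""Typed heterogeneous knowledge graphs and HeteSim relevance.

A heterogeneous biomedical knowledge graph has nodes that are typed
concepts (e.g. UMLS semantic types such as ``DSYN`` for disease/syndrome
or ``PHSU`` for pharmacologic substance) and directed edges carrying a
predicate ("affects", "treats", ...).  HeteSim measures the relevance of
a source concept to a target concept along a *metapath* — a typed path
schema — by meeting in the middle: the source walks forward along the
first half of the path, the target walks backward along the second half,
and the score is the cosine similarity of the two midpoint reachability
distributions.  Transition probabilities are uniform over the out-edges
of each relation (row-normalised adjacency).  Odd edge-length paths have
no midpoint node layer, so the middle edge is split by inserting one
artificial node per edge instance, which preserves the symmetric
meeting-in-the-middle semantics.

Per-disease relevance tables (one row per source concept) are the
pipeline's central currency; :func:`normalize_scores` standardises raw
mean-aggregated scores to zero mean / unit variance and converts them to
mid-rank percentiles on the unit interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DataError, SchemaError

logger = logging.getLogger(__name__)

RANKED_TABLE_COLUMNS = (
    "node_id",
    "name",
    "source_type",
    "raw_score",
    "standardized_score",
    "percentile",
)


@dataclass(frozen=True)
class Metapath:
    """A typed path schema: node types joined by predicates.

    ``node_types`` has one more element than ``predicates``; the path is
    read left to right from the source type to the target type.
    """

    node_types: tuple[str, ...]
    predicates: tuple[str, ...]

    def __post_init__(self):
        if len(self.node_types) != len(self.predicates) + 1:
            raise SchemaError(
                "metapath needs len(node_types) == len(predicates) + 1, got "
                f"{len(self.node_types)} types and {len(self.predicates)} predicates"
            )
        if not self.predicates:
            raise SchemaError("metapath must have at least one edge")

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.predicates)

    @property
    def steps(self) -> tuple[tuple[str, str], ...]:
        """(node_type, predicate-into-that-type) pairs ending at the target."""
        return tuple(zip(self.node_types[1:], self.predicates))

    def reverse(self) -> "Metapath":
        return Metapath(self.node_types[::-1], self.predicates[::-1])

    def __str__(self) -> str:  # e.g. DSYN-affects->AAPP-assoc->TARGET
        out = [self.node_types[0]]
        for t, p in zip(self.node_types[1:], self.predicates):
            out.append(f"-{p}->{t}")
        return "".join(out)


class HetGraph:
    """Directed typed multigraph with predicate-labelled edges."""

    def __init__(
        self,
        nodes: Iterable[tuple[str, str] | tuple[str, str, str]],
        edges: Iterable[tuple[str, str, str]] = (),
        schema: Iterable[tuple[str, str, str]] = (),
    ):
        # declared relations may be instance-free (e.g. sparse samples of a
        # known relation alphabet); the effective schema is declared + derived
        self._declared_schema = set(schema)
        self._type: dict[str, str] = {}
        self._label: dict[str, str] = {}
        for node in nodes:
            node_id, node_type = node[0], node[1]
            label = node[2] if len(node) > 2 else node_id
            if node_id in self._type:
                if self._type[node_id] != node_type:
                    raise SchemaError(
                        f"node {node_id!r} declared with conflicting types "
                        f"{self._type[node_id]!r} and {node_type!r}"
                    )
                continue
            self._type[node_id] = node_type
            self._label[node_id] = label
        self._edges: set[tuple[str, str, str]] = set()
        for src, pred, dst in edges:
            for endpoint in (src, dst):
                if endpoint not in self._type:
                    raise SchemaError(f"edge endpoint {endpoint!r} is not a declared node")
            self._edges.add((src, pred, dst))

    # -- basic accessors -------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return sorted(self._type)

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        return set(self._edges)

    def node_type(self, node_id: str) -> str:
        try:
            return self._type[node_id]
        except KeyError:
            raise SchemaError(f"unknown node id {node_id!r}") from None

    def node_label(self, node_id: str) -> str:
        self.node_type(node_id)
        return self._label[node_id]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self._type.items() if t == node_type)

    @property
    def node_types(self) -> set[str]:
        return set(self._type.values())

    def schema(self) -> set[tuple[str, str, str]]:
        """Declared plus edge-derived relations, as
        (source_type, predicate, target_type) triples."""
        derived = {(self._type[s], p, self._type[d]) for s, p, d in self._edges}
        return derived | self._declared_schema

    def relation_edges(self, src_type: str, predicate: str, dst_type: str):
        return sorted(
            (s, d)
            for s, p, d in self._edges
            if p == predicate
            and self._type[s] == src_type
            and self._type[d] == dst_type
        )

    def reverse(self) -> "HetGraph":
        """Graph with every edge flipped (predicates kept)."""
        return HetGraph(
            [(n, t, self._label[n]) for n, t in self._type.items()],
            [(d, p, s) for s, p, d in self._edges],
            schema=[(dt, p, st) for st, p, dt in self._declared_schema],
        )

    # -- IO ---------------------------------------------------------------
    @classmethod
    def from_edgelist(cls, path) -> "HetGraph":
        """Read a tab-separated edge list.

        Expected header: ``source_id source_type predicate target_id
        target_type``.  Node labels default to their ids.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["source_id", "source_type", "predicate", "target_id", "target_type"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"edge list is missing columns: {missing}")
        nodes = {}
        for _, row in df.iterrows():
            nodes[row.source_id] = row.source_type
            nodes[row.target_id] = row.target_type
        return cls(
            nodes.items(),
            [(r.source_id, r.predicate, r.target_id) for r in df.itertuples()],
        )

    def to_edgelist(self, path) -> None:
        rows = [
            {
                "source_id": s,
                "source_type": self._type[s],
                "predicate": p,
                "target_id": d,
                "target_type": self._type[d],
            }
            for s, p, d in sorted(self._edges)
        ]
        pd.DataFrame(
            rows,
            columns=["source_id", "source_type", "predicate", "target_id", "target_type"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class RankedNodeTable:
    """A disease's ranked concept nodes.

    ``frame`` columns: node_id, name, source_type, raw_score and, once
    normalised, standardized_score and percentile.  node_ids are unique
    within a table.
    """

    entity_label: str
    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(RANKED_TABLE_COLUMNS)))

    def __post_init__(self):
        if self.frame["node_id"].duplicated().any():
            dups = self.frame.loc[self.frame["node_id"].duplicated(), "node_id"].tolist()
            raise DataError(f"duplicate node ids in table {self.entity_label!r}: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "RankedNodeTable":
        return RankedNodeTable(self.entity_label, self.frame.copy())

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, entity_label: str) -> "RankedNodeTable":
        frame = pd.read_csv(path, sep="\t", dtype={"node_id": str, "name": str, "source_type": str})
        return cls(entity_label, frame)


# ---------------------------------------------------------------------------
# Metapath enumeration
# ---------------------------------------------------------------------------

def enumerate_metapaths(
    graph: HetGraph, source_type: str, target_id: str, max_length: int = 3
) -> list[Metapath]:
    """Every schema-consistent typed path pattern of edge-length <= max_length
    from a node of ``source_type`` to the target node, in lexicographic order.

    Patterns are enumerated over the graph's relation schema (the set of
    (source_type, predicate, target_type) triples present), following edge
    direction, and deduplicated.
    """
    if max_length < 1:
        raise SchemaError(f"max_length must be >= 1, got {max_length}")
    target_type = graph.node_type(target_id)  # raises on unknown target
    if source_type not in graph.node_types:
        raise SchemaError(f"unknown source type {source_type!r}")
    schema = graph.schema()
    found: list[Metapath] = []

    def extend(types: tuple[str, ...], preds: tuple[str, ...]):
        if preds and types[-1] == target_type:
            found.append(Metapath(types, preds))
        if len(preds) == max_length:
            return
        for a, p, b in sorted(schema):
            if a == types[-1]:
                extend(types + (b,), preds + (p,))

    extend((source_type,), ())
    unique = sorted(
        set(found), key=lambda m: tuple(zip(m.node_types, m.predicates + ("",)))
    )
    return unique


# ---------------------------------------------------------------------------
# HeteSim
# ---------------------------------------------------------------------------

def _row_normalize(mat: np.ndarray) -> np.ndarray:
    sums = mat.sum(axis=1, keepdims=True)
    out = np.zeros_like(mat, dtype=float)
    np.divide(mat, sums, out=out, where=sums > 0)
    return out


def _adjacency(graph: HetGraph, src_type: str, pred: str, dst_type: str):
    rows = graph.nodes_of_type(src_type)
    cols = graph.nodes_of_type(dst_type)
    ridx = {n: i for i, n in enumerate(rows)}
    cidx = {n: i for i, n in enumerate(cols)}
    mat = np.zeros((len(rows), len(cols)))
    for s, d in graph.relation_edges(src_type, pred, dst_type):
        mat[ridx[s], cidx[d]] = 1.0
    return mat, rows, cols


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def hetesim_path(graph: HetGraph, source_id: str, target_id: str, path: Metapath) -> float:
    """HeteSim relevance of ``source_id`` to ``target_id`` along ``path``.

    The score is the cosine of the source's forward midpoint-reachability
    distribution and the target's backward one, with uniform transition
    probabilities per relation.  A dangling node (zero out-degree along
    the path) yields a zero distribution and hence score 0.
    """
    s_type, t_type = graph.node_type(source_id), graph.node_type(target_id)
    if s_type != path.node_types[0] or t_type != path.node_types[-1]:
        raise SchemaError(
            f"path {path} does not connect a {s_type!r} node to a {t_type!r} node"
        )
    schema = graph.schema()
    rels = list(zip(path.node_types[:-1], path.predicates, path.node_types[1:]))
    for rel in rels:
        if rel not in schema:
            raise SchemaError(f"relation {rel} is not declared in the graph schema")

    length = path.length
    half = length // 2

    # forward distribution over the layer reached after `half` steps
    fwd_nodes = graph.nodes_of_type(s_type)
    fwd = np.zeros(len(fwd_nodes))
    fwd[fwd_nodes.index(source_id)] = 1.0
    for rel in rels[:half]:
        mat, _, fwd_nodes = _adjacency(graph, *rel)
        fwd = fwd @ _row_normalize(mat)

    # backward distribution over the layer `half` steps from the target
    n_back = length - half - (length % 2)
    bwd_nodes = graph.nodes_of_type(t_type)
    bwd = np.zeros(len(bwd_nodes))
    bwd[bwd_nodes.index(target_id)] = 1.0
    for rel in rels[length - n_back:][::-1]:
        mat, bwd_nodes, _ = _adjacency(graph, *rel)
        bwd = bwd @ _row_normalize(mat.T)

    if length % 2 == 0:
        return _cosine(fwd, bwd)

    # odd edge-length: split the middle edge, one artificial node per
    # edge instance of the middle relation
    mid_rel = rels[half]
    mat, mid_rows, mid_cols = _adjacency(graph, *mid_rel)
    instances = [
        (i, j) for i in range(len(mid_rows)) for j in range(len(mid_cols)) if mat[i, j]
    ]
    if not instances:
        return 0.0
    out_deg = mat.sum(axis=1)
    in_deg = mat.sum(axis=0)
    f_mid = np.array(
        [fwd[i] / out_deg[i] if out_deg[i] else 0.0 for i, _ in instances]
    )
    b_mid = np.array(
        [bwd[j] / in_deg[j] if in_deg[j] else 0.0 for _, j in instances]
    )
    return _cosine(f_mid, b_mid)


def aggregate_scores(per_path_scores: Sequence[float]) -> float:
    """Deterministic mean aggregation of per-metapath HeteSim scores.

    An empty list means the node is unreachable under every metapath; by
    convention the aggregate is 0 and a warning is logged.
    """
    if len(per_path_scores) == 0:
        logger.warning("no metapath scores to aggregate; node unreachable, score 0")
        return 0.0
    return float(np.mean(per_path_scores))


def rank_source_nodes(
    graph: HetGraph,
    source_type: str,
    target_id: str,
    max_length: int = 3,
    entity_label: str | None = None,
) -> RankedNodeTable:
    """Score every ``source_type`` node against the target and return a
    normalised ranked table (mean-aggregated HeteSim over all metapaths).
    """
    paths = enumerate_metapaths(graph, source_type, target_id, max_length)
    rows = []
    for node in graph.nodes_of_type(source_type):
        if node == target_id:
            continue
        scores = [hetesim_path(graph, node, target_id, p) for p in paths]
        rows.append(
            {
                "node_id": node,
                "name": graph.node_label(node),
                "source_type": source_type,
                "raw_score": aggregate_scores(scores) if scores else 0.0,
            }
        )
    label = entity_label or graph.node_label(target_id)
    frame = pd.DataFrame(rows, columns=["node_id", "name", "source_type", "raw_score"])
    return normalize_scores(RankedNodeTable(label, frame))


# ---------------------------------------------------------------------------
# Score normalisation
# ---------------------------------------------------------------------------

def normalize_scores(table: RankedNodeTable) -> RankedNodeTable:
    """Add standardized (zero-mean, unit-variance) and mid-rank percentile
    columns, preserving row identity and order.

    Percentile is average-rank/n, so tied raw scores share their mean rank
    and the top score maps to exactly 1.0.  A zero-variance table
    standardises to all zeros.
    """
    frame = table.frame.copy()
    if len(frame) == 0:
        raise DataError(f"cannot normalize empty table {table.entity_label!r}")
    raw = frame["raw_score"].to_numpy(dtype=float)
    sd = raw.std()  # population sd: unit variance over the table itself
    frame["standardized_score"] = np.zeros_like(raw) if sd == 0 else (raw - raw.mean()) / sd
    frame["percentile"] = rankdata(raw, method="average") / len(raw)
    return replace(table, frame=frame)
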