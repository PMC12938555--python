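"""Pairwise-disease intersection profiles, enrichment, and overlap counts.

A concept node shared by two diseases belongs to their multimorbidity
intersection when the harmonic mean (HM) of its two unit-interval
relevance scores clears a threshold (default 0.5, inclusive).  The
harmonic mean penalises nodes strongly tied to one disease but weakly to
the other, so intersections reflect balanced cross-disease relevance.

Each intersection is profiled at the ontology level: per-category member
counts, within-intersection percentages (summing to 100), and signed
Z-score enrichment of each category against the global category
distribution of all three diseases' high-importance nodes.  The
enrichment null is the one-sample binomial proportion test,

    z_c = (k_c - n p0_c) / sqrt(n p0_c (1 - p0_c)),

with a seeded permutation alternative (resampling n nodes from the
pooled baseline) for sensitivity.  Triple-wise node overlap is reported
as the seven Venn region counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import DataError, EmptyProfileError
from .hetgraph import RankedNodeTable
from .ontology import CATEGORIES, CategoryMapping, categorize_table

logger = logging.getLogger(__name__)

MEMBER_COLUMNS = ("node_id", "category", "score_d1", "score_d2", "hm")


def harmonic_mean(h1, h2):
    """Harmonic mean of two unit-interval scores.

    Zero if either input is zero (the limit convention); always between
    min and max of the inputs.  Accepts scalars or numpy arrays.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if np.any((h1 < 0) | (h1 > 1) | (h2 < 0) | (h2 > 1)):
        raise DataError("harmonic_mean inputs must lie in [0, 1]")
    num = 2.0 * h1 * h2
    den = h1 + h2
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GlobalBaseline:
    """Category distribution of the pooled high-importance nodes."""

    proportions: pd.Series  # indexed by category, sums to 1
    total: int

    def __post_init__(self):
        s = float(self.proportions.sum())
        if self.total > 0 and abs(s - 1.0) > 1e-9:
            raise DataError(f"baseline proportions sum to {s}, not 1")
        if ((self.proportions < 0) | (self.proportions > 1)).any():
            raise DataError("baseline proportions must lie in [0, 1]")


@dataclass
class IntersectionProfile:
    """Shared nodes of a disease pair with HM scores and category profile."""

    pair_label: str
    members: pd.DataFrame  # MEMBER_COLUMNS
    category_counts: pd.Series  # indexed by the category alphabet
    category_percentages: pd.Series | None = None  # None when empty
    category_z: pd.Series | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    def summary(self) -> dict:
        return {
            "pair_label": self.pair_label,
            "n_members": self.n_members,
            "counts": {c: int(v) for c, v in self.category_counts.items()},
            "percentages": None
            if self.category_percentages is None
            else {c: float(v) for c, v in self.category_percentages.items()},
            "z": None
            if self.category_z is None
            else {c: float(v) for c, v in self.category_z.items()},
        }


def high_importance(table: RankedNodeTable, top_fraction: float = 0.10) -> RankedNodeTable:
    """Top fraction of a normalised table by percentile rank.

    Keeps the ceil(q*n) highest-percentile rows (ties broken by node_id
    for determinism); at least one row is always retained.
    """
    if not 0 < top_fraction <= 1:
        raise DataError(f"top_fraction must be in (0, 1], got {top_fraction}")
    n_top = max(1, math.ceil(top_fraction * len(table)))
    frame = (
        table.frame.sort_values(["percentile", "node_id"], ascending=[False, True])
        .head(n_top)
        .sort_index()
        .reset_index(drop=True)
    )
    return RankedNodeTable(table.entity_label, frame)


def _check_unit_interval(table: RankedNodeTable, column: str) -> None:
    vals = table.frame[column].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise DataError(
            f"table {table.entity_label!r} column {column!r} is not normalized "
            "to the unit interval"
        )


def build_intersection(
    table_a: RankedNodeTable,
    table_b: RankedNodeTable,
    mapping: CategoryMapping,
    threshold: float = 0.5,
    score_column: str = "percentile",
    unmapped_policy: str = "drop",
) -> IntersectionProfile:
    """Nodes present in both tables whose HM of unit-interval scores meets
    the (inclusive) threshold, annotated with their single category."""
    if not 0 < threshold <= 1:
        raise DataError(f"threshold must be in (0, 1], got {threshold}")
    for t in (table_a, table_b):
        _check_unit_interval(t, score_column)
    a = categorize_table(table_a, mapping, unmapped_policy).frame
    b = categorize_table(table_b, mapping, unmapped_policy).frame
    merged = a.merge(b, on="node_id", suffixes=("_d1", "_d2"))
    if len(merged):
        s1 = merged[f"{score_column}_d1"].to_numpy(dtype=float)
        s2 = merged[f"{score_column}_d2"].to_numpy(dtype=float)
        hm = harmonic_mean(s1, s2)
        keep = hm >= threshold
        members = pd.DataFrame(
            {
                "node_id": merged["node_id"][keep],
                "category": merged["category_d1"][keep],
                "score_d1": s1[keep],
                "score_d2": s2[keep],
                "hm": hm[keep],
            }
        ).sort_values("node_id").reset_index(drop=True)
    else:
        members = pd.DataFrame(columns=list(MEMBER_COLUMNS))
    alphabet = list(mapping.alphabet)
    counts = (
        members["category"].value_counts().reindex(alphabet, fill_value=0).astype(int)
        if len(members)
        else pd.Series(0, index=alphabet, dtype=int)
    )
    pct = category_percentages(counts) if counts.sum() > 0 else None
    label = f"{table_a.entity_label}∩{table_b.entity_label}"
    return IntersectionProfile(label, members, counts, pct)


def category_percentages(counts: pd.Series) -> pd.Series:
    """Within-intersection percentages, normalised to sum to 100."""
    total = int(counts.sum())
    if total == 0:
        raise EmptyProfileError("all-zero category counts: empty intersection")
    return 100.0 * counts / total


def global_baseline(
    categorized_tables: Iterable[RankedNodeTable],
    alphabet: tuple[str, ...] = CATEGORIES,
    mode: str = "union",
) -> GlobalBaseline:
    """Category distribution of the pooled categorized nodes.

    ``union`` counts each node id once even when shared across diseases;
    ``concat`` counts every (disease, node) occurrence.
    """
    if mode not in {"union", "concat"}:
        raise DataError(f"unknown baseline mode {mode!r}")
    frames = [t.frame[["node_id", "category"]] for t in categorized_tables]
    pooled = pd.concat(frames, ignore_index=True)
    if mode == "union":
        pooled = pooled.drop_duplicates(subset="node_id")
    counts = pooled["category"].value_counts().reindex(list(alphabet), fill_value=0)
    total = int(counts.sum())
    if total == 0:
        raise DataError("cannot build a baseline from zero categorized nodes")
    return GlobalBaseline(counts / total, total)


def z_enrichment(counts: pd.Series, baseline: GlobalBaseline) -> pd.Series:
    """Signed binomial-proportion Z per category against the baseline.

    Positive values mean over-representation.  Degenerate baselines:
    p0 = 0 with k > 0 (or p0 = 1 with k < n) yield signed-infinity
    sentinels with a warning; consistent degenerate cells yield 0.
    """
    n = int(counts.sum())
    if n < 1:
        raise EmptyProfileError("cannot compute enrichment for an empty intersection")
    p0 = baseline.proportions.reindex(counts.index)
    if p0.isna().any():
        raise DataError("baseline is missing categories present in counts")
    k = counts.to_numpy(dtype=float)
    p = p0.to_numpy(dtype=float)
    z = np.zeros(len(k))
    regular = (p > 0) & (p < 1)
    with np.errstate(invalid="ignore"):
        z[regular] = (k[regular] - n * p[regular]) / np.sqrt(
            n * p[regular] * (1 - p[regular])
        )
    inconsistent_lo = (p == 0) & (k > 0)
    inconsistent_hi = (p == 1) & (k < n)
    z[inconsistent_lo] = np.inf
    z[inconsistent_hi] = -np.inf
    if inconsistent_lo.any() or inconsistent_hi.any():
        logger.warning(
            "degenerate baseline proportions with inconsistent counts in %s",
            list(counts.index[inconsistent_lo | inconsistent_hi]),
        )
    return pd.Series(z, index=counts.index)


def permutation_z(
    counts: pd.Series,
    baseline: GlobalBaseline,
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Permutation-null enrichment: resample n nodes from the baseline pool
    ``n_draws`` times and standardise the observed counts against the
    empirical null mean and sd."""
    rng = rng or np.random.default_rng()
    n = int(counts.sum())
    if n < 1:
        raise EmptyProfileError("cannot compute enrichment for an empty intersection")
    p = baseline.proportions.reindex(counts.index).to_numpy(dtype=float)
    null = rng.multinomial(n, p / p.sum(), size=n_draws)
    mu = null.mean(axis=0)
    sd = null.std(axis=0)
    k = counts.to_numpy(dtype=float)
    z = np.zeros(len(k))
    np.divide(k - mu, sd, out=z, where=sd > 0)
    return pd.Series(z, index=counts.index)


def overlap_partition(
    node_sets: Mapping[str, set] | tuple[set, set, set],
    labels: tuple[str, str, str] = ("AD", "ALS", "FTD"),
) -> dict[str, int]:
    """Seven Venn region counts (3 exclusive, 3 pairwise-only, 1 triple)
    for three node-id sets; the regions partition the union."""
    if isinstance(node_sets, Mapping):
        labels = tuple(node_sets)  # type: ignore[assignment]
        sets = [set(node_sets[l]) for l in labels]
    else:
        sets = [set(s) for s in node_sets]
    if len(sets) != 3:
        raise DataError("overlap_partition expects exactly three node sets")
    a, b, c = sets
    la, lb, lc = labels
    return {
        f"{la} only": len(a - b - c),
        f"{lb} only": len(b - a - c),
        f"{lc} only": len(c - a - b),
        f"{la}∩{lb} only": len((a & b) - c),
        f"{la}∩{lc} only": len((a & c) - b),
        f"{lb}∩{lc} only": len((b & c) - a),
        f"{la}∩{lb}∩{lc}": len(a & b & c),
    }
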