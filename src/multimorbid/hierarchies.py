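"""Category hierarchies and rank-based cross-entity comparison.

Normalised node scores are aggregated by ontology category (sum by
default, so both node count and node strength contribute) and the
categories ranked 1 (highest importance) to 13 (lowest).  Hierarchies of
diseases and intersections are then compared with rank statistics:
Spearman's rho and Kendall's tau-b for disease pairs, intersection
versus parent-disease alignment, and per-category signed rank
differences (disease rank minus intersection rank; negative means the
category is prioritised more within the disease than in shared space).

Ties in aggregates are broken by the canonical category order so that
every hierarchy is a strict permutation; the correlation statistics
nonetheless use tie-aware forms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .hetgraph import RankedNodeTable
from .intersections import IntersectionProfile
from .ontology import CATEGORIES

logger = logging.getLogger(__name__)

AGGREGATION_MODES = ("sum", "mean", "count")


@dataclass(frozen=True)
class CategoryHierarchy:
    """Per-entity category aggregates and their ranks (1 = top)."""

    entity_label: str
    scores: pd.Series  # non-negative aggregates, indexed by category
    ranks: pd.Series  # permutation of 1..n_categories

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.ranks.index)


@dataclass(frozen=True)
class SimilarityResult:
    spearman_rho: float
    kendall_tau: float
    n: int


def aggregate_by_category(
    table: RankedNodeTable,
    mode: str = "sum",
    score_column: str = "percentile",
    alphabet: tuple[str, ...] = CATEGORIES,
) -> pd.Series:
    """Aggregate a categorized table's scores per category.

    Categories with no nodes aggregate to 0 (in every mode).
    """
    if mode not in AGGREGATION_MODES:
        raise DataError(f"unknown aggregation mode {mode!r}")
    frame = table.frame
    if "category" not in frame.columns or frame["category"].isna().any():
        raise DataError(f"table {table.entity_label!r} is not fully categorized")
    grouped = frame.groupby("category")[score_column]
    agg = {"sum": grouped.sum, "mean": grouped.mean, "count": grouped.count}[mode]()
    return agg.reindex(list(alphabet), fill_value=0.0).astype(float)


def rank_categories(scores: pd.Series) -> pd.Series:
    """Rank categories 1 (largest aggregate) .. n (smallest).

    Ties are broken deterministically by the canonical order of the
    score index, so the result is always a strict permutation.
    """
    order = sorted(range(len(scores)), key=lambda i: (-scores.iloc[i], i))
    ranks = pd.Series(0, index=scores.index, dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks.iloc[i] = rank
    return ranks


def hierarchy_from_table(
    table: RankedNodeTable,
    mode: str = "sum",
    score_column: str = "percentile",
    alphabet: tuple[str, ...] = CATEGORIES,
) -> CategoryHierarchy:
    scores = aggregate_by_category(table, mode, score_column, alphabet)
    return CategoryHierarchy(table.entity_label, scores, rank_categories(scores))


def hierarchy_from_intersection(
    profile: IntersectionProfile, mode: str = "count"
) -> CategoryHierarchy:
    """Hierarchy of an intersection profile.

    Default ranks categories by member count (equivalently by
    within-intersection percentage); ``sum``/``mean`` aggregate the
    members' harmonic-mean scores instead.
    """
    if mode == "count":
        scores = profile.category_counts.astype(float)
    else:
        table = RankedNodeTable(
            profile.pair_label,
            profile.members.rename(columns={"hm": "percentile"}),
        )
        scores = aggregate_by_category(
            table, mode, "percentile", tuple(profile.category_counts.index)
        )
    return CategoryHierarchy(profile.pair_label, scores, rank_categories(scores))


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def _as_rank_array(ranks) -> np.ndarray:
    arr = np.asarray(pd.Series(ranks).to_numpy(), dtype=float)
    if len(arr) < 3:
        raise DataError("rank correlation needs length >= 3")
    return arr


def spearman_rho(ranks_a, ranks_b) -> float:
    """Spearman rank correlation (tie-safe Pearson-of-ranks form).

    Returns NaN, with a warning, when either vector has zero variance.
    """
    a, b = _as_rank_array(ranks_a), _as_rank_array(ranks_b)
    if len(a) != len(b):
        raise DataError("rank vectors differ in length")
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero-variance rank vector: Spearman undefined")
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


def kendall_tau(ranks_a, ranks_b) -> float:
    """Kendall's tau (tau-b, tie-adjusted)."""
    a, b = _as_rank_array(ranks_a), _as_rank_array(ranks_b)
    if len(a) != len(b):
        raise DataError("rank vectors differ in length")
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero-variance rank vector: Kendall tau undefined")
        return float("nan")
    return float(stats.kendalltau(a, b).statistic)


def similarity(hier_a: CategoryHierarchy, hier_b: CategoryHierarchy) -> SimilarityResult:
    _check_same_categories(hier_a, hier_b)
    a, b = hier_a.ranks, hier_b.ranks.reindex(hier_a.ranks.index)
    return SimilarityResult(spearman_rho(a, b), kendall_tau(a, b), len(a))


def _check_same_categories(*hierarchies: CategoryHierarchy) -> None:
    base = set(hierarchies[0].categories)
    for h in hierarchies[1:]:
        if set(h.categories) != base:
            raise DataError(
                f"category set mismatch between {hierarchies[0].entity_label!r} "
                f"and {h.entity_label!r}"
            )


def alignment(
    intersection: CategoryHierarchy,
    parent_1: CategoryHierarchy,
    parent_2: CategoryHierarchy,
) -> dict[str, SimilarityResult]:
    """Similarity of an intersection hierarchy to each parent disease's,
    on equal footing (same categories, same statistics)."""
    _check_same_categories(intersection, parent_1, parent_2)
    return {
        parent_1.entity_label: similarity(intersection, parent_1),
        parent_2.entity_label: similarity(intersection, parent_2),
    }


def rank_differences(disease_ranks: pd.Series, intersection_ranks: pd.Series) -> pd.Series:
    """Per-category disease rank minus intersection rank.

    Negative entries mark categories prioritised more within the disease
    than within the shared intersection space.  Sums to zero whenever
    both inputs are full permutations over the same categories.
    """
    if set(disease_ranks.index) != set(intersection_ranks.index):
        raise DataError("rank vectors cover different category sets")
    diff = disease_ranks - intersection_ranks.reindex(disease_ranks.index)
    return diff.astype(int)
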