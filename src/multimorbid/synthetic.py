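"""Synthetic semantic-network outputs with planted multimorbidity structure.

The generator emulates the statistical shape of per-disease ranked
concept tables exported from a literature-derived knowledge graph:
unit-interval raw relevance scores, category-structured node
populations, and controllable cross-disease node sharing.  It plants
two recoverable structures so the full pipeline can be validated
end-to-end:

* a shared metabolic–immune core — nodes shared between diseases are
  drawn from a pool whose category distribution multiplies the two
  designated core categories by ``shared_core_boost``;
* a disease-similarity ordering — each disease's category-weight
  profile defaults to ``14 - published rank`` from the reference
  disease-rank matrix, which orders profile similarity as
  AD–FTD > AD–ALS > ALS–FTD.

Sharing rule: each of a disease's ``n`` node slots is independently
shared with probability ``overlap_fraction`` and then filled by
sampling without replacement from a common pool of size ``n``;
remaining slots get disease-exclusive nodes.  Two diseases therefore
share about ``f**2 * n`` nodes, giving an expected pairwise Jaccard
index of ``f**2 / (2 - f**2)``.

Raw scores are Beta-distributed with a category-dependent mean shift
(categories weighted higher in a disease's profile score higher on
average); shared nodes receive correlated-but-imperfect scores across
diseases through a Gaussian copula with a shared latent factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .exceptions import ConfigError
from .hetgraph import HetGraph, RankedNodeTable, normalize_scores
from .intersections import build_intersection
from .hierarchies import hierarchy_from_table, spearman_rho, rank_categories
from .ontology import CATEGORIES, CategoryMapping

DISEASES = ("AD", "ALS", "FTD")

DEFAULT_SHARED_CATEGORIES = ("Metabolic", "Immune/Inflammatory/Infectious")


def default_profiles() -> dict[str, np.ndarray]:
    """Category-weight profiles derived from the published disease rank
    matrix: weight = 14 - rank, in canonical category order."""
    from .landscape import load_published_disease_ranks

    ranks = load_published_disease_ranks()
    return {d: (14 - ranks[d].to_numpy()).astype(float) for d in DISEASES}


def uniform_profiles() -> dict[str, np.ndarray]:
    """Flat profiles: no category structure, no planted similarity."""
    return {d: np.ones(len(CATEGORIES)) for d in DISEASES}


@dataclass(frozen=True)
class SyntheticConfig:
    n_nodes_per_disease: int = 2000
    category_weight_profiles: Mapping[str, np.ndarray] | None = None  # None -> default_profiles()
    shared_categories: tuple[str, ...] = DEFAULT_SHARED_CATEGORIES
    shared_core_boost: float = 5.0
    overlap_fraction: float = 0.3
    beta_concentration: float = 8.0
    score_mean_low: float = 0.30
    score_mean_high: float = 0.75
    shared_score_corr: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes_per_disease < 1:
            raise ConfigError("n_nodes_per_disease must be >= 1")
        if not 0 <= self.overlap_fraction <= 1:
            raise ConfigError("overlap_fraction must be in [0, 1]")
        if self.shared_core_boost <= 0:
            raise ConfigError("shared_core_boost must be positive")
        unknown = set(self.shared_categories) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown shared categories: {sorted(unknown)}")
        for d, w in self.profiles().items():
            w = np.asarray(w, dtype=float)
            if len(w) != len(CATEGORIES) or (w < 0).any() or w.sum() == 0:
                raise ConfigError(
                    f"profile for {d!r} must be {len(CATEGORIES)} non-negative "
                    "weights, not all zero"
                )

    def profiles(self) -> dict[str, np.ndarray]:
        if self.category_weight_profiles is None:
            return default_profiles()
        return {d: np.asarray(w, dtype=float) for d, w in self.category_weight_profiles.items()}


def expected_pairwise_jaccard(overlap_fraction: float) -> float:
    """Closed-form expectation implied by the sharing rule (ratio of the
    expected intersection and union sizes)."""
    f2 = overlap_fraction**2
    return f2 / (2 - f2) if f2 > 0 else 0.0


def _category_means(weights: np.ndarray, low: float, high: float) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    top = w.max() if w.max() > 0 else 1.0
    return low + (high - low) * (w / top)


def generate_disease_tables(
    config: SyntheticConfig,
) -> tuple[dict[str, RankedNodeTable], CategoryMapping, dict]:
    """Three normalised ranked tables, their ground-truth category
    mapping, and a ground-truth record of the planted structure.

    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes_per_disease
    profiles = config.profiles()
    cat_idx = {c: i for i, c in enumerate(CATEGORIES)}

    # shared pool: boosted category distribution, one latent factor per node
    pool_w = np.mean([profiles[d] for d in DISEASES], axis=0)
    boost = np.ones(len(CATEGORIES))
    for c in config.shared_categories:
        boost[cat_idx[c]] = config.shared_core_boost
    pool_p = pool_w * boost
    pool_p = pool_p / pool_p.sum()
    pool_ids = np.array([f"S{i:06d}" for i in range(n)])
    pool_cats = rng.choice(len(CATEGORIES), size=n, p=pool_p)
    pool_latent = rng.standard_normal(n)

    mapping_entries: dict[str, str] = {
        pid: CATEGORIES[c] for pid, c in zip(pool_ids, pool_cats)
    }
    tables: dict[str, RankedNodeTable] = {}
    truth: dict = {
        "planted_categories": list(config.shared_categories),
        "seed": config.seed,
        "overlap_fraction": config.overlap_fraction,
        "shared_core_boost": config.shared_core_boost,
        "shared_ids": {},
        "exclusive_ids": {},
    }
    rho = config.shared_score_corr
    kappa = config.beta_concentration

    for d in DISEASES:
        w = profiles[d]
        means = _category_means(w, config.score_mean_low, config.score_mean_high)
        n_shared = rng.binomial(n, config.overlap_fraction)
        shared_pos = (
            rng.choice(n, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
        )
        n_excl = n - n_shared
        excl_ids = np.array([f"{d}{i:06d}" for i in range(n_excl)])
        excl_p = w / w.sum()
        excl_cats = rng.choice(len(CATEGORIES), size=n_excl, p=excl_p)

        # scores: Beta(mu*k, (1-mu)*k); shared nodes via Gaussian copula
        noise = rng.standard_normal(n_shared)
        u_shared = norm.cdf(rho * pool_latent[shared_pos] + math.sqrt(1 - rho**2) * noise)
        mu_s = means[pool_cats[shared_pos]]
        raw_shared = beta_dist.ppf(u_shared, mu_s * kappa, (1 - mu_s) * kappa)
        mu_e = means[excl_cats]
        raw_excl = rng.beta(mu_e * kappa, (1 - mu_e) * kappa) if n_excl else np.array([])

        node_ids = np.concatenate([pool_ids[shared_pos], excl_ids])
        cats = np.concatenate([pool_cats[shared_pos], excl_cats]).astype(int)
        raw = np.concatenate([raw_shared, raw_excl])
        order = np.argsort(node_ids)
        frame = pd.DataFrame(
            {
                "node_id": node_ids[order],
                "name": [
                    f"{CATEGORIES[c]} concept {i}"
                    for i, c in zip(node_ids[order], cats[order])
                ],
                "source_type": "DSYN",
                "raw_score": np.clip(raw[order], 0.0, 1.0),
            }
        )
        tables[d] = normalize_scores(RankedNodeTable(d, frame))
        for nid, c in zip(excl_ids, excl_cats):
            mapping_entries[nid] = CATEGORIES[c]
        truth["shared_ids"][d] = sorted(pool_ids[shared_pos])
        truth["exclusive_ids"][d] = {
            nid: CATEGORIES[c] for nid, c in zip(excl_ids, excl_cats)
        }

    return tables, CategoryMapping(mapping_entries), truth


# ---------------------------------------------------------------------------
# Toy heterogeneous graphs
# ---------------------------------------------------------------------------

DEFAULT_TOY_SCHEMA = (
    ("DSYN", "affects", "AAPP"),
    ("AAPP", "associated_with", "TARGET"),
)


def generate_toy_graph(
    n_per_type: int = 3,
    relation_density: float = 1.0,
    seed: int = 0,
    schema: tuple[tuple[str, str, str], ...] = DEFAULT_TOY_SCHEMA,
) -> HetGraph:
    """Random schema-valid typed graph; every possible edge of every
    declared relation is present independently with ``relation_density``
    (density 1 keeps them all, guaranteeing a source-to-target path)."""
    if n_per_type < 1:
        raise ConfigError("n_per_type must be >= 1")
    if not 0 < relation_density <= 1:
        raise ConfigError("relation_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    types = sorted({t for rel in schema for t in (rel[0], rel[2])})
    nodes = [(f"{t}{i}", t) for t in types for i in range(n_per_type)]
    edges = []
    for src_t, pred, dst_t in schema:
        for i in range(n_per_type):
            for j in range(n_per_type):
                if relation_density == 1.0 or rng.random() < relation_density:
                    edges.append((f"{src_t}{i}", pred, f"{dst_t}{j}"))
    return HetGraph(nodes, edges, schema=schema)


# ---------------------------------------------------------------------------
# Planted-structure recovery
# ---------------------------------------------------------------------------

PAIRS = (("AD", "ALS"), ("AD", "FTD"), ("ALS", "FTD"))


def _replicate_outcome(config: SyntheticConfig, threshold: float = 0.5):
    from .ontology import categorize_table

    tables, mapping, _ = generate_disease_tables(config)
    top3_sets = []
    for d1, d2 in PAIRS:
        prof = build_intersection(tables[d1], tables[d2], mapping, threshold)
        if prof.n_members == 0:
            top3_sets.append(set())
            continue
        ranks = rank_categories(prof.category_counts.astype(float))
        top3_sets.append(set(ranks.index[ranks <= 3]))
    hiers = {
        d: hierarchy_from_table(categorize_table(tables[d], mapping)) for d in DISEASES
    }
    rho = {
        f"{a}-{b}": spearman_rho(hiers[a].ranks, hiers[b].ranks) for a, b in PAIRS
    }
    ordering_ok = rho["AD-FTD"] > rho["AD-ALS"] > rho["ALS-FTD"]
    return top3_sets, rho, ordering_ok


def planted_recovery_suite(
    config: SyntheticConfig, n_replicates: int = 100, base_seed: int | None = None
) -> dict:
    """Run the full pipeline over seeded replicates and report how often
    the planted structure is recovered.

    ``top3_recovery``: fraction of replicates in which every planted core
    category ranks in the top 3 of every pairwise intersection's category
    profile.  ``ordering_recovery``: fraction in which the planted
    disease-similarity ordering (AD–FTD > AD–ALS > ALS–FTD by Spearman's
    rho between disease hierarchies) is recovered.
    ``chance_top3_rate``: the top-3 rate expected if the planted pair of
    category labels were assigned by random permutation, given the
    observed jointly-top-3 sets.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    base = config.seed if base_seed is None else base_seed
    planted = set(config.shared_categories)
    n_cat = len(CATEGORIES)
    top3_hits = 0
    ordering_hits = 0
    chance_rates = []
    for r in range(n_replicates):
        seed_r = int(np.random.SeedSequence((base, r)).generate_state(1)[0] % 2**31)
        cfg = replace(config, seed=seed_r)
        top3_sets, _, ordering_ok = _replicate_outcome(cfg)
        joint = set.intersection(*top3_sets) if top3_sets else set()
        if all(planted <= s for s in top3_sets):
            top3_hits += 1
        ordering_hits += bool(ordering_ok)
        k = len(planted)
        chance_rates.append(
            math.comb(len(joint), k) / math.comb(n_cat, k) if len(joint) >= k else 0.0
        )
    return {
        "n_replicates": n_replicates,
        "top3_recovery": top3_hits / n_replicates,
        "ordering_recovery": ordering_hits / n_replicates,
        "chance_top3_rate": float(np.mean(chance_rates)),
        "planted_categories": sorted(planted),
    }
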