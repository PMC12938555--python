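"""Integrated priority landscape, Borda integrative ranking, reporting.

The landscape juxtaposes the six entities (three diseases and their
three pairwise intersections) over the thirteen categories.  Ordinal
ranks are shown both directly (1 = highest importance) and as
rank-based priority scores, 15 - rank, which preserve order while
making "higher = more important" visually; no averaging of ordinal
ranks across entities is ever performed.

The integrative cross-disease summary is a Borda aggregation: categories
are ordered by the ascending sum of their three disease-specific ranks,
with ties broken by lower median rank, then lower minimum rank; a
residual three-way tie (impossible to break by those rules) falls back
to the canonical category order and is flagged in the tie trace.

The published disease-rank matrix for Alzheimer's disease (AD),
amyotrophic lateral sclerosis (ALS) and frontotemporal dementia (FTD)
ships as package data and is the reference input for the Borda stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError
from .hierarchies import CategoryHierarchy
from .ontology import CATEGORIES

#: Published systemic-domain labels -> canonical category labels.
TABLE1_DOMAIN_TO_CATEGORY: dict[str, str] = {
    "Autoimmune, Immunological, Infectious Disorders": "Immune/Inflammatory/Infectious",
    "Metabolic Dysfunction and Mitochondrial Impairment": "Metabolic",
    "Cardiovascular Pathology or Dysfunction": "Cardiovascular",
    "Gastrointestinal or Gut-Brain Axis Disorders": "Gastrointestinal",
    "Endocrine and Hormonal Imbalances": "Endocrine",
    "Hematological Dysfunction": "Hematological",
    "Other/Neuropsychiatric Disorders": "Other/Neuro-Psych",
    "Kidney Dysfunction": "Kidney",
    "Liver Dysfunction": "Liver",
    "Dermatological": "Dermatological",
    "Eyes, Ears, Throat (EET)": "Sensory (EET)",
    "Environmental Toxins": "Environmental Toxins",
    "Orthopedic and Muscle": "Musculoskeletal/Orthopedic",
}

DISEASES = ("AD", "ALS", "FTD")


def load_published_disease_ranks(path=None) -> pd.DataFrame:
    """The published 13x3 disease rank matrix (plus its integrative
    column), reindexed to canonical category labels in canonical order."""
    if path is None:
        with resources.as_file(
            resources.files("multimorbid.data") / "table1_disease_ranks.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    df["category"] = df["systemic_domain"].map(TABLE1_DOMAIN_TO_CATEGORY)
    if df["category"].isna().any():
        bad = df.loc[df["category"].isna(), "systemic_domain"].tolist()
        raise DataError(f"unrecognised systemic domain label(s): {bad}")
    df = df.set_index("category").reindex(list(CATEGORIES))
    return df[["AD", "ALS", "FTD", "integrative"]].astype(int)


def priority_score(rank):
    """Priority transform of an ordinal rank: 15 - rank.

    Accepts a scalar or vector of ranks in 1..13.
    """
    arr = np.asarray(rank)
    if np.any((arr < 1) | (arr > 13)):
        raise DataError(f"rank out of range 1..13: {rank!r}")
    out = 15 - arr
    return int(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BordaResult:
    rank_sum: pd.Series  # per-category sum of disease ranks
    integrative_rank: pd.Series  # permutation of 1..n
    tie_trace: tuple[str, ...]  # which rule resolved each tie group


def _validate_permutation_column(col: pd.Series, name: str) -> None:
    n = len(col)
    if sorted(col.tolist()) != list(range(1, n + 1)):
        raise DataError(f"column {name!r} is not a permutation of 1..{n}")


def borda_aggregate(disease_ranks: pd.DataFrame) -> BordaResult:
    """Integrative category ranking across the disease columns.

    Categories are ordered by ascending sum of their per-disease ranks;
    ties by lower median rank, then lower minimum rank, then (flagged)
    canonical input order.
    """
    cats = list(disease_ranks.index)
    for name in disease_ranks.columns:
        _validate_permutation_column(disease_ranks[name], str(name))
    rows = {c: disease_ranks.loc[c].tolist() for c in cats}
    rank_sum = pd.Series({c: int(sum(r)) for c, r in rows.items()})
    canon = {c: i for i, c in enumerate(cats)}
    order = sorted(
        cats,
        key=lambda c: (rank_sum[c], median(rows[c]), min(rows[c]), canon[c]),
    )
    integrative = pd.Series({c: i for i, c in enumerate(order, start=1)}).reindex(cats)

    trace: list[str] = []
    by_sum: dict[int, list[str]] = {}
    for c in cats:
        by_sum.setdefault(rank_sum[c], []).append(c)
    for s, group in sorted(by_sum.items()):
        if len(group) == 1:
            continue
        medians = {c: median(rows[c]) for c in group}
        if len(set(medians.values())) == len(group):
            trace.append(f"sum={s} {sorted(group)}: resolved by median")
            continue
        mins = {c: (medians[c], min(rows[c])) for c in group}
        if len(set(mins.values())) == len(group):
            trace.append(f"sum={s} {sorted(group)}: resolved by median then minimum")
        else:
            trace.append(
                f"sum={s} {sorted(group)}: RESIDUAL tie, canonical order fallback"
            )
    return BordaResult(rank_sum, integrative.astype(int), tuple(trace))


def build_landscape(
    hierarchies: Sequence[CategoryHierarchy],
    as_priority: bool = True,
) -> pd.DataFrame:
    """Entities x categories matrix of priority scores (or raw ranks).

    Requires complete hierarchies over one shared category set; entity
    rows keep the order they were given in.
    """
    if not hierarchies:
        raise DataError("no hierarchies supplied")
    cats = hierarchies[0].categories
    rows = {}
    for h in hierarchies:
        if set(h.categories) != set(cats):
            raise DataError(f"entity {h.entity_label!r} covers a different category set")
        ranks = h.ranks.reindex(list(cats))
        if ranks.isna().any():
            raise DataError(f"entity {h.entity_label!r} has missing category ranks")
        rows[h.entity_label] = priority_score(ranks.to_numpy()) if as_priority else ranks.to_numpy()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(cats))


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

REQUIRED_STAGES = (
    "tables",
    "mapping",
    "intersections",
    "baseline",
    "hierarchies",
    "similarity",
    "alignment",
    "rank_differences",
    "landscape",
    "borda",
)


def _slug(label: str) -> str:
    return label.replace("∩", "_x_").replace("/", "-").replace(" ", "_")


def write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, ensure_ascii=False) + "\n")


def file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(outdir, stages: Mapping[str, object]) -> dict[str, str]:
    """Write the deterministic report bundle; returns file digests.

    ``stages`` must contain every key in :data:`REQUIRED_STAGES` (tables,
    mapping, intersection profiles, baseline, hierarchies, similarity and
    alignment results, rank differences, landscape, Borda result).
    Byte-identical across reruns with the same config and seed: floats
    use a fixed format and JSON keys are sorted; no timestamps.
    """
    missing = [s for s in REQUIRED_STAGES if s not in stages]
    if missing:
        raise DataError(f"cannot write report, missing stage output(s): {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}

    def _register(path: Path):
        digests[str(path.relative_to(outdir))] = file_digest(path)

    for label, table in stages["tables"].items():  # type: ignore[union-attr]
        p = outdir / f"ranked_{_slug(label)}.tsv"
        table.to_tsv(p)
        _register(p)

    from .ontology import write_mapping  # local import to avoid cycle

    p = outdir / "mapping.tsv"
    write_mapping(stages["mapping"], p)
    _register(p)

    for profile in stages["intersections"].values():  # type: ignore[union-attr]
        slug = _slug(profile.pair_label)
        p = outdir / f"intersection_{slug}_members.tsv"
        profile.members.to_csv(p, sep="\t", index=False, float_format="%.10g")
        _register(p)
        p = outdir / f"intersection_{slug}_summary.json"
        write_json(profile.summary(), p)
        _register(p)

    baseline = stages["baseline"]
    p = outdir / "global_baseline.json"
    write_json(
        {
            "total": baseline.total,
            "proportions": {c: float(v) for c, v in baseline.proportions.items()},
        },
        p,
    )
    _register(p)

    rows = []
    for h in stages["hierarchies"]:  # type: ignore[union-attr]
        for cat in h.categories:
            rows.append(
                {
                    "entity": h.entity_label,
                    "category": cat,
                    "score": float(h.scores[cat]),
                    "rank": int(h.ranks[cat]),
                }
            )
    p = outdir / "hierarchies.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.10g")
    _register(p)

    p = outdir / "similarity.json"
    write_json(
        {
            pair: {"spearman": r.spearman_rho, "kendall": r.kendall_tau, "n": r.n}
            for pair, r in stages["similarity"].items()
        },
        p,
    )
    _register(p)

    p = outdir / "alignment.json"
    write_json(
        {
            inter: {
                parent: {"spearman": r.spearman_rho, "kendall": r.kendall_tau, "n": r.n}
                for parent, r in parents.items()
            }
            for inter, parents in stages["alignment"].items()
        },
        p,
    )
    _register(p)

    p = outdir / "rank_differences.tsv"
    stages["rank_differences"].to_csv(p, sep="\t")
    _register(p)

    landscape = stages["landscape"]
    p = outdir / "landscape_priority.tsv"
    landscape.to_csv(p, sep="\t")
    _register(p)
    p = outdir / "landscape_ranks.tsv"
    (15 - landscape).to_csv(p, sep="\t")
    _register(p)

    borda: BordaResult = stages["borda"]  # type: ignore[assignment]
    p = outdir / "borda.tsv"
    pd.DataFrame(
        {
            "rank_sum": borda.rank_sum,
            "integrative_rank": borda.integrative_rank,
        }
    ).rename_axis("category").to_csv(p, sep="\t")
    _register(p)
    p = outdir / "borda_tie_trace.json"
    write_json(list(borda.tie_trace), p)
    _register(p)

    if "overlap" in stages:
        p = outdir / "venn_overlap.json"
        write_json({k: int(v) for k, v in stages["overlap"].items()}, p)
        _register(p)

    summary = {
        "n_tables": len(stages["tables"]),
        "n_intersections": len(stages["intersections"]),
        "members_per_intersection": {
            prof.pair_label: prof.n_members
            for prof in stages["intersections"].values()
        },
        "baseline_total": stages["baseline"].total,
        "entities": [h.entity_label for h in stages["hierarchies"]],
    }
    if "config" in stages:
        summary["config"] = stages["config"]
    p = outdir / "run_summary.json"
    write_json(summary, p)
    _register(p)
    return digests
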