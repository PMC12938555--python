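"""End-to-end orchestration: config, staged execution, run manifest.

A run takes per-disease ranked concept tables (synthetic by default, or
supplied as files), a node-to-category mapping, and a configuration, and
executes the stages in order::

    simulate -> normalize -> categorize -> intersect -> enrich ->
    hierarchy -> similarity -> landscape -> borda -> report

Every stage is a pure function of (inputs, config, seed): the single
global seed is expanded into independent per-stage substreams, so a
stage run in isolation reproduces its in-pipeline output.  The report
bundle is byte-identical across reruns with the same config and seed;
the manifest records the config hash, seed, stage list and per-file
SHA-256 digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError, DataError
from .hetgraph import RankedNodeTable, normalize_scores
from .hierarchies import (
    AGGREGATION_MODES,
    alignment,
    hierarchy_from_intersection,
    hierarchy_from_table,
    rank_differences,
    similarity,
)
from .intersections import (
    build_intersection,
    global_baseline,
    high_importance,
    overlap_partition,
    permutation_z,
    z_enrichment,
)
from .landscape import BordaResult, borda_aggregate, build_landscape, write_json, write_report
from .ontology import categorize_table, load_mapping, merge_neuro_psych
from .synthetic import DISEASES, PAIRS, SyntheticConfig, generate_disease_tables

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "normalize",
    "categorize",
    "intersect",
    "enrich",
    "hierarchy",
    "similarity",
    "landscape",
    "borda",
    "report",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scores": {"use": "percentile"},
    "ontology": {"unmapped_policy": "drop"},
    "intersection": {"threshold": 0.5, "high_importance_fraction": 0.10},
    "aggregation": {"mode": "sum"},
    "enrichment": {
        "formula": "binomial",
        "baseline_mode": "union",
        "permutation_draws": 10000,
    },
    "synthetic": {
        "enabled": True,
        "n_nodes_per_disease": 2000,
        "overlap_fraction": 0.3,
        "shared_core_boost": 5.0,
    },
    "inputs": {"tables": {}, "mapping": None},
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Default config, optionally merged with a YAML file and overrides."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        config = _deep_merge(config, user)
    if overrides:
        config = _deep_merge(config, overrides)
    validate_config(config)
    return config


def validate_config(config: Mapping) -> None:
    thr = config["intersection"]["threshold"]
    if not 0 < thr <= 1:
        raise ConfigError(f"intersection.threshold must be in (0, 1], got {thr}")
    q = config["intersection"]["high_importance_fraction"]
    if not 0 < q <= 1:
        raise ConfigError(f"intersection.high_importance_fraction must be in (0, 1], got {q}")
    mode = config["aggregation"]["mode"]
    if mode not in AGGREGATION_MODES:
        raise ConfigError(f"aggregation.mode must be one of {AGGREGATION_MODES}, got {mode!r}")
    use = config["scores"]["use"]
    if use not in {"percentile", "standardized"}:
        raise ConfigError(f"scores.use must be 'percentile' or 'standardized', got {use!r}")
    formula = config["enrichment"]["formula"]
    if formula not in {"binomial", "permutation"}:
        raise ConfigError(f"enrichment.formula must be 'binomial' or 'permutation', got {formula!r}")
    if config["enrichment"]["baseline_mode"] not in {"union", "concat"}:
        raise ConfigError("enrichment.baseline_mode must be 'union' or 'concat'")
    if config["ontology"]["unmapped_policy"] not in {"error", "drop", "bucket"}:
        raise ConfigError("ontology.unmapped_policy must be error, drop or bucket")
    if not config["synthetic"].get("enabled", False):
        tables = config["inputs"].get("tables") or {}
        if not tables or not config["inputs"].get("mapping"):
            raise ConfigError(
                "synthetic.enabled is false but inputs.tables / inputs.mapping are not set"
            )


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage substream seed (< 2**31) from the global seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence((int(global_seed), idx)).generate_state(1)[0] % 2**31)


def _load_input_tables(config: Mapping) -> dict[str, RankedNodeTable]:
    tables = {}
    for label, path in config["inputs"]["tables"].items():
        if not Path(path).exists():
            raise DataError(f"input table for {label!r} not found: {path}")
        tables[label] = RankedNodeTable.from_tsv(path, label)
    return tables


def run_all(config: Mapping, outdir) -> dict:
    """Execute the full pipeline; returns the run manifest (also written
    to ``outdir/manifest.json``).  Fails fast, naming the failing stage."""
    validate_config(config)
    outdir = Path(outdir)
    seed = int(config["seed"])
    stage = "simulate"
    try:
        if config["synthetic"]["enabled"]:
            syn = config["synthetic"]
            syn_cfg = SyntheticConfig(
                n_nodes_per_disease=int(syn["n_nodes_per_disease"]),
                overlap_fraction=float(syn["overlap_fraction"]),
                shared_core_boost=float(syn["shared_core_boost"]),
                seed=stage_seed(seed, "simulate"),
            )
            tables, mapping, _truth = generate_disease_tables(syn_cfg)
        else:
            tables = _load_input_tables(config)
            mapping = load_mapping(config["inputs"]["mapping"])
        diseases = list(tables)

        stage = "normalize"
        tables = {d: normalize_scores(t) for d, t in tables.items()}

        stage = "categorize"
        mapping = merge_neuro_psych(mapping)
        policy = config["ontology"]["unmapped_policy"]
        categorized = {d: categorize_table(t, mapping, policy) for d, t in tables.items()}
        q = config["intersection"]["high_importance_fraction"]
        high = {d: high_importance(t, q) for d, t in categorized.items()}
        overlap = overlap_partition(
            {d: set(h.frame["node_id"]) for d, h in high.items()}
        )

        stage = "intersect"
        threshold = config["intersection"]["threshold"]
        pairs = [(a, b) for a, b in PAIRS if a in tables and b in tables] or [
            (diseases[i], diseases[j])
            for i in range(len(diseases))
            for j in range(i + 1, len(diseases))
        ]
        profiles = {
            (a, b): build_intersection(
                tables[a], tables[b], mapping, threshold, "percentile", policy
            )
            for a, b in pairs
        }

        stage = "enrich"
        baseline = global_baseline(
            high.values(), mode=config["enrichment"]["baseline_mode"]
        )
        rng = np.random.default_rng(stage_seed(seed, "enrich"))
        for prof in profiles.values():
            if prof.n_members == 0:
                logger.info("empty intersection %s: no enrichment", prof.pair_label)
                continue
            if config["enrichment"]["formula"] == "binomial":
                prof.category_z = z_enrichment(prof.category_counts, baseline)
            else:
                prof.category_z = permutation_z(
                    prof.category_counts,
                    baseline,
                    int(config["enrichment"]["permutation_draws"]),
                    rng,
                )

        stage = "hierarchy"
        mode = config["aggregation"]["mode"]
        score_col = config["scores"]["use"]
        disease_hier = {
            d: hierarchy_from_table(t, mode, score_col) for d, t in categorized.items()
        }
        inter_hier = {
            pair: hierarchy_from_intersection(profiles[pair]) for pair in pairs
        }

        stage = "similarity"
        sim = {
            f"{a}-{b}": similarity(disease_hier[a], disease_hier[b]) for a, b in pairs
        }
        align = {
            profiles[(a, b)].pair_label: alignment(
                inter_hier[(a, b)], disease_hier[a], disease_hier[b]
            )
            for a, b in pairs
        }
        diffs = {}
        for a, b in pairs:
            label = profiles[(a, b)].pair_label
            for d in (a, b):
                diffs[f"{d} vs {label}"] = rank_differences(
                    disease_hier[d].ranks, inter_hier[(a, b)].ranks
                )
        diff_frame = pd.DataFrame(diffs).rename_axis("category")

        stage = "landscape"
        entities = [disease_hier[d] for d in diseases] + [
            inter_hier[p] for p in pairs
        ]
        landscape = build_landscape(entities, as_priority=True)

        stage = "borda"
        rank_matrix = pd.DataFrame(
            {d: disease_hier[d].ranks for d in diseases}
        )
        borda = borda_aggregate(rank_matrix)

        stage = "report"
        digests = write_report(
            outdir,
            {
                "tables": tables,
                "mapping": mapping,
                "intersections": {profiles[p].pair_label: profiles[p] for p in pairs},
                "baseline": baseline,
                "hierarchies": entities,
                "similarity": sim,
                "alignment": align,
                "rank_differences": diff_frame,
                "landscape": landscape,
                "borda": borda,
                "overlap": overlap,
                "config": json.loads(json.dumps(config, sort_keys=True, default=str)),
            },
        )
    except Exception as err:
        raise type(err)(f"stage {stage!r} failed: {err}") from err

    manifest = {
        "tool_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "stages": list(STAGES),
        "digests": digests,
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
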