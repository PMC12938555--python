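"""The 13-category mechanistic ontology and node-to-category mappings.

Disease/syndrome concept nodes are assigned to exactly one of thirteen
mechanistically interpretable system categories (metabolic, immune,
cardiovascular, ...).  The category set is closed; "Neurological" and
"Psychiatric" exist only as provisional labels that are merged into the
single Other/Neuro-Psych category, because in neurodegenerative disease
those node sets are dominated by disease-defining phenomena (dementia,
mood change) rather than independent comorbidity.

Mappings are an input artifact — curated upstream, read here from a
two-column table — never computed by this package.  The pharmacologic
(PHSU) channel reuses the same machinery with a different, user-declared
label alphabet of broad mechanistic drug classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping

import pandas as pd

from .exceptions import DataError, MappingError
from .hetgraph import RankedNodeTable

logger = logging.getLogger(__name__)

#: Canonical category order, used for reporting and for every
#: deterministic tie-break in the pipeline.
CATEGORIES: tuple[str, ...] = (
    "Metabolic",
    "Immune/Inflammatory/Infectious",
    "Cardiovascular",
    "Other/Neuro-Psych",
    "Sensory (EET)",
    "Gastrointestinal",
    "Endocrine",
    "Hematological",
    "Dermatological",
    "Liver",
    "Kidney",
    "Musculoskeletal/Orthopedic",
    "Environmental Toxins",
)

NEURO_PSYCH = "Other/Neuro-Psych"

#: Provisional labels accepted on input and rewritten by merge_neuro_psych.
PROVISIONAL_LABELS: frozenset[str] = frozenset({"Neurological", "Psychiatric"})

#: Default mechanistic drug-class alphabet for the PHSU channel; user
#: extensible via config, unlike the closed DSYN set above.
PHSU_CLASSES: tuple[str, ...] = (
    "anti-inflammatory",
    "antioxidant",
    "neuromodulatory",
    "cardiometabolic",
    "antimicrobial",
    "toxin-related",
    "other",
)


@dataclass(frozen=True)
class CategoryMapping:
    """node_id -> single category, over a declared label alphabet."""

    entries: Mapping[str, str]
    alphabet: tuple[str, ...] = CATEGORIES
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        allowed = set(self.alphabet) | PROVISIONAL_LABELS
        bad = {c for c in self.entries.values() if c not in allowed}
        if bad:
            raise MappingError(f"categories outside the declared alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, node_id: str) -> str | None:
        return self.entries.get(node_id)


def load_mapping(path, alphabet: tuple[str, ...] = CATEGORIES) -> CategoryMapping:
    """Read a tab-separated ``node_id<TAB>category_label`` mapping table.

    Leading ``# alias old=new`` comment lines declare label aliases.
    Unknown labels and conflicting duplicate assignments are collected
    and reported together in a single :class:`MappingError`.
    """
    aliases: dict[str, str] = {}
    entries: dict[str, str] = {}
    problems: list[str] = []
    allowed = set(alphabet) | PROVISIONAL_LABELS
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("alias ") and "=" in body:
                    old, new = body[len("alias "):].split("=", 1)
                    aliases[old.strip()] = new.strip()
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                problems.append(f"line {lineno}: expected 2 tab-separated fields: {line!r}")
                continue
            node_id, label = parts[0].strip(), parts[1].strip()
            if lineno == 1 and (node_id, label) == ("node_id", "category_label"):
                continue  # optional header row
            label = aliases.get(label, label)
            if label not in allowed:
                problems.append(f"line {lineno}: unknown category {label!r} for node {node_id!r}")
                continue
            if node_id in entries and entries[node_id] != label:
                problems.append(
                    f"line {lineno}: node {node_id!r} already mapped to "
                    f"{entries[node_id]!r}, conflicting with {label!r}"
                )
                continue
            entries[node_id] = label
    if problems:
        raise MappingError(
            f"{len(problems)} invalid mapping row(s):\n" + "\n".join(problems),
            conflicts=problems,
        )
    return CategoryMapping(entries, alphabet=tuple(alphabet))


def write_mapping(mapping: CategoryMapping, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tcategory_label\n")
        for node_id in sorted(mapping.entries):
            fh.write(f"{node_id}\t{mapping.entries[node_id]}\n")


def merge_neuro_psych(mapping: CategoryMapping) -> CategoryMapping:
    """Rewrite provisional Neurological/Psychiatric labels to
    Other/Neuro-Psych.  Idempotent; all other entries unchanged."""
    merged = {
        n: (NEURO_PSYCH if c in PROVISIONAL_LABELS else c)
        for n, c in mapping.entries.items()
    }
    return dc_replace(mapping, entries=merged)


def categorize_table(
    table: RankedNodeTable,
    mapping: CategoryMapping,
    unmapped_policy: str = "drop",
) -> RankedNodeTable:
    """Annotate every row with its single ontology category.

    ``unmapped_policy``: ``error`` raises naming the first unmapped node,
    ``drop`` removes unmapped rows (count logged and recorded in
    ``frame.attrs['n_unmapped']``), ``bucket`` assigns them to
    Other/Neuro-Psych.
    """
    if unmapped_policy not in {"error", "drop", "bucket"}:
        raise DataError(f"unknown unmapped_policy {unmapped_policy!r}")
    frame = table.frame.copy()
    cats = frame["node_id"].map(mapping.entries)
    unmapped = frame.loc[cats.isna(), "node_id"].tolist()
    if unmapped and unmapped_policy == "error":
        raise MappingError(
            f"{len(unmapped)} unmapped node(s) in {table.entity_label!r}, "
            f"first: {unmapped[0]!r}"
        )
    frame["category"] = cats
    if unmapped_policy == "bucket":
        frame["category"] = frame["category"].fillna(NEURO_PSYCH)
    elif unmapped:
        frame = frame[~cats.isna()].reset_index(drop=True)
        logger.info(
            "dropped %d unmapped node(s) from %s", len(unmapped), table.entity_label
        )
    out = RankedNodeTable(table.entity_label, frame)
    out.frame.attrs["n_unmapped"] = len(unmapped)
    return out
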