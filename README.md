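# multimorbid

Ontology-guided multimorbidity landscapes from semantic-network concept
rankings.

Neurodegenerative diseases such as Alzheimer's disease (AD), amyotrophic
lateral sclerosis (ALS) and frontotemporal dementia (FTD) share comorbidity
and antecedent-disease structure that single-disease studies miss.
Literature-based discovery platforms rank disease/syndrome (DSYN) and
pharmacologic-substance (PHSU) concept nodes against a target disease by
HeteSim relevance over a heterogeneous biomedical knowledge graph.
`multimorbid` turns those per-disease ranked tables into a comparative
multimorbidity analysis:

1. **HeteSim ranking** (`hetgraph`) — metapath enumeration over a typed
   graph, meeting-in-the-middle HeteSim relevance
   `HeteSim(s,t|P) = cos(fwd_P(s), bwd_P(t))` with row-normalised
   transition probabilities, deterministic mean aggregation across
   metapaths, and score normalisation (z-scores and mid-rank percentiles).
2. **Ontology mapping** (`ontology`) — a closed 13-category mechanistic
   ontology (Metabolic, Immune/Inflammatory/Infectious, Cardiovascular,
   Other/Neuro-Psych, ...); provisional Neurological/Psychiatric labels
   merge into Other/Neuro-Psych.
3. **Intersections** (`intersections`) — a node shared by diseases d1, d2
   joins their intersection when the harmonic mean
   `HM = 2 / (1/H_d1 + 1/H_d2) ≥ 0.5` of its normalised scores; profiles
   report per-category counts, percentages and binomial Z-score enrichment
   `z = (k − n·p0) / √(n·p0·(1−p0))` against the pooled high-importance
   baseline, plus three-set Venn partitions.
4. **Hierarchies** (`hierarchies`) — category aggregates ranked 1..13 per
   entity; Spearman's ρ and Kendall's τ between entities; intersection–
   disease alignment and signed rank differences.
5. **Landscape** (`landscape`) — the 6-entity × 13-category priority
   landscape (priority = 15 − rank) and the Borda integrative ranking
   (order by rank sum; ties by lower median rank, then lower minimum rank).
6. **Synthetic data** (`synthetic`) — a generator that emulates the ranked
   tables with planted core categories and a planted disease-similarity
   ordering, so every stage is testable without downloads.
7. **Pipeline/CLI** (`pipeline`, `multimorbid` command) — seeded,
   deterministic staged execution with a digest manifest.

## Worked example

Borda aggregation of the published AD/ALS/FTD category rank matrix (shipped
as package data):

```python
import pandas as pd
import multimorbid as mm

t1 = mm.load_published_disease_ranks()
res = mm.borda_aggregate(t1[["AD", "ALS", "FTD"]])
print(pd.DataFrame({"AD": t1["AD"], "ALS": t1["ALS"], "FTD": t1["FTD"],
                    "rank_sum": res.rank_sum,
                    "integrative": res.integrative_rank}).head(6))
print(res.tie_trace)
```

prints

```
                                AD  ALS  FTD  rank_sum  integrative
Metabolic                        1    2    3         6            2
Immune/Inflammatory/Infectious   2    1    2         5            1
Cardiovascular                   3    9    4        16            3
Other/Neuro-Psych                7   13    1        21            7
Sensory (EET)                   11    3   13        27            9
Gastrointestinal                 4    8    5        17            4
("sum=17 ['Endocrine', 'Gastrointestinal']: resolved by median",)
```

The immune category wins the integrative ranking (lowest rank sum, 5),
metabolic dysfunction is second — the shared metabolic–immune core — and
the Gastrointestinal/Endocrine tie at rank sum 17 resolves in favour of GI
by its lower median rank (5 vs 6).  Other one-liners:

```python
>>> mm.harmonic_mean(0.4, 0.8)        # balanced-relevance statistic
0.5333333333333333
>>> mm.spearman_rho(t1["AD"], t1["FTD"])   # most similar disease pair
0.7802197802197801
```

A full synthetic run from the shell:

```bash
multimorbid --seed 1 --outdir out run-all
```

writes ranked tables, intersection member tables and summaries, the
baseline, hierarchies, similarity/alignment JSON, rank differences, the
priority landscape, the Borda ranking and a digest manifest; rerunning
with the same seed reproduces the bundle byte for byte.

## Layout

```
src/multimorbid/      hetgraph, ontology, intersections, hierarchies,
                      landscape, synthetic, pipeline, cli (+ packaged
                      disease-rank fixture under data/)
tests/                pytest suite with independent brute-force oracles
docs/methods.md       models, conventions, parameter choices, limitations
```
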