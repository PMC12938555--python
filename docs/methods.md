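# Methods

This note documents the models and conventions implemented in
`multimorbid`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and known limitations.

## HeteSim over typed graphs

A heterogeneous knowledge graph is a directed multigraph whose nodes are
typed concepts and whose edges carry predicates.  A metapath
`P = T0 -p1-> T1 ... -pL-> TL` is a typed path schema; relevance of a
source node `s : T0` to a target `t : TL` along `P` is the cosine of two
reachability distributions that meet in the middle:

* the forward distribution of `s` after the first `⌊L/2⌋` steps, and
* the backward distribution of `t` after the last `⌊L/2⌋` steps,

with transition probabilities uniform over the out-edges of each relation
(row-normalised 0/1 adjacency — no edge weights are assumed).  Paths of
odd edge length have no midpoint node layer; the middle edge is split by
treating each edge instance of the middle relation as an artificial
midpoint node, with mass `1/outdeg` forward and `1/indeg` backward.  This
preserves the symmetric meeting-in-the-middle semantics: reversing the
graph, the path and the node roles leaves the score unchanged (property
tested).  A dangling node contributes a zero distribution and scores 0;
that is data, not an error.

Conventions the source material leaves open, fixed here:

* **Metapath counting.**  "Length 3" is read as *at most* 3 edges and
  "search depth 2" as at most 2 intermediate nodes; both are arguments,
  not constants.
* **Direction.**  Metapath enumeration and traversal follow edge
  direction.  Graphs may declare schema relations explicitly (useful when
  a sparse sample leaves a known relation without instances); the
  effective schema is declared ∪ derived, and a metapath using a relation
  outside it is an error.
* **Aggregation.**  Per-node scores are the unweighted arithmetic mean
  over all enumerated metapaths (equal weighting, not instance-count
  weighting).  An empty score list aggregates to 0 with a warning.
* **Normalisation.**  Standardised scores use the population standard
  deviation of the table (zero-variance tables standardise to all zeros
  rather than erroring, so degenerate synthetic inputs flow through);
  percentiles are mid-rank/n, so ties share their average rank and the
  top score maps to exactly 1.0.

Downstream stages consume the **percentile** column by default
(`scores.use` switches hierarchies to the standardised score; harmonic-
mean intersections always use percentiles because the statistic is only
defined on the unit interval).

## Ontology

The 13 category labels form a closed set with a canonical order
(Metabolic first, Environmental Toxins last) used for reporting and for
every deterministic tie-break.  "Neurological" and "Psychiatric" are
provisional input labels merged into Other/Neuro-Psych (idempotent),
because in this disease family they are dominated by disease-defining
phenomena rather than independent comorbidity.  Mappings are curated
inputs (two-column TSV with optional `# alias old=new` headers); all
invalid rows — unknown labels, conflicting duplicates — are collected and
reported together.  The default policy for unmapped nodes is
drop-with-count, since the analysis concerns mapped high-importance
nodes; `error` and `bucket` (to Other/Neuro-Psych) are available.  The
PHSU channel reuses the same machinery with an open, user-declared
alphabet of broad mechanistic drug classes (anti-inflammatory,
antioxidant, neuromodulatory, cardiometabolic, antimicrobial,
toxin-related, other).

## Intersections and enrichment

A shared node joins a pairwise intersection when the harmonic mean of its
two percentile scores is ≥ the threshold (default 0.5, **inclusive**).
The harmonic mean is 0 when either input is 0 and never exceeds the
arithmetic mean, penalising one-sided relevance.  "High-importance" nodes
are the top fraction `q` of a table by percentile (default q = 0.10,
ceil(q·n) rows, ties broken by node id) — the source material uses the
phrase without a cutoff, so the fraction is configurable.

The enrichment baseline is the category distribution of the pooled
high-importance nodes of all three diseases.  Pooling defaults to
**union** (a shared node counts once); `concat` counts per-disease
occurrences, since the pooling convention is not otherwise determined.
Enrichment is the one-sample binomial proportion Z — the standard choice
when only a name ("Z-score enrichment") is given — with a seeded
permutation alternative (multinomial resampling of n nodes from the
baseline, default 10,000 draws) for sensitivity; the two agree in sign
wherever an integer count is meaningfully away from its expectation.
Degenerate baseline cells (p0 = 0 with k > 0, or p0 = 1 with k < n)
yield signed-infinity sentinels with a warning; consistent degenerate
cells yield 0.  Empty intersections carry no percentages or Z values —
they are reported as empty, not as numbers.

## Hierarchies and comparison

Disease hierarchies aggregate normalised scores per category — default
**sum**, which reflects both node count and strength; `mean` and `count`
are provided.  Intersection hierarchies default to member **count**
(equivalent to ranking by within-intersection percentage).  Ranks 1..13
are forced to a strict permutation with canonical-order tie-breaking;
correlations nonetheless use tie-aware forms (Spearman as
Pearson-of-ranks, Kendall τ-b, both via scipy) so externally supplied
tied rank vectors are handled.  Zero-variance rank vectors return NaN
with a warning rather than a fabricated coefficient.  Rank differences
are disease rank minus intersection rank; with two full permutations
they sum to zero, and negative values mark categories prioritised more
inside the disease than in shared space.

Near-zero Spearman and Kendall coefficients on the same pair can differ
in sign; sign agreement is only a meaningful invariant for coefficients
bounded away from zero, and the tests treat it that way.

## Landscape and Borda

Priority = 15 − rank maps ranks 1..13 onto {14..2}; each entity's row of
the landscape is a permutation of {2..14} summing to 104.  No ordinal
averaging across entities is ever performed.  The Borda integrative
ranking orders categories by ascending sum of the three disease ranks,
breaking ties by lower median rank, then lower minimum rank.  Those
rules are not total — three categories can share sum, median and
minimum — so a residual tie falls back to canonical category order and
is flagged in the tie trace.  Applied to the packaged published
disease-rank matrix, the procedure reproduces the published integrative
column exactly, including the Gastrointestinal/Endocrine tie at rank
sum 17 resolved by median (5 vs 6).

## Synthetic generator

The generator emulates what the analysis assumes about real exports:
unit-interval scores, category-structured node populations, and partial
cross-disease overlap with correlated scores.

* **Profiles.**  Default per-disease category weights are `14 − rank`
  from the packaged disease-rank matrix.  This simultaneously plants the
  qualitative similarity ordering AD–FTD > AD–ALS > ALS–FTD (Spearman
  between the implied profiles: 0.78 / 0.30 / −0.01) without asserting
  any unpublished coefficient values.
* **Sharing.**  Each of a disease's n node slots is shared with
  probability `overlap_fraction` (default 0.3) and filled without
  replacement from a common pool of size n; other slots are exclusive.
  Expected pairwise Jaccard is `f²/(2−f²)` (≈ 0.047 at f = 0.3), which
  the tests verify empirically.
* **Planted core.**  The pool's category distribution is the mean of the
  disease profiles with the two core categories (Metabolic,
  Immune/Inflammatory/Infectious) multiplied by `shared_core_boost`
  (default 5), so intersections are enriched for the core.
* **Scores.**  Beta(μκ, (1−μ)κ) with κ = 8 and μ interpolating 0.30–0.75
  with the category's profile weight — bounded like normalised scores,
  flexible skew, and irrelevant in distributional detail because
  downstream consumes percentiles.  Shared nodes get a Gaussian-copula
  shared latent factor (ρ = 0.8), giving correlated but imperfect
  cross-disease relevance, which is what makes HM intersections
  non-trivial.
* **Scale.**  Default 2000 nodes per disease; the recovery suite runs
  100 seeded replicates of the full pipeline and reports how often both
  planted core categories rank top-3 in every pairwise intersection and
  how often the planted similarity ordering is recovered, plus the
  label-permutation chance rate for the top-3 event.

What it does **not** emulate: literature bias, vocabulary realism, node
counts of any real export, temporal structure, or the real knowledge
graph itself.  Passing recovery tests show the pipeline's statistics
recover structure of this planted kind at this scale; they say nothing
about the fidelity of any particular literature-derived dataset.

## Pipeline determinism

One global seed expands into per-stage substreams
(`SeedSequence((seed, stage_index))`, kept below 2³¹), so a stage run in
isolation matches its in-pipeline output.  All artifacts are written
with fixed float formatting and sorted JSON keys, and no timestamps are
recorded anywhere in the bundle, so reruns with the same config and
seed are byte-identical; the manifest stores the config hash, seed,
stage list and per-file SHA-256 digests.  CLI exit codes: 0 success,
2 config error, 3 data error, 4 internal invariant violation.

## Limitations

* HeteSim here is the exact dense construction; it is meant for the toy
  and validation graphs this package targets, not for million-node
  literature graphs (no sparse or randomised approximation).
* The ontology mapping is an input; nothing here reproduces any
  particular curated assignment, and fixtures use synthetic mappings.
* Enrichment Z values are descriptive; no multiplicity-corrected
  significance claims are made (n = 13 categories, correlated counts).
* Rank correlations at n = 13 are volatile; the pipeline reports
  coefficients without p-values.
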