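# Methods

## Evidence model and scoring

Every disease–gene association is backed by one or more evidence items,
each a (source, annotation class, optional publication) triple. The raw
D-G score is a weighted sum over evidence items of
`source_weight(source) × base_score(source, class)`; source weights default
to 1.0 and every evidence item of a source counts (a `max`-per-source mode
is available for deduplicating redundant source exports). The default base
scores live in a versioned YAML shipped with the package
(`malanet/data/score_table.yaml`): 500/400/350/300/100/50 for the curated
classes, and a uniform 25 for the three data/text-mining sources
(GeneCards, DISEASE, Novoseek), placing any single mining assertion far
below curated grade.

**Normalization.** The class scores (25–500) and the elite threshold (2.5)
live on different scales; we bridge them with `dg = log10(1 + dg_raw)`.
This choice makes exactly the high-curation classes (raw ≥ ~316, i.e. the
OMIM/ClinVar/Orphanet top classes) clear the 2.5 bar on a single evidence
item, while GeneTests (100 → 2.004) and weaker OMIM classes (50 → 1.708)
do not — consistent with elite status arising only from strong curated
evidence. Other monotone bridges are possible; this one is simple,
invertible and keeps the additive structure interpretable (each order of
magnitude of raw evidence adds one unit of dg).

**Elite status** requires both `dg > 2.5` (strict inequality) and at least
one evidence item from an elite source. We default the elite sources to
{OMIM, Orphanet, ClinVar}: all three are manually curated, and with this
default the set of elite-capable lone annotations coincides exactly with
the three top-scoring curated classes. Humsavar, though curated, scores
300 → dg 2.479 < 2.5, so a lone Humsavar annotation is never elite.

**G-D** is `dg` plus an additive bonus (default 1.0) for elite edges. An
additive bonus on the normalized scale preserves ranking within the elite
and non-elite blocks separately and guarantees `gd ≥ dg`; a multiplicative
bonus would distort low-dg elite edges less than high ones for no evident
reason.

## Promiscuity filtering

1. **Publication filter.** A publication attached to more than 5 distinct
   disease–gene pairs (strictly more; exactly 5 is kept) has all of its
   evidence items removed — large-scale screens contribute noisy
   associations. Evidence without a publication id is never touched;
   associations left with no evidence are dropped. This filter is
   idempotent.

2. **Per-disease truncation.** For a disease with Nt genes, Ne of them
   elite, only the top `Nm = round(√(Ne′·Nt))` genes are retained
   (`Ne′ = clamp(Ne, 1, Nt)`), the geometric mean interpolating half-way
   between Ne and Nt on the log10 scale. Rounding is half-away-from-zero
   and the result is clamped into `[Ne′, Nt]`. Retention ranks elite
   edges first, then descending dg, then ascending gene symbol — so all
   elite edges survive by construction. We clamp Ne below by 1 because
   the log form is undefined at 0; a disease with no elite genes thus
   interpolates from 1 and keeps `round(√Nt)` genes.

   A filtered edge table no longer records the original Nt, and
   `Nm(Nm, Ne) < Nm` whenever `Ne < Nm`, so naively re-running the
   truncation on its own output would shrink it again. The filter
   therefore accepts the original per-disease totals (returned in
   `FilterStats`); re-application with those totals is exactly the
   identity. The pipeline order is: publication filter → re-score →
   disease truncation.

## Network and projections

The bipartite network excludes isolated nodes and exists in three nested
tiers (all ⊇ filtered ⊇ elite). The disease projection links two diseases
through every shared gene, weighted by the raw shared-gene count
(Jaccard-style weights would conflate gene-list size with relatedness for
the heavy-tailed lists involved). Indirect disease relations are pairs at
distance exactly 2 in the projection: no shared gene, but a bridge disease
overlapping both. A symmetric gene–gene projection backs the prioritizer.

## Disease pathways and SuperPaths

A disease pathway is the disease's retained gene set viewed as a
bag-of-genes pathway (elite-only by default when used as clustering
input). SuperPath clustering is greedy agglomeration: each round merges
the cluster pair with maximal overlap coefficient `|A∩B| / min(|A|,|B|)`
computed on cluster *union* gene sets (bag-of-genes semantics), provided
it reaches the threshold (default 0.5); ties break by larger intersection,
then lexicographically smaller cluster-id pair; cluster id is the smallest
member id. Because the merge sequence is threshold-independent until the
stopping condition triggers, lowering the threshold only extends the same
merge sequence — hence the cluster count is monotone in the threshold.
Within a SuperPath, member pairs sharing no genes but bridged by a common
overlapping member are reported as indirect relations.

The pair-overlap statistic measures, for a disease pathway, the percentage
of its gene pairs co-occurring in at least one biological gene set, and
averages it over a seeded uniform sample of pathways in a size range
(15–20 by default, n = 92 by default, mirroring the published sampling
design). The spread is the population standard deviation — with n fixed by
design rather than sampled from a larger population, the uncorrected
spread describes the sample itself.

## Prioritization

Query terms are lowercased, deduplicated and matched without stemming
against disease main names and aliases; `substring` matching is the
default (phenotype words are usually fragments of disease names),
`exact_token` is available. Direct scores aggregate G-D over matched
diseases per candidate (`max` by default — the best single disease link is
the natural headline; `sum` rewards multi-disease support). Indirect
scores apply only to candidates with zero direct score: attenuation
(default 0.25) times the best direct score among genes sharing a context
(disease pathway, SuperPath or gene set). Implicating genes are drawn from
*all* genes connected to matched diseases, not only from the candidate
list — the implicating gene in a real case is typically not among the
patient's variant-harboring genes. Attenuation ≤ 1 guarantees an
indirect hit never outranks the direct evidence it derives from. Ranking:
direct block, indirect block, then unmatched candidates, lexicographic
tie-breaks.

## Synthetic knowledgebase generator

The generator emulates the statistical shape the pipeline assumes, at desk
scale, from a single integer seed:

- **Per-disease gene counts**: discrete power law `P(k) ∝ k^−2` truncated
  at 300 genes/disease (defaults: 1000 diseases × 5000 genes). The heavy
  tail emulates text-mining-inflated diseases; the exponent is a config
  knob.
- **Evidence mix**: every association gets 1–2 text-mining items with
  publication ids; with probability 0.1 (`elite_fraction`) it also gets
  one curated top-class item (no publication id). Since every curated
  class here scores ≥ 350, curated ⟺ elite, which the truth record
  exploits.
- **Promiscuous publications**: dedicated publication ids attached to 8
  distinct pairs each (above the removal threshold of 5); ordinary
  publication ids are drawn from a finite pool, so the truth record lists
  promiscuous publications by counting pairs per publication post hoc
  rather than assuming only the planted ones exceed the threshold.
- **Vocabulary**: unique main names with 2 aliases each, so alias-based
  queries resolve to a single disease.
- **Planted causal gene**: `direct` mode adds an OMIM top-class annotation
  linking the planted gene to its disease; `indirect` mode removes any
  direct link and instead wires planted gene and an implicating gene into
  a bridge disease's pathway, with the implicating gene elite-linked to
  the query disease — the guilt-by-association geometry.

What the generator does **not** emulate: real gene/disease nomenclature,
correlated evidence across sources, per-variant structure, disease-name
ambiguity across vocabularies, or the true size of curated databases.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under the assumed statistical shape, not performance on real
MalaCards-scale content, whose global statistics (e.g. retention
percentages) are database-version dependent.

## Problem sizes and numerical choices

The test suite exercises 50-seed batches of 1000-disease × 5000-gene
knowledgebases for filter properties and recovery experiments, 200 random
instances (≤ 50 nodes) for projection/overlap brute-force oracles, and the
full `1 ≤ Ne ≤ Nt ≤ 500` grid for the truncation formula — sizes chosen
so the whole suite completes in well under a minute of compute per batch
while keeping binomial/recovery margins far from their thresholds.
Floating-point comparisons in tests use absolute tolerances ≤ 1e-6; edge
TSV round-trips carry six decimals. Degenerate inputs are defined
explicitly: empty networks are valid and project to nothing, singleton
pathways raise on the pair statistic, an all-zero query yields an
all-`none` ranking, and `tier=elite` on an elite-free edge set is an empty
network with a warning rather than an error.

## Known limitations

- The log10 normalization and the additive elite bonus are reconstructions
  of unpublished normalizations; both are config knobs.
- The SuperPath clustering rule (overlap coefficient, greedy best-pair,
  threshold 0.5, recompute-on-unions) is a fully specified stand-in for a
  published-elsewhere clustering procedure; results depend on the
  threshold.
- Only OR queries are supported; no variant-level scoring; no disease-name
  unification across vocabularies.
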