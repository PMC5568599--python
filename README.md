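# malanet

Evidence-scored gene–disease networks and phenotype-driven candidate-gene
prioritization for NGS interpretation, with a seeded synthetic-knowledgebase
generator so every stage runs without any external database.

## Who this is for

Bioinformaticians interpreting exome/genome sequencing results (ranking
variant-harboring genes against a patient's phenotype terms) and systems
biologists studying the structure of gene–disease association networks
built from heterogeneous evidence sources (curated databases such as OMIM,
ClinVar and Orphanet alongside literature text mining).

## The model

The knowledgebase is a bipartite network of disease and gene nodes with one
edge type (disease–gene association), weighted and directional:

- **D-G** (gene importance for the disease): a weighted sum of per-evidence
  base scores. Curated annotation classes score high — OMIM *molecular
  basis known* 500, ClinVar *pathogenic mutation* 400, Orphanet *causative
  germ-line mutation* 350, Humsavar *causative variation* 300, GeneTests
  appearance 100 — while weaker classes (OMIM *role in phenotype* /
  *genetic linkage*, 50) and text-mining assertions (25) score low.
  The raw sum is normalized as `dg = log10(1 + dg_raw)`.
- **Elite edge**: `dg > 2.5` (strict) *and* at least one evidence item from
  a curated source. Exactly the three top curated classes clear the bar on
  their own.
- **G-D** (disease association strength from the gene's side):
  `gd = dg + 1.0·[elite]`.

Two promiscuity filters produce the trusted tier: publications attached to
more than 5 distinct disease–gene pairs are removed wholesale, and each
disease's gene list is truncated to its top

```
log10(Nm) = log10(Ne) + (log10(Nt) − log10(Ne)) / 2      (Nm = √(Ne·Nt))
```

genes, ranked elite-first then by descending D-G — so elite edges always
survive.

On top of the network: disease projections (diseases linked through shared
genes, including indirect distance-2 relations), *disease pathways* (a
disease's gene set treated as a bag-of-genes pathway), greedy
overlap-coefficient clustering of gene sets into *SuperPaths*, and a
VarElect-style prioritizer that ranks candidate genes against free-text
phenotype terms directly (via the disease vocabulary and G-D scores) or
indirectly (guilt by association through shared disease pathways,
SuperPaths or gene sets, attenuated by 0.25).

## Worked example

```python
from malanet import Association, EvidenceItem, ScoreTable, score_all

kb = [
    Association("gaucher_3", "GBA",   [EvidenceItem("OMIM", "molecular_basis_known")]),
    Association("gaucher_3", "CHIT1", [EvidenceItem("GeneTests", "appearance"),
                                       EvidenceItem("Novoseek", "text_mining", "PMID1")]),
]
for e in score_all(kb, ScoreTable.default()):
    print(e.disease_id, e.gene_symbol, e.dg_raw, round(e.dg, 3), round(e.gd, 3), e.elite)
```

prints

```
gaucher_3 GBA 500.0 2.7 3.7 True
gaucher_3 CHIT1 125.0 2.1 2.1 False
```

GBA's single curated annotation (raw 500) normalizes to 2.700 — above the
elite threshold, so its G-D score carries the +1.0 elite bonus. CHIT1's
mixed evidence (100 + 25 = 125) normalizes to 2.100 — a real association
but below elite grade. The scripts in `examples/` walk through each
capability (scoring + filtering, network projections, SuperPaths and the
pair-overlap statistic, prioritization with a planted causal gene) and
print annotated output; the `malanet` CLI exposes the same stages
(`simulate`, `score`, `filter`, `network`, `superpaths`, `prioritize`,
`report`, `pipeline`).

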