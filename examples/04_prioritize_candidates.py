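"""Phenotype-driven gene prioritization on a synthetic exome-style case.

Simulates a knowledgebase with a planted causal gene that has NO direct
annotation to the queried disease — it only shares a bridge disease's
pathway with an implicating gene.  A 10-gene candidate list queried with the
disease's alias terms must surface the planted gene through the indirect
("guilt by association") mode.
"""

import random

from malanet import (
    Context,
    PhenotypeQuery,
    PlantedGene,
    ScoreTable,
    SynthConfig,
    apply_filters,
    extract_disease_pathways,
    generate_kb,
    rank,
)

config = SynthConfig(n_genes=1000, n_diseases=200, seed=42,
                     planted=PlantedGene(5, 17, mode="indirect"))
kb, records, truth = generate_kb(config)
table = ScoreTable.default()
kept, _, _ = apply_filters(kb, table)
contexts = [Context.from_disease_pathway(p) for p in extract_disease_pathways(kept)]

rng = random.Random(1)
decoys = {f"SYG{rng.randrange(1000):05d}" for _ in range(12)} - {truth.planted_gene}
candidates = sorted(decoys | {truth.planted_gene})
query = PhenotypeQuery(tuple(truth.query_terms))

print(f"query terms: {' OR '.join(query.terms)}")
print(f"planted causal gene: {truth.planted_gene} "
      f"(no direct link; bridged via {truth.bridge_disease})\n")
print(f"{'rank':<5} {'gene':<9} {'score':>6}  mode      implicated via")
for i, r in enumerate(rank(candidates, query, records, kept, contexts), 1):
    via = ", ".join(f"{g}@{c}" for g, c, _ in r.implicating_genes[:2])
    print(f"{i:<5} {r.gene_symbol:<9} {r.score:>6.3f}  {r.mode:<9} {via}")
# The planted gene inherits 0.25 x the implicating gene's direct G-D score;
# decoys sharing no context with a direct hit score 0.
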