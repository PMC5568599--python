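# Default evidence score table, version 1.
#
# Base scores reflect the level of manual curation of each source and the
# significance the source assigns to its annotation classes.  The three
# data/text-mining sources (GeneCards, DISEASE, Novoseek) receive a low
# uniform score of 25, below every curated class.
version: 1
elite_threshold: 2.5        # strict: an edge is elite-eligible only if dg > 2.5
elite_bonus: 1.0            # added to gd for elite edges, on the normalized scale
pub_promiscuity_max: 5      # publications linked to more than this many pairs are dropped
per_source_mode: sum        # "sum" (all evidence items count) or "max" (best per source)
elite_sources:
  - OMIM
  - Orphanet
  - ClinVar
source_weights: {}          # sources absent here default to weight 1.0
base_scores:
  OMIM:
    molecular_basis_known: 500
    role_in_phenotype: 50
    genetic_linkage: 50
  ClinVar:
    pathogenic_mutation: 400
  Orphanet:
    causative_germline_mutation: 350
  Humsavar:
    causative_variation: 300
  GeneTests:
    appearance: 100
  GeneCards:
    text_mining: 25
  DISEASE:
    text_mining: 25
  Novoseek:
    text_mining: 25
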