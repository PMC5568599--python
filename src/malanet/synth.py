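"""Seeded synthetic knowledgebase generator.

Emulates the statistical structure the pipeline assumes, at desk scale:

* heavy-tailed per-disease gene counts (discrete power law, default exponent
  2, truncated at 300 genes per disease — some diseases accumulate large
  text-mined gene lists, most have a handful);
* a minority of associations carrying curated ("elite"-grade) evidence
  (OMIM / ClinVar / Orphanet top classes) against a majority of text-mined
  evidence with publication ids;
* promiscuous publications attached to many disease-gene pairs (size > 5 by
  default, so the publication filter removes them);
* unique disease names with aliases, so phenotype terms resolve to a single
  disease;
* an optional planted causal gene, either directly annotated to its disease
  (``direct`` mode) or stripped of direct annotation but sharing a bridge
  disease's pathway with an implicating gene (``indirect`` mode), for
  recovery experiments.

Every random draw flows from one integer seed; identical configs produce
byte-identical output files.  The truth record lists everything a recovery
test needs: the planted edge, all promiscuous publication ids, per-disease
elite counts, and the query terms of the planted disease.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .kb import Association, DiseaseRecord, EvidenceItem, GeneSet

CURATED_EVIDENCE = [
    ("OMIM", "molecular_basis_known"),
    ("ClinVar", "pathogenic_mutation"),
    ("Orphanet", "causative_germline_mutation"),
]
MINING_SOURCES = ["GeneCards", "DISEASE", "Novoseek"]


@dataclass
class PlantedGene:
    disease_index: int
    gene_index: int
    mode: str = "direct"  # direct | indirect


@dataclass
class SynthConfig:
    n_genes: int = 5000
    n_diseases: int = 1000
    seed: int = 0
    degree_exponent: float = 2.0
    max_genes: int = 300
    elite_fraction: float = 0.1
    pub_count: int = 400
    promiscuous_pub_fraction: float = 0.02
    promiscuous_pub_size: int = 8
    alias_per_disease: int = 2
    text_evidence_max: int = 2
    planted: Optional[PlantedGene] = None

    def __post_init__(self) -> None:
        for name in ("elite_fraction", "promiscuous_pub_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.max_genes < 1:
            raise ConfigError("max_genes must be >= 1")
        # per-disease degree cannot exceed the gene pool
        self.max_genes = min(self.max_genes, self.n_genes)
        if self.planted is not None:
            if not (0 <= self.planted.disease_index < self.n_diseases):
                raise ConfigError("planted disease index out of range")
            if not (0 <= self.planted.gene_index < self.n_genes):
                raise ConfigError("planted gene index out of range")
            if self.planted.mode not in ("direct", "indirect"):
                raise ConfigError(f"unknown planted mode {self.planted.mode!r}")


@dataclass
class TruthRecord:
    promiscuous_pubs: list[str]
    elite_pairs: set[tuple[str, str]]
    elite_per_disease: dict[str, int]
    planted_disease: Optional[str] = None
    planted_gene: Optional[str] = None
    planted_mode: Optional[str] = None
    bridge_disease: Optional[str] = None
    implicating_gene: Optional[str] = None
    query_terms: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "promiscuous_pubs": self.promiscuous_pubs,
            "elite_pairs": sorted(list(p) for p in self.elite_pairs),
            "elite_per_disease": self.elite_per_disease,
            "planted_disease": self.planted_disease,
            "planted_gene": self.planted_gene,
            "planted_mode": self.planted_mode,
            "bridge_disease": self.bridge_disease,
            "implicating_gene": self.implicating_gene,
            "query_terms": self.query_terms,
        }


def _gene_symbol(i: int) -> str:
    return f"SYG{i:05d}"


def _disease_id(i: int) -> str:
    return f"SMD{i:04d}"


def _power_law_degrees(rng: np.random.Generator, n: int, exponent: float, kmax: int) -> np.ndarray:
    ks = np.arange(1, kmax + 1, dtype=float)
    p = ks ** (-exponent)
    p /= p.sum()
    return rng.choice(np.arange(1, kmax + 1), size=n, p=p)


def generate_kb(
    config: SynthConfig,
) -> tuple[list[Association], list[DiseaseRecord], TruthRecord]:
    """Generate (associations, disease records, truth record) from one seed."""
    rng = np.random.default_rng(config.seed)

    # disease vocabulary with unique, queryable names
    records = []
    for i in range(config.n_diseases):
        aliases = [
            f"synthetic disease {i:04d} variant {j}"
            for j in range(config.alias_per_disease)
        ]
        records.append(DiseaseRecord(_disease_id(i), f"synthetic disease {i:04d}", aliases))

    degrees = _power_law_degrees(
        rng, config.n_diseases, config.degree_exponent, config.max_genes
    )

    # evidence assembly per (disease, gene) pair
    evidence: dict[tuple[str, str], list[EvidenceItem]] = defaultdict(list)
    elite_pairs: set[tuple[str, str]] = set()
    for i in range(config.n_diseases):
        did = _disease_id(i)
        gene_idx = rng.choice(config.n_genes, size=int(degrees[i]), replace=False)
        for gi in sorted(gene_idx):
            pair = (did, _gene_symbol(int(gi)))
            n_text = 1 + int(rng.integers(0, config.text_evidence_max))
            for _ in range(n_text):
                src = MINING_SOURCES[int(rng.integers(0, len(MINING_SOURCES)))]
                pub = f"PMID{int(rng.integers(0, config.pub_count)):06d}"
                evidence[pair].append(EvidenceItem(src, "text_mining", pub))
            if rng.random() < config.elite_fraction:
                src, ann = CURATED_EVIDENCE[int(rng.integers(0, len(CURATED_EVIDENCE)))]
                evidence[pair].append(EvidenceItem(src, ann))
                elite_pairs.add(pair)

    # promiscuous publications: attach a dedicated pub to many distinct pairs
    n_promiscuous = int(round(config.promiscuous_pub_fraction * config.pub_count))
    pairs = sorted(evidence)
    planted_pubs = []
    for k in range(n_promiscuous):
        if config.promiscuous_pub_size > len(pairs):
            break
        pub = f"PROMPUB{k:04d}"
        chosen = rng.choice(len(pairs), size=config.promiscuous_pub_size, replace=False)
        for idx in sorted(chosen):
            evidence[pairs[int(idx)]].append(EvidenceItem("Novoseek", "text_mining", pub))
        planted_pubs.append(pub)

    truth = TruthRecord(promiscuous_pubs=[], elite_pairs=elite_pairs,
                        elite_per_disease={})

    # planted causal gene
    if config.planted is not None:
        p = config.planted
        did = _disease_id(p.disease_index)
        gene = _gene_symbol(p.gene_index)
        truth.planted_disease = did
        truth.planted_gene = gene
        truth.planted_mode = p.mode
        truth.query_terms = list(records[p.disease_index].aliases)
        if p.mode == "direct":
            evidence[(did, gene)].append(EvidenceItem("OMIM", "molecular_basis_known"))
            elite_pairs.add((did, gene))
        else:
            # strip any direct link to the planted disease; connect via a bridge
            evidence.pop((did, gene), None)
            elite_pairs.discard((did, gene))
            bridge_i = (p.disease_index + 1) % config.n_diseases
            bridge = _disease_id(bridge_i)
            implicating_i = (p.gene_index + 1) % config.n_genes
            implicating = _gene_symbol(implicating_i)
            for pair in [(bridge, gene), (bridge, implicating), (did, implicating)]:
                src, ann = CURATED_EVIDENCE[0]
                ev = EvidenceItem(src, ann)
                if ev not in evidence[pair]:
                    evidence[pair].append(ev)
                elite_pairs.add(pair)
            truth.bridge_disease = bridge
            truth.implicating_gene = implicating

    associations = [
        Association(d, g, evs) for (d, g), evs in sorted(evidence.items())
    ]

    # promiscuous pubs recorded post hoc, from the generated data itself
    pairs_per_pub: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for a in associations:
        for ev in a.evidence:
            if ev.publication_id is not None:
                pairs_per_pub[ev.publication_id].add(a.pair)
    truth.promiscuous_pubs = sorted(
        pub for pub, ps in pairs_per_pub.items() if len(ps) > 5
    )
    per_disease: dict[str, int] = defaultdict(int)
    for d, _ in elite_pairs:
        per_disease[d] += 1
    truth.elite_pairs = elite_pairs
    truth.elite_per_disease = dict(sorted(per_disease.items()))
    return associations, records, truth


def generate_gene_sets(
    pathways: Sequence, co_membership_rate: float, seed: int = 0
) -> list[GeneSet]:
    """Gene sets planting a target within-pathway pair co-membership rate.

    For every unordered gene pair of every pathway, an independent coin with
    probability ``co_membership_rate`` decides whether a fresh two-gene set
    containing the pair is emitted, so the expected fraction of pathway gene
    pairs sharing a set is exactly the rate (when pathways are gene-disjoint).
    """
    if not (0 <= co_membership_rate <= 1):
        raise ConfigError(f"co_membership_rate must be in [0, 1], got {co_membership_rate}")
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    k = 0
    for p in sorted(pathways, key=lambda p: p.disease_id):
        genes = sorted(p.genes)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < co_membership_rate:
                    sets.append(GeneSet(
                        set_id=f"SET{k:06d}",
                        name=f"synthetic pair set {k}",
                        genes=frozenset({genes[i], genes[j]}),
                    ))
                    k += 1
    return sets


def generate_overlap_fixture(
    n_pathways: int = 92,
    size_range: tuple[int, int] = (15, 20),
    co_membership_rate: float = 0.1,
    seed: int = 0,
):
    """Gene-disjoint disease pathways plus gene sets with a planted overlap rate.

    Mirrors the sampling design of the pair-overlap analysis: ``n_pathways``
    pathways sized within ``size_range``, with gene sets constructed so each
    within-pathway pair co-occurs in a set with the given probability.
    """
    from .pathways import DiseasePathway

    rng = np.random.default_rng(seed)
    pathways = []
    gene_counter = 0
    lo, hi = size_range
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        genes = frozenset(_gene_symbol(gene_counter + j) for j in range(size))
        gene_counter += size
        pathways.append(DiseasePathway(_disease_id(i), genes))
    sets = generate_gene_sets(pathways, co_membership_rate, seed=seed + 1)
    return pathways, sets
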