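"""Phenotype-driven candidate-gene prioritization (direct and indirect modes).

Given a candidate gene list (typically variant-harboring genes from an NGS
experiment) and free-text phenotype/disease terms combined with OR:

* **Direct mode** matches each term, case-insensitively and without
  stemming, against disease main names and aliases, then scores each
  candidate by aggregating the G-D scores of its edges to matched diseases
  (``max`` by default, ``sum`` optionally).

* **Indirect ("guilt by association") mode** rescues candidates with no
  direct evidence: a candidate sharing a context — a disease pathway, a
  disease SuperPath, or a biological gene set — with a directly matched gene
  inherits that gene's direct score attenuated by a configurable factor
  (default 0.25, always <= 1 so an indirect hit never outranks the direct
  hit it derives from).  The implicating genes and the shared context are
  reported alongside the score.

The ranking lists direct hits first (descending score), then indirect hits,
then unmatched candidates, with lexicographic tie-breaks throughout.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import MalanetError, ValidationError
from .kb import DiseaseRecord, GeneSet
from .pathways import DiseasePathway, SuperPath
from .scoring import ScoredEdge


@dataclass(frozen=True)
class PhenotypeQuery:
    """Free-text terms combined with OR; lowercased, trimmed, deduplicated."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        cleaned = []
        seen = set()
        for t in self.terms:
            t = t.strip().lower()
            if t and t not in seen:
                seen.add(t)
                cleaned.append(t)
        if not cleaned:
            raise ValidationError("phenotype query has no usable terms")
        object.__setattr__(self, "terms", tuple(cleaned))

    @classmethod
    def parse(cls, text: str) -> "PhenotypeQuery":
        """Parse a query string of the form ``term1 OR term2 OR ...``."""
        return cls(tuple(part for part in text.split(" OR ")))


@dataclass(frozen=True)
class DiseaseMatch:
    disease_id: str
    term: str
    via: str  # main_name | alias


@dataclass(frozen=True)
class Context:
    """A gene grouping through which indirect evidence propagates."""

    context_id: str
    kind: str  # disease_pathway | superpath | gene_set
    genes: frozenset[str]

    @classmethod
    def from_disease_pathway(cls, p: DiseasePathway) -> "Context":
        return cls(p.disease_id, "disease_pathway", p.genes)

    @classmethod
    def from_superpath(cls, sp: SuperPath) -> "Context":
        return cls(sp.superpath_id, "superpath", sp.union_genes)

    @classmethod
    def from_gene_set(cls, s: GeneSet) -> "Context":
        return cls(s.set_id, "gene_set", s.genes)


@dataclass
class PrioritizerConfig:
    attenuation: float = 0.25     # multiplier on scores propagated through implicating genes
    match_mode: str = "substring"  # substring | exact_token
    aggregation: str = "max"       # max | sum

    def __post_init__(self) -> None:
        if not (0 < self.attenuation <= 1):
            raise ValidationError(f"attenuation must be in (0, 1], got {self.attenuation}")
        if self.match_mode not in ("substring", "exact_token"):
            raise ValidationError(f"unknown match_mode {self.match_mode!r}")
        if self.aggregation not in ("max", "sum"):
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class RankedGene:
    gene_symbol: str
    score: float
    mode: str  # direct | indirect | none
    matched_diseases: list[tuple[str, str, str]] = field(default_factory=list)
    implicating_genes: list[tuple[str, str, str]] = field(default_factory=list)


def match_diseases(
    query: PhenotypeQuery,
    records: Sequence[DiseaseRecord],
    match_mode: str = "substring",
) -> list[DiseaseMatch]:
    """Match each query term against disease main names and aliases.

    Case-insensitive and non-stemmed; ``substring`` mode matches a term
    contained anywhere in a name, ``exact_token`` requires the term to equal
    the whole name or one of its whitespace tokens.  OR semantics: any term
    suffices; all (disease, term, via) matches are reported.
    """
    matches: list[DiseaseMatch] = []
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        for name, via in rec.all_names():
            lowered = name.lower()
            tokens = set(lowered.split()) if match_mode == "exact_token" else None
            for term in query.terms:
                hit = (
                    term in lowered
                    if match_mode == "substring"
                    else (term == lowered or term in tokens)
                )
                if hit and (rec.disease_id, term, via) not in seen:
                    seen.add((rec.disease_id, term, via))
                    matches.append(DiseaseMatch(rec.disease_id, term, via))
    return matches


def direct_scores(
    candidates: Sequence[str],
    matches: Sequence[DiseaseMatch],
    edges: Sequence[ScoredEdge],
    config: Optional[PrioritizerConfig] = None,
) -> dict[str, tuple[float, list[tuple[str, str, str]]]]:
    """Aggregate G-D over matched diseases connected to each candidate.

    Returns gene -> (score, provenance) with provenance rows of
    (disease_id, matched term, via).  Unconnected candidates score 0.
    """
    config = config or PrioritizerConfig()
    candidates = [c.upper() for c in candidates]
    matched_ids = {m.disease_id for m in matches}
    match_info: dict[str, list[DiseaseMatch]] = defaultdict(list)
    for m in matches:
        match_info[m.disease_id].append(m)

    gd_by_gene: dict[str, dict[str, float]] = defaultdict(dict)
    for e in edges:
        if e.disease_id in matched_ids:
            prev = gd_by_gene[e.gene_symbol].get(e.disease_id)
            if prev is None or e.gd > prev:
                gd_by_gene[e.gene_symbol][e.disease_id] = e.gd

    out: dict[str, tuple[float, list[tuple[str, str, str]]]] = {}
    for gene in candidates:
        per_disease = gd_by_gene.get(gene, {})
        if not per_disease:
            out[gene] = (0.0, [])
            continue
        values = per_disease.values()
        score = max(values) if config.aggregation == "max" else sum(values)
        provenance = [
            (d, m.term, m.via)
            for d in sorted(per_disease)
            for m in match_info[d]
        ]
        out[gene] = (score, provenance)
    return out


def indirect_scores(
    candidates: Sequence[str],
    direct: Mapping[str, tuple[float, list]],
    contexts: Sequence[Context],
    config: Optional[PrioritizerConfig] = None,
) -> dict[str, tuple[float, list[tuple[str, str, str]]]]:
    """Attenuated propagation from direct hits through shared contexts.

    Only candidates with direct score 0 are considered; each inherits
    ``attenuation x max(direct score of genes sharing a context)``.  Returns
    gene -> (score, implicating genes) with rows (gene, context id, kind).
    """
    config = config or PrioritizerConfig()
    candidates = [c.upper() for c in candidates]
    direct_hits = {g: s for g, (s, _) in direct.items() if s > 0}

    contexts_by_gene: dict[str, list[Context]] = defaultdict(list)
    for ctx in contexts:
        for g in ctx.genes:
            contexts_by_gene[g].append(ctx)

    out: dict[str, tuple[float, list[tuple[str, str, str]]]] = {}
    for gene in candidates:
        if direct.get(gene, (0.0, []))[0] > 0:
            continue
        best = 0.0
        implicating: list[tuple[str, str, str]] = []
        for ctx in contexts_by_gene.get(gene, []):
            for other, score in direct_hits.items():
                if other != gene and other in ctx.genes:
                    implicating.append((other, ctx.context_id, ctx.kind))
                    if score > best:
                        best = score
        if best > 0:
            out[gene] = (config.attenuation * best, sorted(set(implicating)))
        else:
            out[gene] = (0.0, [])
    return out


def rank(
    candidates: Sequence[str],
    query: PhenotypeQuery,
    records: Sequence[DiseaseRecord],
    edges: Sequence[ScoredEdge],
    contexts: Sequence[Context] = (),
    config: Optional[PrioritizerConfig] = None,
) -> list[RankedGene]:
    """Full prioritization: direct hits first, then indirect, then unmatched.

    Candidate symbols absent from the knowledgebase are retained with
    mode='none'.  Output is deterministic: descending score within each mode
    block, ties broken lexicographically.
    """
    config = config or PrioritizerConfig()
    candidates = sorted({c.upper() for c in candidates})
    if not candidates:
        raise ValidationError("candidate gene list is empty")
    matches = match_diseases(query, records, config.match_mode)
    direct = direct_scores(candidates, matches, edges, config)
    # implicating genes need not be candidates: propagate from the direct
    # scores of every gene connected to a matched disease
    matched_ids = {m.disease_id for m in matches}
    connected = {e.gene_symbol for e in edges if e.disease_id in matched_ids}
    direct_all = direct_scores(sorted(set(candidates) | connected), matches, edges, config)
    indirect = indirect_scores(candidates, direct_all, contexts, config)

    ranked: list[RankedGene] = []
    for gene in candidates:
        d_score, provenance = direct[gene]
        if d_score > 0:
            ranked.append(RankedGene(gene, d_score, "direct", matched_diseases=provenance))
            continue
        i_score, implicating = indirect.get(gene, (0.0, []))
        if i_score > 0:
            ranked.append(RankedGene(gene, i_score, "indirect", implicating_genes=implicating))
        else:
            ranked.append(RankedGene(gene, 0.0, "none"))

    mode_order = {"direct": 0, "indirect": 1, "none": 2}
    ranked.sort(key=lambda r: (mode_order[r.mode], -r.score, r.gene_symbol))
    return ranked
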