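"""Directional scoring of disease-gene associations.

Two scores are attached to every edge of the bipartite network:

* **D-G** — the importance of the gene for the disease.  The raw D-G score is
  a weighted sum of per-evidence base scores (curated annotation classes
  score 50-500, text-mining classes much lower); it is then normalized as
  ``dg = log10(1 + dg_raw)`` so that the high-curation classes (raw >= ~316)
  clear the elite threshold of 2.5 while lower-evidence edges do not.
* **G-D** — the association strength of the disease from the gene's
  perspective: the normalized D-G plus an additive bonus for elite edges.

An edge is *elite* when its normalized D-G strictly exceeds the threshold
(default 2.5) AND at least one evidence item comes from a manually curated
source (OMIM, Orphanet, ClinVar by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DomainError
from .kb import Association, EvidenceItem, ScoreTable


@dataclass(frozen=True)
class ScoredEdge:
    """A disease-gene edge with raw and normalized D-G, G-D and elite flag."""

    disease_id: str
    gene_symbol: str
    dg_raw: float
    dg: float
    gd: float
    elite: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.disease_id, self.gene_symbol)


def score_dg_raw(assoc: Association, table: ScoreTable) -> float:
    """Weighted sum of evidence base scores for one association.

    With ``per_source_mode='max'`` only the best-scoring evidence item per
    source counts; the default ``'sum'`` counts every item.  Deterministic and
    invariant under evidence permutation.
    """
    contributions: dict[str, float] = {}
    total = 0.0
    for ev in assoc.evidence:
        value = table.weight(ev.source) * table.base_score(ev.source, ev.annotation_class)
        if table.per_source_mode == "max":
            contributions[ev.source] = max(contributions.get(ev.source, 0.0), value)
        else:
            total += value
    if table.per_source_mode == "max":
        total = sum(contributions.values())
    return total


def normalize_dg(dg_raw: float) -> float:
    """Bridge the 50-500 base-score scale to the elite threshold: log10(1 + raw)."""
    if dg_raw < 0:
        raise DomainError(f"dg_raw must be non-negative, got {dg_raw}")
    return math.log10(1.0 + dg_raw)


def is_elite(dg: float, evidence: Sequence[EvidenceItem], table: ScoreTable) -> bool:
    """Elite iff dg strictly exceeds the threshold and a curated source attests.

    The inequality is strict: dg == threshold is not elite.
    """
    if dg <= table.elite_threshold:
        return False
    return any(ev.source in table.elite_sources for ev in evidence)


def score_gd(dg: float, elite: bool, table: ScoreTable) -> float:
    """G-D score: normalized D-G plus an additive bonus for elite edges."""
    return dg + (table.elite_bonus if elite else 0.0)


def score_edge(assoc: Association, table: ScoreTable) -> ScoredEdge:
    dg_raw = score_dg_raw(assoc, table)
    dg = normalize_dg(dg_raw)
    elite = is_elite(dg, assoc.evidence, table)
    return ScoredEdge(
        disease_id=assoc.disease_id,
        gene_symbol=assoc.gene_symbol,
        dg_raw=dg_raw,
        dg=dg,
        gd=score_gd(dg, elite, table),
        elite=elite,
    )


def score_all(kb: Iterable[Association], table: ScoreTable) -> list[ScoredEdge]:
    """Score every association; output ordered by (disease_id, -dg, gene_symbol)."""
    edges = [score_edge(a, table) for a in kb]
    edges.sort(key=lambda e: (e.disease_id, -e.dg, e.gene_symbol))
    return edges
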