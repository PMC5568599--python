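"""Promiscuity filters producing the trusted tier of the gene-disease network.

Two heuristics reduce spurious associations:

1. **Publication filter** — a publication attached to more than
   ``pub_promiscuity_max`` (default 5) distinct disease-gene pairs is
   considered promiscuous (typically a large-scale screen) and all of its
   evidence items are removed.  Evidence without a publication id is never
   touched; associations left without evidence are dropped.

2. **Per-disease truncation** — for each disease with Nt genes of which Ne
   are elite, only the top Nm genes are retained, where Nm interpolates
   half-way between Ne and Nt on a log10 scale:

       log10(Nm) = log10(Ne) + (log10(Nt) - log10(Ne)) / 2

   i.e. Nm is the geometric mean sqrt(Ne * Nt), rounded.  Retention ranks
   elite edges first, then by descending normalized D-G, then by gene symbol,
   so every elite edge survives (Nm >= Ne by construction).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import DomainError
from .kb import Association, ScoreTable
from .scoring import ScoredEdge, score_all


@dataclass
class FilterStats:
    """Per-disease filtering bookkeeping: Nt total, Ne elite, Nm retained."""

    disease_id: str
    Nt: int
    Ne: int
    Nm: int
    removed_publications: list[str] = field(default_factory=list)
    associations_before: int = 0
    associations_after: int = 0


def publication_filter(
    kb: Sequence[Association],
    max_per_pub: Optional[int] = None,
    table: Optional[ScoreTable] = None,
) -> tuple[list[Association], list[str]]:
    """Drop all evidence from publications linked to > max_per_pub pairs.

    Returns the filtered knowledgebase and the sorted list of removed
    publication ids.  A publication attached to exactly ``max_per_pub`` pairs
    is kept (the threshold is "more than").  Idempotent.
    """
    if max_per_pub is None:
        max_per_pub = table.pub_promiscuity_max if table is not None else 5
    if max_per_pub < 1:
        raise DomainError(f"max_per_pub must be >= 1, got {max_per_pub}")

    pairs_per_pub: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for assoc in kb:
        for ev in assoc.evidence:
            if ev.publication_id is not None:
                pairs_per_pub[ev.publication_id].add(assoc.pair)
    promiscuous = {p for p, pairs in pairs_per_pub.items() if len(pairs) > max_per_pub}

    kept: list[Association] = []
    for assoc in kb:
        evidence = [ev for ev in assoc.evidence if ev.publication_id not in promiscuous]
        if evidence:
            kept.append(Association(assoc.disease_id, assoc.gene_symbol, evidence))
    return kept, sorted(promiscuous)


def compute_nm(Nt: int, Ne: int) -> int:
    """Number of genes retained for a disease: round(sqrt(Ne' * Nt)).

    Ne is clamped to [1, Nt] before evaluation (a disease with no elite genes
    interpolates from 1).  Equivalent to evaluating the log10 interpolation
    formula directly; rounding is half-away-from-zero, and the result is
    clamped back into [Ne', Nt].
    """
    if Nt < 1:
        raise DomainError(f"Nt must be >= 1, got {Nt}")
    ne = min(max(Ne, 1), Nt)
    nm = math.floor(math.sqrt(ne * Nt) + 0.5)
    return min(max(nm, ne), Nt)


def disease_promiscuity_filter(
    edges: Sequence[ScoredEdge],
    totals: Optional[dict[str, int]] = None,
) -> tuple[list[ScoredEdge], list[FilterStats]]:
    """Retain the top-Nm edges per disease, elite edges always included.

    Ranking within a disease: elite edges first, then descending dg, ties
    broken by ascending gene symbol.  Because Nm >= Ne and elites sort first,
    no elite edge is ever removed.

    ``totals`` optionally supplies the original (pre-filter) gene count Nt
    per disease; a filtered edge table no longer records those totals, so
    re-applying the filter to its own output with the Nt values from the
    first pass (available in the returned :class:`FilterStats`) is exactly
    the identity.  Without ``totals``, Nt defaults to the group size in
    ``edges``.
    """
    by_disease: dict[str, list[ScoredEdge]] = defaultdict(list)
    for e in edges:
        by_disease[e.disease_id].append(e)

    kept: list[ScoredEdge] = []
    stats: list[FilterStats] = []
    for disease_id in sorted(by_disease):
        group = sorted(
            by_disease[disease_id],
            key=lambda e: (not e.elite, -e.dg, e.gene_symbol),
        )
        nt = len(group)
        if totals is not None:
            nt = max(totals.get(disease_id, nt), nt)
        ne = sum(1 for e in group if e.elite)
        nm = compute_nm(nt, ne)
        kept.extend(group[:nm])
        stats.append(
            FilterStats(
                disease_id=disease_id, Nt=nt, Ne=ne, Nm=nm,
                associations_before=nt, associations_after=nm,
            )
        )
    kept.sort(key=lambda e: (e.disease_id, -e.dg, e.gene_symbol))
    return kept, stats


def stats_totals(stats: Sequence[FilterStats]) -> dict[str, int]:
    """Per-disease original gene totals from a previous filter pass."""
    return {s.disease_id: s.Nt for s in stats}


def apply_filters(
    kb: Sequence[Association],
    table: ScoreTable,
    max_per_pub: Optional[int] = None,
) -> tuple[list[ScoredEdge], list[FilterStats], list[str]]:
    """Full filtering pipeline: publication filter, re-score, disease filter."""
    filtered_kb, removed_pubs = publication_filter(kb, max_per_pub, table)
    edges = score_all(filtered_kb, table)
    kept, stats = disease_promiscuity_filter(edges)
    for s in stats:
        s.removed_publications = removed_pubs
    return kept, stats, removed_pubs


def filter_report(
    edges_before: Sequence[ScoredEdge],
    edges_after: Sequence[ScoredEdge],
    removed_publications: Sequence[str] = (),
) -> dict:
    """Global retention fractions after filtering.

    Reports the percentage of associations and genes retained, elite-edge
    retention (100% under this design), and the largest per-disease gene
    count after filtering.
    """
    if not edges_before:
        return {}
    genes_before = {e.gene_symbol for e in edges_before}
    genes_after = {e.gene_symbol for e in edges_after}
    elite_before = sum(1 for e in edges_before if e.elite)
    elite_after = sum(1 for e in edges_after if e.elite)
    per_disease = Counter(e.disease_id for e in edges_after)
    return {
        "associations_before": len(edges_before),
        "associations_after": len(edges_after),
        "associations_retained_pct": 100.0 * len(edges_after) / len(edges_before),
        "genes_before": len(genes_before),
        "genes_after": len(genes_after),
        "genes_retained_pct": 100.0 * len(genes_after) / len(genes_before),
        "elite_retained_pct": (100.0 * elite_after / elite_before) if elite_before else 100.0,
        "max_genes_per_disease": max(per_disease.values()) if per_disease else 0,
        "removed_publications": list(removed_publications),
    }
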