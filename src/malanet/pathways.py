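"""Disease pathways, SuperPath clustering, and the pair-overlap statistic.

A *disease pathway* treats the (filtered or elite) gene set of one disease
as a bag-of-genes pathway.  Disease pathways — like biological pathways —
can be coalesced into *SuperPaths* by greedy agglomerative clustering on
gene-sharing similarity: repeatedly merge the pair of clusters with the
highest overlap coefficient ``|A ∩ B| / min(|A|, |B|)`` (computed on cluster
union gene sets) until no pair reaches the threshold.  Members of one
SuperPath that share no genes directly may still be indirectly related
through a bridging member that overlaps both.

The pair-overlap statistic asks how often two genes of the same disease
pathway also co-occur in some biological gene set — the fraction of
within-pathway gene pairs that share at least one set, averaged over a
random sample of pathways of a given size range.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DomainError, StatError
from .kb import GeneSet
from .scoring import ScoredEdge


@dataclass(frozen=True)
class DiseasePathway:
    """The retained gene set of one disease, viewed as a bag-of-genes pathway."""

    disease_id: str
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)

    def as_gene_set(self) -> GeneSet:
        return GeneSet(set_id=self.disease_id, name=f"disease pathway {self.disease_id}",
                       genes=self.genes)


@dataclass
class SuperPath:
    """A cluster of gene sets with its union gene set and member-overlap edges."""

    superpath_id: str
    members: list[str]
    union_genes: frozenset[str]
    edges: list[tuple[str, str, int]] = field(default_factory=list)


@dataclass
class OverlapStat:
    per_pathway_percent: list[float]
    mean: float
    sd: float
    n_sampled: int
    size_range: tuple[int, int]
    seed: int


def extract_disease_pathways(
    edges: Sequence[ScoredEdge], elite_only: bool = False
) -> list[DiseasePathway]:
    """One pathway per disease with >= 1 retained (or elite) gene."""
    genes: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        if elite_only and not e.elite:
            continue
        genes[e.disease_id].add(e.gene_symbol)
    return [DiseasePathway(d, frozenset(g)) for d, g in sorted(genes.items())]


def pair_superpath_overlap(pathway: DiseasePathway, sets: Sequence[GeneSet]) -> float:
    """Percent of within-pathway gene pairs co-occurring in at least one set."""
    genes = sorted(pathway.genes)
    if len(genes) < 2:
        raise StatError(
            f"pathway {pathway.disease_id} has {len(genes)} gene(s); "
            "pair overlap needs at least 2"
        )
    membership: dict[str, set[int]] = defaultdict(set)
    for i, s in enumerate(sets):
        for g in s.genes:
            membership[g].add(i)
    hits = sum(
        1 for a, b in combinations(genes, 2)
        if membership.get(a, set()) & membership.get(b, set())
    )
    n_pairs = len(genes) * (len(genes) - 1) // 2
    return 100.0 * hits / n_pairs


def sample_overlap_stat(
    pathways: Sequence[DiseasePathway],
    sets: Sequence[GeneSet],
    n: int,
    size_range: tuple[int, int] = (15, 20),
    seed: int = 0,
) -> OverlapStat:
    """Mean +/- sd pair overlap over a seeded sample of n size-eligible pathways.

    Pathways are sampled uniformly without replacement; the sd is the
    population standard deviation of the per-pathway percentages.
    """
    lo, hi = size_range
    eligible = sorted(
        (p for p in pathways if lo <= p.size <= hi), key=lambda p: p.disease_id
    )
    if len(eligible) < n:
        raise StatError(
            f"only {len(eligible)} pathways in size range {size_range}, need {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = [eligible[i] for i in sorted(rng.choice(len(eligible), size=n, replace=False))]
    percents = [pair_superpath_overlap(p, sets) for p in chosen]
    return OverlapStat(
        per_pathway_percent=percents,
        mean=float(np.mean(percents)),
        sd=float(np.std(percents)),  # population sd
        n_sampled=n,
        size_range=size_range,
        seed=seed,
    )


def _overlap_coefficient(a: frozenset, b: frozenset) -> tuple[float, int]:
    inter = len(a & b)
    return inter / min(len(a), len(b)), inter


def cluster_superpaths(
    sets: Sequence[GeneSet], threshold: float = 0.5
) -> list[SuperPath]:
    """Greedy agglomerative clustering of gene sets into SuperPaths.

    Each round merges the cluster pair with maximal overlap-coefficient
    similarity (on union gene sets) if it reaches the threshold; ties break
    by larger intersection, then lexicographically smaller cluster-id pair.
    A cluster's id is the smallest member set id.  Terminates when no pair
    reaches the threshold; the result partitions the input sets.
    """
    if threshold <= 0:
        raise DomainError(f"threshold must be in (0, 1], got {threshold}")
    by_id = {s.set_id: s for s in sets}
    if len(by_id) != len(sets):
        from .errors import ValidationError

        raise ValidationError("duplicate set_id in clustering input")

    # cluster id -> (member ids, union genes)
    clusters: dict[str, tuple[list[str], frozenset[str]]] = {
        s.set_id: ([s.set_id], s.genes) for s in sets
    }
    while len(clusters) > 1:
        best = None  # (sim, inter, (id_a, id_b))
        ids = sorted(clusters)
        for i, a in enumerate(ids):
            ua = clusters[a][1]
            for b in ids[i + 1:]:
                sim, inter = _overlap_coefficient(ua, clusters[b][1])
                if sim < threshold:
                    continue
                if (
                    best is None
                    or sim > best[0]
                    or (sim == best[0] and inter > best[1])
                    or (sim == best[0] and inter == best[1] and (a, b) < best[2])
                ):
                    best = (sim, inter, (a, b))
        if best is None:
            break
        _, _, (a, b) = best
        members = clusters[a][0] + clusters[b][0]
        union = clusters[a][1] | clusters[b][1]
        del clusters[a], clusters[b]
        clusters[min(a, b)] = (members, union)

    out: list[SuperPath] = []
    for k, cid in enumerate(sorted(clusters), start=1):
        members, union = clusters[cid]
        members = sorted(members)
        edges = [
            (x, y, len(by_id[x].genes & by_id[y].genes))
            for x, y in combinations(members, 2)
            if by_id[x].genes & by_id[y].genes
        ]
        out.append(SuperPath(
            superpath_id=f"SP{k}", members=members,
            union_genes=union, edges=edges,
        ))
    return out


def superpath_indirect_relations(superpath: SuperPath) -> list[tuple[str, str, str]]:
    """Member pairs sharing no genes but bridged by a common overlapping member."""
    neighbors: dict[str, set[str]] = defaultdict(set)
    direct: set[tuple[str, str]] = set()
    for a, b, _ in superpath.edges:
        neighbors[a].add(b)
        neighbors[b].add(a)
        direct.add((min(a, b), max(a, b)))
    found: dict[tuple[str, str], str] = {}
    for bridge in sorted(neighbors):
        for a, b in combinations(sorted(neighbors[bridge]), 2):
            if (a, b) not in direct and (a, b) not in found:
                found[(a, b)] = bridge
    return [(a, b, w) for (a, b), w in sorted(found.items())]


def superpaths_to_gene_sets(superpaths: Iterable[SuperPath]) -> list[GeneSet]:
    return [
        GeneSet(set_id=sp.superpath_id,
                name="|".join(sp.members),
                genes=sp.union_genes)
        for sp in superpaths
    ]
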