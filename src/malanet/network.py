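"""The weighted, directional bipartite gene-disease network and its projections.

Nodes are genes and diseases; the single edge type connects a disease to a
gene and carries both directional scores (D-G, G-D) and the elite flag.
Three stringency tiers exist: ``all`` (every scored edge), ``filtered``
(after promiscuity filtering) and ``elite`` (elite edges only); the edge sets
nest, elite within filtered within all.

The disease projection connects two diseases through every gene associated
with both; two diseases at distance exactly 2 in the projection share no
gene themselves but are bridged by a third disease that shares genes with
each — the indirect disease-disease relation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .scoring import ScoredEdge

TIERS = ("all", "filtered", "elite")


@dataclass
class BipartiteNetwork:
    graph: nx.Graph
    tier: str
    edges: list[ScoredEdge]

    @property
    def disease_nodes(self) -> set[str]:
        return {n[1] for n in self.graph.nodes if n[0] == "disease"}

    @property
    def gene_nodes(self) -> set[str]:
        return {n[1] for n in self.graph.nodes if n[0] == "gene"}


@dataclass(frozen=True)
class DiseaseProjectionEdge:
    disease_a: str
    disease_b: str
    shared_genes: frozenset[str]

    @property
    def weight(self) -> int:
        return len(self.shared_genes)


def build_network(edges: Iterable[ScoredEdge], tier: str = "all") -> BipartiteNetwork:
    """Assemble the bipartite graph for one stringency tier.

    ``tier='elite'`` keeps only elite edges; other tiers keep every edge
    passed in (the caller decides whether they were filtered).  Isolated
    nodes are excluded: every node in the graph touches an edge.
    """
    if tier not in TIERS:
        from .errors import ValidationError

        raise ValidationError(f"unknown tier {tier!r}; expected one of {TIERS}")
    selected = [e for e in edges if e.elite] if tier == "elite" else list(edges)
    g = nx.Graph()
    for e in selected:
        d, gn = ("disease", e.disease_id), ("gene", e.gene_symbol)
        g.add_node(d, kind="disease")
        g.add_node(gn, kind="gene")
        g.add_edge(d, gn, dg_raw=e.dg_raw, dg=e.dg, gd=e.gd, elite=e.elite)
    return BipartiteNetwork(graph=g, tier=tier, edges=selected)


def connected_components(network: BipartiteNetwork) -> list[BipartiteNetwork]:
    """Components as sub-networks, largest first; ties by smallest node id."""
    comps = []
    for nodes in nx.connected_components(network.graph):
        sub_edges = [
            e for e in network.edges
            if ("disease", e.disease_id) in nodes
        ]
        comps.append((nodes, sub_edges))
    comps.sort(key=lambda c: (-len(c[0]), min(n[1] for n in c[0])))
    return [
        BipartiteNetwork(graph=network.graph.subgraph(nodes).copy(), tier=network.tier, edges=sub)
        for nodes, sub in comps
    ]


def disease_gene_sets(edges: Iterable[ScoredEdge]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        out[e.disease_id].add(e.gene_symbol)
    return dict(out)


def project_diseases(network: BipartiteNetwork) -> list[DiseaseProjectionEdge]:
    """One projection edge per unordered disease pair sharing >= 1 gene.

    The weight is the raw shared-gene count.  Computed by scanning each
    gene's disease neighborhood, so sparse networks project quickly.
    """
    diseases_per_gene: dict[str, set[str]] = defaultdict(set)
    for e in network.edges:
        diseases_per_gene[e.gene_symbol].add(e.disease_id)
    shared: dict[tuple[str, str], set[str]] = defaultdict(set)
    for gene, diseases in diseases_per_gene.items():
        for a, b in combinations(sorted(diseases), 2):
            shared[(a, b)].add(gene)
    return [
        DiseaseProjectionEdge(a, b, frozenset(genes))
        for (a, b), genes in sorted(shared.items())
    ]


def project_genes(network: BipartiteNetwork) -> list[tuple[str, str, frozenset[str]]]:
    """Gene-gene projection: pairs of genes sharing >= 1 disease, with the shared diseases."""
    genes_per_disease = disease_gene_sets(network.edges)
    shared: dict[tuple[str, str], set[str]] = defaultdict(set)
    for disease, genes in genes_per_disease.items():
        for a, b in combinations(sorted(genes), 2):
            shared[(a, b)].add(disease)
    return [(a, b, frozenset(ds)) for (a, b), ds in sorted(shared.items())]


def indirect_disease_pairs(
    projection: Sequence[DiseaseProjectionEdge],
) -> list[tuple[str, str, str]]:
    """Disease pairs at distance exactly 2 in the projection, with a bridge.

    These pairs share no gene directly but each shares genes with a common
    third disease.  One witness bridge (the lexicographically smallest) is
    reported per pair.
    """
    g = nx.Graph()
    for e in projection:
        g.add_edge(e.disease_a, e.disease_b)
    found: dict[tuple[str, str], str] = {}
    for bridge in sorted(g.nodes):
        for a, b in combinations(sorted(g.neighbors(bridge)), 2):
            if not g.has_edge(a, b) and (a, b) not in found:
                found[(a, b)] = bridge
    return [(a, b, bridge) for (a, b), bridge in sorted(found.items())]
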