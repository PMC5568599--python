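"""Bipartite network, disease projection, and indirect disease relations.

Recreates the canonical bridge pattern: two Gaucher-type diseases share
genes with a third (bridge) disease but not with each other, so they sit at
distance 2 in the disease projection — an indirect disease-disease relation
discovered through gene sharing.
"""

from malanet import (
    build_network,
    connected_components,
    indirect_disease_pairs,
    project_diseases,
)
from malanet.scoring import ScoredEdge


def edge(d, g):
    return ScoredEdge(d, g, 499.0, 2.699, 3.699, True)


edges = [
    edge("gaucher_3c", "GBA"),
    edge("gaucher_3", "GBA"),
    edge("gaucher_3", "CHIT1"),
    edge("chitotriosidase_def", "CHIT1"),
]

net = build_network(edges, tier="elite")
print(f"network: {len(net.disease_nodes)} diseases, {len(net.gene_nodes)} genes, "
      f"{len(net.edges)} edges, {len(connected_components(net))} component(s)")

projection = project_diseases(net)
for p in projection:
    print(f"direct relation: {p.disease_a} -- {p.disease_b} "
          f"(shared genes: {', '.join(sorted(p.shared_genes))})")

for a, b, bridge in indirect_disease_pairs(projection):
    print(f"indirect relation: {a} -- {b} via bridge {bridge} (no shared genes)")
# The indirect pair shares no gene; the bridge disease overlaps both.
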