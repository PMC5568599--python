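"""Independent greedy-agglomeration oracle used by clustering tests.

Re-implements the same rule as the library (overlap-coefficient on cluster
unions, best-pair merges, tie-breaks by intersection then id pair) from a
fresh similarity scan each round, without sharing any code path with
malanet.pathways.
"""

from itertools import combinations


def independent_greedy(sets, threshold):
    clusters = {s.set_id: (frozenset([s.set_id]), set(s.genes)) for s in sets}
    while True:
        candidates = []
        for a, b in combinations(sorted(clusters), 2):
            ua, ub = clusters[a][1], clusters[b][1]
            inter = len(ua & ub)
            sim = inter / min(len(ua), len(ub))
            if sim >= threshold:
                candidates.append((-sim, -inter, a, b))
        if not candidates:
            break
        _, _, a, b = min(candidates)
        merged = (clusters[a][0] | clusters[b][0], clusters[a][1] | clusters[b][1])
        del clusters[a], clusters[b]
        clusters[min(a, b)] = merged
    return {frozenset(v[0]) for v in clusters.values()}
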