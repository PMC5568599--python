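"""Disease pathways, the pair-overlap statistic (vs brute force) and greedy
SuperPath clustering (vs an independent re-implementation)."""

import random
from itertools import combinations

import pytest

from malanet import (
    GeneSet,
    cluster_superpaths,
    extract_disease_pathways,
    pair_superpath_overlap,
    sample_overlap_stat,
    superpath_indirect_relations,
)
from malanet.errors import DomainError, StatError
from malanet.pathways import DiseasePathway
from malanet.scoring import ScoredEdge
from malanet.synth import generate_overlap_fixture


def edge(d, g, elite=False):
    dg = 3.0 if elite else 1.5
    return ScoredEdge(d, g, 10 ** dg - 1, dg, dg + (1.0 if elite else 0.0), elite)


class TestExtractPathways:
    def test_all_vs_elite_only(self):
        edges = [edge("D1", f"G{i}", elite=i < 2) for i in range(5)]
        assert extract_disease_pathways(edges)[0].size == 5
        assert extract_disease_pathways(edges, elite_only=True)[0].size == 2

    def test_disease_without_elite_excluded_in_elite_mode(self):
        edges = [edge("D1", "G1", elite=True), edge("D2", "G2", elite=False)]
        ids = [p.disease_id for p in extract_disease_pathways(edges, elite_only=True)]
        assert ids == ["D1"]


class TestPairOverlap:
    def test_two_of_six_pairs(self):
        pw = DiseasePathway("D1", frozenset("ABCD"))
        sets = [GeneSet("S1", "s", frozenset("AB")), GeneSet("S2", "s", frozenset("CD"))]
        assert pair_superpath_overlap(pw, sets) == pytest.approx(100 * 2 / 6)

    def test_all_in_one_set_is_100(self):
        pw = DiseasePathway("D1", frozenset("ABC"))
        assert pair_superpath_overlap(pw, [GeneSet("S", "s", frozenset("ABC"))]) == 100.0

    def test_no_membership_is_0(self):
        pw = DiseasePathway("D1", frozenset("ABC"))
        assert pair_superpath_overlap(pw, [GeneSet("S", "s", frozenset("XY"))]) == 0.0

    def test_singleton_pathway_rejected(self):
        with pytest.raises(StatError):
            pair_superpath_overlap(DiseasePathway("D1", frozenset("A")), [])

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(9)
        genes = [f"G{i}" for i in range(30)]
        for _ in range(60):
            pw = DiseasePathway("D", frozenset(rng.sample(genes, rng.randint(2, 12))))
            sets = [
                GeneSet(f"S{k}", "s", frozenset(rng.sample(genes, rng.randint(2, 8))))
                for k in range(rng.randint(0, 10))
            ]
            if not sets:
                assert pair_superpath_overlap(pw, sets) == 0.0
                continue
            hits = sum(
                1 for a, b in combinations(sorted(pw.genes), 2)
                if any(a in s.genes and b in s.genes for s in sets)
            )
            n_pairs = len(pw.genes) * (len(pw.genes) - 1) // 2
            assert pair_superpath_overlap(pw, sets) == pytest.approx(100 * hits / n_pairs)


class TestSampleOverlapStat:
    def test_single_pathway_sd_zero(self):
        pathways, sets = generate_overlap_fixture(n_pathways=3, co_membership_rate=0.5, seed=1)
        stat = sample_overlap_stat(pathways, sets, n=1, seed=2)
        assert stat.sd == 0.0
        assert stat.mean == pytest.approx(stat.per_pathway_percent[0])

    def test_zero_rate_gives_zero_mean(self):
        pathways, sets = generate_overlap_fixture(n_pathways=10, co_membership_rate=0.0, seed=1)
        stat = sample_overlap_stat(pathways, sets, n=10, seed=3)
        assert stat.mean == 0.0 and stat.sd == 0.0

    def test_insufficient_pathways_errors_with_count(self):
        pathways, sets = generate_overlap_fixture(n_pathways=4, co_membership_rate=0.1, seed=1)
        with pytest.raises(StatError, match="4"):
            sample_overlap_stat(pathways, sets, n=10, seed=0)

    def test_seed_determinism(self):
        pathways, sets = generate_overlap_fixture(n_pathways=20, co_membership_rate=0.2, seed=5)
        s1 = sample_overlap_stat(pathways, sets, n=10, seed=7)
        s2 = sample_overlap_stat(pathways, sets, n=10, seed=7)
        assert s1.per_pathway_percent == s2.per_pathway_percent


from tests_clustering_oracle import independent_greedy  # noqa: E402


def random_sets(rng, n_sets, pool=20):
    genes = [f"G{i}" for i in range(pool)]
    return [
        GeneSet(f"S{k}", "s", frozenset(rng.sample(genes, rng.randint(2, 8))))
        for k in range(n_sets)
    ]


class TestClusterSuperpaths:
    def test_overlapping_pair_merges(self):
        sets = [GeneSet("S1", "s", frozenset("ABC")), GeneSet("S2", "s", frozenset("BCD"))]
        out = cluster_superpaths(sets, threshold=0.5)
        assert len(out) == 1
        assert out[0].union_genes == frozenset("ABCD")
        assert out[0].members == ["S1", "S2"]

    def test_disjoint_sets_stay_apart(self):
        sets = [GeneSet("S1", "s", frozenset("AB")), GeneSet("S2", "s", frozenset("CD"))]
        assert len(cluster_superpaths(sets, threshold=0.5)) == 2

    def test_threshold_above_one_identity_partition(self):
        rng = random.Random(1)
        sets = random_sets(rng, 6)
        out = cluster_superpaths(sets, threshold=1.0000001)
        assert len(out) == len(sets)

    def test_invalid_threshold(self):
        with pytest.raises(DomainError):
            cluster_superpaths([GeneSet("S", "s", frozenset("A"))], threshold=0.0)

    def test_partition_property(self):
        rng = random.Random(2)
        for _ in range(20):
            sets = random_sets(rng, rng.randint(1, 12))
            out = cluster_superpaths(sets, threshold=0.5)
            members = [m for sp in out for m in sp.members]
            assert sorted(members) == sorted(s.set_id for s in sets)
            union_of_unions = frozenset().union(*(sp.union_genes for sp in out))
            assert union_of_unions == frozenset().union(*(s.genes for s in sets))

    def test_threshold_monotonicity(self):
        rng = random.Random(3)
        for _ in range(10):
            sets = random_sets(rng, 10)
            counts = [
                len(cluster_superpaths(sets, threshold=t))
                for t in [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
            ]
            assert counts == sorted(counts, reverse=True)

    def test_matches_independent_greedy(self):
        rng = random.Random(4)
        for _ in range(30):
            sets = random_sets(rng, rng.randint(2, 10))
            for t in (0.3, 0.5, 0.8):
                got = {frozenset(sp.members) for sp in cluster_superpaths(sets, t)}
                assert got == independent_greedy(sets, t)


class TestIndirectRelations:
    def test_bridge_pattern_inside_cluster(self):
        sets = [
            GeneSet("A", "s", frozenset({"G1", "G2"})),
            GeneSet("B", "s", frozenset({"G2", "G3"})),
            GeneSet("C", "s", frozenset({"G3", "G4"})),
        ]
        out = cluster_superpaths(sets, threshold=0.5)
        assert len(out) == 1
        assert superpath_indirect_relations(out[0]) == [("A", "C", "B")]

    def test_clique_has_none(self):
        sets = [
            GeneSet("A", "s", frozenset({"G1", "G2"})),
            GeneSet("B", "s", frozenset({"G1", "G2", "G3"})),
            GeneSet("C", "s", frozenset({"G1", "G3"})),
        ]
        out = cluster_superpaths(sets, threshold=0.4)
        assert len(out) == 1
        assert superpath_indirect_relations(out[0]) == []

    def test_singleton_superpath_has_none(self):
        out = cluster_superpaths([GeneSet("A", "s", frozenset({"G1"}))], threshold=0.5)
        assert superpath_indirect_relations(out[0]) == []
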