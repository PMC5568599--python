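"""Phenotype-term matching, direct/indirect candidate scoring, ranking order,
and the prioritizer's invariants (direct dominance, query monotonicity)."""

import pytest
from hypothesis import given, settings, strategies as st

from malanet import (
    Context,
    DiseaseRecord,
    PhenotypeQuery,
    PrioritizerConfig,
    direct_scores,
    indirect_scores,
    match_diseases,
    rank,
)
from malanet.errors import ValidationError
from malanet.pathways import DiseasePathway
from malanet.scoring import ScoredEdge


def edge(d, g, gd, elite=False):
    return ScoredEdge(d, g, 0.0, max(gd - (1.0 if elite else 0.0), 0.0), gd, elite)


class TestQueryParsing:
    def test_or_split_lowercase_dedup(self):
        q = PhenotypeQuery.parse("Epilepsy OR MACULAR OR epilepsy OR retinitis")
        assert q.terms == ("epilepsy", "macular", "retinitis")

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            PhenotypeQuery.parse("   ")


class TestMatchDiseases:
    def test_case_insensitive_main_name(self, tiny_vocab):
        q = PhenotypeQuery.parse("epilepsy")
        hits = match_diseases(q, tiny_vocab)
        assert ("D1", "epilepsy", "main_name") in [
            (m.disease_id, m.term, m.via) for m in hits
        ]

    def test_substring_matches_alias(self, tiny_vocab):
        q = PhenotypeQuery.parse("retinitis")
        hits = match_diseases(q, tiny_vocab, match_mode="substring")
        assert [(m.disease_id, m.via) for m in hits] == [("D1", "alias")]

    def test_no_match(self, tiny_vocab):
        assert match_diseases(PhenotypeQuery.parse("cln6"), tiny_vocab) == []

    def test_exact_token_mode(self, tiny_vocab):
        q = PhenotypeQuery.parse("gaucher")
        assert match_diseases(q, tiny_vocab, match_mode="exact_token")
        q2 = PhenotypeQuery.parse("gauch")
        assert match_diseases(q2, tiny_vocab, match_mode="exact_token") == []
        assert match_diseases(q2, tiny_vocab, match_mode="substring")


class TestDirectScores:
    def setup_method(self):
        self.records = [DiseaseRecord("D1", "epilepsy"), DiseaseRecord("D2", "macular x")]
        self.matches = match_diseases(PhenotypeQuery.parse("epilepsy OR macular"), self.records)

    def test_single_matched_disease(self):
        out = direct_scores(["G1"], self.matches, [edge("D1", "G1", 3.7, elite=True)])
        assert out["G1"][0] == pytest.approx(3.7)
        assert out["G1"][1] == [("D1", "epilepsy", "main_name")]

    def test_unconnected_candidate_scores_zero(self):
        out = direct_scores(["G9"], self.matches, [edge("D1", "G1", 3.7)])
        assert out["G9"] == (0.0, [])

    def test_aggregation_max_vs_sum(self):
        edges = [edge("D1", "G1", 2.0), edge("D2", "G1", 3.0)]
        assert direct_scores(["G1"], self.matches, edges,
                             PrioritizerConfig(aggregation="max"))["G1"][0] == 3.0
        assert direct_scores(["G1"], self.matches, edges,
                             PrioritizerConfig(aggregation="sum"))["G1"][0] == 5.0


class TestIndirectScores:
    def test_attenuated_propagation(self):
        direct = {"GHIT": (4.0, [("D1", "t", "main_name")]), "GX": (0.0, [])}
        ctx = [Context("P1", "disease_pathway", frozenset({"GHIT", "GX"}))]
        out = indirect_scores(["GX"], direct, ctx, PrioritizerConfig(attenuation=0.25))
        assert out["GX"][0] == pytest.approx(1.0)
        assert out["GX"][1] == [("GHIT", "P1", "disease_pathway")]

    def test_no_shared_context_scores_zero(self):
        direct = {"GHIT": (4.0, []), "GX": (0.0, [])}
        ctx = [Context("P1", "superpath", frozenset({"GHIT", "GOTHER"}))]
        assert indirect_scores(["GX"], direct, ctx)["GX"] == (0.0, [])

    def test_attenuation_one_is_identity_limit(self):
        direct = {"GHIT": (4.0, []), "GX": (0.0, [])}
        ctx = [Context("P1", "gene_set", frozenset({"GHIT", "GX"}))]
        out = indirect_scores(["GX"], direct, ctx, PrioritizerConfig(attenuation=1.0))
        assert out["GX"][0] == 4.0

    def test_attenuation_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            PrioritizerConfig(attenuation=0.0)
        with pytest.raises(ValidationError):
            PrioritizerConfig(attenuation=1.5)


class TestRank:
    def setup_method(self):
        self.records = [DiseaseRecord("D1", "epilepsy syndrome", ["atypical epilepsy"])]
        self.edges = [
            edge("D1", "GCAUSE", 3.7, elite=True),
            edge("D1", "GWEAK", 1.4),
        ]
        self.contexts = [
            Context.from_disease_pathway(DiseasePathway("DP", frozenset({"GCAUSE", "GNEAR"}))),
        ]

    def test_direct_before_indirect_before_none(self):
        q = PhenotypeQuery.parse("epilepsy")
        ranking = rank(["GCAUSE", "GWEAK", "GNEAR", "GNOPE"], q, self.records,
                       self.edges, self.contexts)
        assert [r.gene_symbol for r in ranking] == ["GCAUSE", "GWEAK", "GNEAR", "GNOPE"]
        assert [r.mode for r in ranking] == ["direct", "direct", "indirect", "none"]
        assert ranking[2].score == pytest.approx(0.25 * 3.7)
        assert ranking[2].implicating_genes == [("GCAUSE", "DP", "disease_pathway")]

    def test_unknown_candidates_kept_as_none(self):
        q = PhenotypeQuery.parse("nothing matches this")
        ranking = rank(["GB", "GA"], q, self.records, self.edges)
        assert [r.gene_symbol for r in ranking] == ["GA", "GB"]
        assert all(r.mode == "none" and r.score == 0.0 for r in ranking)

    def test_single_candidate_rank_1(self):
        q = PhenotypeQuery.parse("epilepsy")
        ranking = rank(["GNOPE"], q, self.records, self.edges)
        assert len(ranking) == 1

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValidationError):
            rank([], PhenotypeQuery.parse("x"), self.records, self.edges)

    def test_candidate_order_invariance(self):
        q = PhenotypeQuery.parse("epilepsy")
        r1 = rank(["GCAUSE", "GNEAR", "GWEAK"], q, self.records, self.edges, self.contexts)
        r2 = rank(["GWEAK", "GCAUSE", "GNEAR"], q, self.records, self.edges, self.contexts)
        assert [(r.gene_symbol, r.score) for r in r1] == [(r.gene_symbol, r.score) for r in r2]

    def test_direct_dominance(self):
        """With attenuation < 1 and max aggregation, no indirect-only gene
        outranks the direct gene it derives its score from."""
        q = PhenotypeQuery.parse("epilepsy")
        ranking = rank(["GCAUSE", "GNEAR"], q, self.records, self.edges,
                       self.contexts, PrioritizerConfig(attenuation=0.99))
        assert ranking[0].gene_symbol == "GCAUSE"
        assert ranking[0].score > ranking[1].score


@settings(deadline=None, derandomize=True)
@given(extra_term=st.sampled_from(["macular", "retinal", "gaucher", "zzz"]))
def test_query_monotonicity(extra_term):
    """Adding an OR term never decreases any candidate's score."""
    records = [
        DiseaseRecord("D1", "epilepsy"),
        DiseaseRecord("D2", "macular degeneration"),
        DiseaseRecord("D3", "gaucher disease"),
    ]
    edges = [edge("D1", "G1", 2.0), edge("D2", "G1", 3.0),
             edge("D3", "G2", 2.5), edge("D2", "G3", 1.0)]
    candidates = ["G1", "G2", "G3"]
    base_q = PhenotypeQuery.parse("epilepsy")
    big_q = PhenotypeQuery(("epilepsy", extra_term))
    cfg = PrioritizerConfig(aggregation="sum")
    base = {r.gene_symbol: r.score for r in rank(candidates, base_q, records, edges, (), cfg)}
    grown = {r.gene_symbol: r.score for r in rank(candidates, big_q, records, edges, (), cfg)}
    for g in candidates:
        assert grown[g] >= base[g]
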