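import pytest

from malanet import (
    Association,
    DiseaseRecord,
    EvidenceItem,
    ScoreTable,
)


@pytest.fixture(scope="session")
def default_table() -> ScoreTable:
    return ScoreTable.default()


def ev(source, ann, pub=None):
    return EvidenceItem(source, ann, pub)


@pytest.fixture
def tiny_kb():
    """Four associations over two diseases: one elite-grade, the rest mixed."""
    return [
        Association("D1", "G1", [ev("OMIM", "molecular_basis_known")]),
        Association("D1", "G2", [ev("GeneTests", "appearance"),
                                 ev("Novoseek", "text_mining", "PMID1")]),
        Association("D2", "G2", [ev("ClinVar", "pathogenic_mutation")]),
        Association("D2", "G3", [ev("DISEASE", "text_mining", "PMID2")]),
    ]


@pytest.fixture
def tiny_vocab():
    return [
        DiseaseRecord("D1", "Epilepsy, atypical", ["retinitis pigmentosa epilepsy"]),
        DiseaseRecord("D2", "Gaucher disease type 3", ["gaucher iii"]),
    ]
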