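import pytest

from phenonet.corpus import DiseaseCorpus, DiseaseProfile, FrequencyValue
from phenonet.datasets import muscle_tone_ontology
from phenonet.ontology import Ontology, compute_ic


@pytest.fixture(scope="session")
def muscle_tone():
    """The seven-term muscle-tone DAG of the query-expansion worked example."""
    return muscle_tone_ontology()


@pytest.fixture()
def diamond():
    """a -> {b, c} -> root: the smallest multi-parent DAG."""
    return Ontology(
        {"root": [], "b": ["root"], "c": ["root"], "a": ["b", "c"]},
        names={"root": "root", "a": "a", "b": "b", "c": "c"},
    )


def make_corpus(term_sets: dict[str, set[str]]) -> DiseaseCorpus:
    """Corpus from bare term sets, every frequency 1.0."""
    profiles = {
        did: DiseaseProfile(did, did, {t: FrequencyValue(1.0) for t in terms})
        for did, terms in term_sets.items()
    }
    return DiseaseCorpus(profiles)


@pytest.fixture()
def diamond_ic(diamond):
    """IC over the diamond from a 3-disease corpus: ic(a)=log3, ic(b)=ic(c)=log(3/2)."""
    corpus = make_corpus({"d1": {"a"}, "d2": {"b"}, "d3": {"c"}})
    return compute_ic(diamond, corpus)
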