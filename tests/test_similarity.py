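"""The five similarity measures and query expansion, against hand
computations and brute-force oracles."""

import math

import numpy as np
import pytest

from phenonet.corpus import DiseaseProfile, FrequencyValue
from phenonet.datasets import (
    HYPOTONIA,
    LOWER_LIMB_HYPERTONIA,
    SPASTICITY,
    muscle_tone_ontology,
    muscle_tone_query,
)
from phenonet.errors import ConfigError, DataError
from phenonet.ontology import Ontology, compute_ic
from phenonet.profile import QueryProfile
from phenonet.similarity import (
    cosine,
    expand_query,
    graphic,
    jaccard,
    resnik_avg,
    resnik_bma,
    resnik_term,
    score_all,
    tfidf_vectors,
    SimilarityVector,
)
from phenonet.synthetic_data import SyntheticConfig, generate_ontology

from conftest import make_corpus


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"x", "y"}, {"x", "z"}, 1 / 3),
            (set(), set(), 0.0),
            (set(), {"x"}, 0.0),
        ],
    )
    def test_cases(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"t{i}" for i in range(12)]
        a = {t for t in universe if rng.random() < 0.4}
        b = {t for t in universe if rng.random() < 0.4}
        inter = sum(1 for t in universe if t in a and t in b)
        union = sum(1 for t in universe if t in a or t in b)
        expected = inter / union if union else 0.0
        assert jaccard(a, b) == pytest.approx(expected)
        assert jaccard(b, a) == jaccard(a, b)


@pytest.fixture()
def shared_mid():
    """root <- m <- {x, y}, root <- z; four diseases give ic(m) = log 2."""
    ont = Ontology({"root": [], "m": ["root"], "x": ["m"], "y": ["m"], "z": ["root"]})
    corpus = make_corpus({"d1": {"x"}, "d2": {"y"}, "d3": {"z"}, "d4": {"z"}})
    return ont, compute_ic(ont, corpus)


class TestResnikTerm:
    def test_self_similarity_is_own_ic(self, shared_mid):
        ont, ic = shared_mid
        assert resnik_term("x", "x", ic, ont) == pytest.approx(ic.get_ic("x"))

    def test_only_root_shared_gives_zero(self, shared_mid):
        ont, ic = shared_mid
        assert resnik_term("x", "z", ic, ont) == 0.0

    def test_shared_mid_term_gives_its_ic(self, shared_mid):
        ont, ic = shared_mid
        assert resnik_term("x", "y", ic, ont) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_max_oracle(self, seed):
        ont = generate_ontology(SyntheticConfig(n_terms=30, max_parents=3, seed=seed))
        rng = np.random.default_rng(seed)
        terms = sorted(ont.terms - {ont.root})
        corpus = make_corpus(
            {f"d{i}": set(rng.choice(terms, size=3, replace=False)) for i in range(10)}
        )
        ic = compute_ic(ont, corpus)
        for _ in range(10):
            x, y = (terms[i] for i in rng.integers(0, len(terms), size=2))
            common = ont.ancestors(x) & ont.ancestors(y)
            expected = max(ic.get_ic(t) for t in common)
            assert resnik_term(x, y, ic, ont) == pytest.approx(expected)
            assert resnik_term(y, x, ic, ont) == pytest.approx(expected)


class TestResnikProfiles:
    def test_single_term_profiles(self, shared_mid):
        ont, ic = shared_mid
        assert resnik_avg({"x"}, {"x"}, ic, ont) == pytest.approx(ic.get_ic("x"))
        assert resnik_bma({"x"}, {"x"}, ic, ont) == pytest.approx(ic.get_ic("x"))

    def test_two_pair_average_by_hand(self, shared_mid):
        # A={x}, B={x,z}: pairs (x,x)=ic(x) and (x,z)=0
        ont, ic = shared_mid
        icx = ic.get_ic("x")
        assert resnik_avg({"x"}, {"x", "z"}, ic, ont) == pytest.approx(icx / 2)
        # BMA: A side best-match ic(x); B side best matches ic(x) and 0
        expected = 0.5 * (icx + icx / 2)
        assert resnik_bma({"x"}, {"x", "z"}, ic, ont) == pytest.approx(expected)

    def test_symmetry(self, shared_mid):
        ont, ic = shared_mid
        a, b = {"x", "y"}, {"y", "z"}
        assert resnik_avg(a, b, ic, ont) == pytest.approx(resnik_avg(b, a, ic, ont))
        assert resnik_bma(a, b, ic, ont) == pytest.approx(resnik_bma(b, a, ic, ont))

    def test_empty_profile_is_error(self, shared_mid):
        ont, ic = shared_mid
        with pytest.raises(DataError):
            resnik_avg(set(), {"x"}, ic, ont)
        with pytest.raises(DataError):
            resnik_bma({"x"}, set(), ic, ont)


class TestGraphIC:
    def test_identical_profiles_score_one(self, shared_mid):
        ont, ic = shared_mid
        assert graphic({"x", "z"}, {"x", "z"}, ic, ont) == pytest.approx(1.0)

    def test_root_only_overlap_scores_zero(self, shared_mid):
        ont, ic = shared_mid
        assert graphic({"x"}, {"z"}, ic, ont) == 0.0

    def test_hand_summed_ratio_on_diamond(self, diamond, diamond_ic):
        # A={a}: expands to {a,b,c,root}; B={b}: expands to {b,root}
        # intersection {b,root}, union {a,b,c,root}
        ic = diamond_ic
        num = ic.get_ic("b")
        den = ic.get_ic("a") + ic.get_ic("b") + ic.get_ic("c")
        assert graphic({"a"}, {"b"}, ic, diamond) == pytest.approx(num / den)

    def test_zero_denominator_warns_and_returns_zero(self, caplog):
        ont = Ontology({"root": [], "x": ["root"]})
        ic = compute_ic(ont, make_corpus({"d1": {"x"}, "d2": {"x"}}))  # all ic 0
        with caplog.at_level("WARNING"):
            assert graphic({"x"}, {"x"}, ic, ont) == 0.0
        assert "denominator" in caplog.text


class TestTfidf:
    @pytest.fixture()
    def three_docs(self):
        # t1 in every document, t2 in one, t3 in two
        profiles = {
            "d1": {"t1": 0.5, "t2": 0.8},
            "d2": {"t1": 1.0, "t3": 0.4},
            "d3": {"t1": 0.2, "t3": 0.9},
        }
        return make_corpus_with_freqs(profiles)

    def test_weights_match_hand_computation(self, three_docs):
        query = QueryProfile("q", {"t2": 1.0})
        vectors, _qv = tfidf_vectors(three_docs, query)
        # idf(t) = log((1+3)/(1+df)) + 1
        idf1 = math.log(4 / 4) + 1  # df=3 -> 1.0, the smoothing floor
        idf2 = math.log(4 / 2) + 1
        idf3 = math.log(4 / 3) + 1
        assert vectors["d1"].weights == pytest.approx({"t1": 0.5 * idf1, "t2": 0.8 * idf2})
        assert vectors["d2"].weights == pytest.approx({"t1": 1.0 * idf1, "t3": 0.4 * idf3})

    def test_universal_term_hits_idf_floor(self, three_docs):
        query = QueryProfile("q", {"t1": 1.0})
        _v, qv = tfidf_vectors(three_docs, query)
        assert qv.weights["t1"] == pytest.approx(1.0)  # log(4/4)+1

    def test_query_term_outside_vocabulary_retained(self, three_docs):
        query = QueryProfile("q", {"t9": 1.0})
        _v, qv = tfidf_vectors(three_docs, query)
        assert qv.weights["t9"] == pytest.approx(math.log(4 / 1) + 1)

    def test_binary_tf_mode(self, three_docs):
        query = QueryProfile("q", {"t2": 0.3})
        _v, qv = tfidf_vectors(three_docs, query, tf_mode="binary")
        assert qv.weights["t2"] == pytest.approx(math.log(4 / 2) + 1)


class TestCosine:
    def test_self_similarity_is_one(self):
        u = SimilarityVector({"a": 1.0, "b": 2.0})
        assert cosine(u, u) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        assert cosine(SimilarityVector({"a": 1.0}), SimilarityVector({"b": 1.0})) == 0.0

    def test_hand_case(self):
        u = SimilarityVector({"a": 1.0, "b": 1.0})
        v = SimilarityVector({"a": 1.0, "c": 1.0})
        assert cosine(u, v) == pytest.approx(0.5)

    def test_zero_norm_gives_zero(self):
        assert cosine(SimilarityVector({}), SimilarityVector({"a": 1.0})) == 0.0


class TestExpandQuery:
    def test_worked_example_decay(self, muscle_tone):
        query = muscle_tone_query(f_spasticity=0.4, f_hypotonia=0.45)
        expanded = expand_query(query, muscle_tone, alpha=0.5)
        # Spasticity at distance 3 beats Hypotonia at distance 4 even though
        # the hypotonia frequency is larger
        seed, d = expanded.nearest_seed[LOWER_LIMB_HYPERTONIA]
        assert (seed, d) == (SPASTICITY, 3)
        f = expanded.frequencies[LOWER_LIMB_HYPERTONIA]
        assert f == pytest.approx(0.4 * 0.5**3)
        assert f / expanded.frequencies[SPASTICITY] == pytest.approx(0.125)

    def test_seeds_keep_their_frequency(self, muscle_tone):
        query = muscle_tone_query()
        for alpha in (0.0, 0.5, 1.0):
            expanded = expand_query(query, muscle_tone, alpha=alpha)
            for t, f in query.annotations.items():
                assert expanded.frequencies[t] == pytest.approx(f)

    def test_alpha_zero_support_is_exactly_the_seed_set(self, muscle_tone):
        expanded = expand_query(muscle_tone_query(), muscle_tone, alpha=0.0)
        assert expanded.terms == muscle_tone_query().terms

    def test_alpha_one_propagates_unchanged(self, muscle_tone):
        query = muscle_tone_query(f_spasticity=0.4, f_hypotonia=0.45)
        expanded = expand_query(query, muscle_tone, alpha=1.0)
        assert expanded.terms == muscle_tone.terms
        for t, f in expanded.frequencies.items():
            seed, _d = expanded.nearest_seed[t]
            assert f == pytest.approx(query.annotations[seed])

    def test_equidistant_tie_takes_larger_frequency(self):
        # c is one step from both seeds a and b
        ont = Ontology({"root": [], "a": ["root"], "b": ["root"], "c": ["a", "b"]})
        query = QueryProfile("q", {"a": 0.2, "b": 0.9})
        expanded = expand_query(query, ont, alpha=0.5)
        assert expanded.frequencies["c"] == pytest.approx(0.9 * 0.5)
        assert expanded.nearest_seed["c"][0] == "b"

    def test_increasing_alpha_never_decreases_frequencies(self, muscle_tone):
        query = muscle_tone_query()
        lo = expand_query(query, muscle_tone, alpha=0.3)
        hi = expand_query(query, muscle_tone, alpha=0.7)
        for t, f in lo.frequencies.items():
            assert hi.frequencies[t] >= f - 1e-12

    def test_missing_query_term_is_error(self, muscle_tone):
        with pytest.raises(DataError, match="HP:9999999"):
            expand_query(QueryProfile("q", {"HP:9999999": 0.5}), muscle_tone, alpha=0.5)

    def test_invalid_alpha_is_error(self, muscle_tone):
        with pytest.raises(ConfigError):
            expand_query(muscle_tone_query(), muscle_tone, alpha=1.5)


def make_corpus_with_freqs(profiles: dict[str, dict[str, float]]):
    from phenonet.corpus import DiseaseCorpus

    return DiseaseCorpus(
        {
            did: DiseaseProfile(did, did, {t: FrequencyValue(f) for t, f in ann.items()})
            for did, ann in profiles.items()
        }
    )


class TestScoreAll:
    @pytest.fixture()
    def planted(self, muscle_tone):
        query = muscle_tone_query(f_spasticity=0.4, f_hypotonia=0.45)
        corpus = make_corpus_with_freqs(
            {
                "clone": dict(query.annotations),
                "other": {LOWER_LIMB_HYPERTONIA: 0.8},
                "partial": {SPASTICITY: 0.4, LOWER_LIMB_HYPERTONIA: 0.2},
            }
        )
        ic = compute_ic(muscle_tone, corpus)
        return corpus, query, muscle_tone, ic

    def test_clone_scores_top_under_every_method(self, planted):
        corpus, query, ont, ic = planted
        frame = score_all(corpus, query, ont, ic)
        wide = frame.pivot(index="disease_id", columns="method", values="score")
        assert wide.loc["clone", "jaccard"] == pytest.approx(1.0)
        assert wide.loc["clone", "graphic"] == pytest.approx(1.0)
        for method in wide.columns:
            assert wide.loc["clone", method] == wide[method].max()

    def test_query_expansion_eliminates_zero_scores(self, planted):
        corpus, query, ont, ic = planted
        frame = score_all(corpus, query, ont, ic, methods=("tfidf", "tfidf_qe"), alpha=0.5)
        wide = frame.pivot(index="disease_id", columns="method", values="score")
        assert wide.loc["other", "tfidf"] == 0.0  # no direct term overlap
        assert wide.loc["other", "tfidf_qe"] > 0.0
        assert (wide["tfidf_qe"] > 0).all()

    def test_alpha_zero_expansion_degenerates_to_plain_tfidf(self, planted):
        corpus, query, ont, ic = planted
        frame = score_all(corpus, query, ont, ic, methods=("tfidf", "tfidf_qe"), alpha=0.0)
        wide = frame.pivot(index="disease_id", columns="method", values="score")
        assert wide["tfidf"].values == pytest.approx(wide["tfidf_qe"].values)

    def test_single_disease_corpus_gives_one_row_per_method(self, planted):
        _corpus, query, ont, ic = planted
        corpus = make_corpus_with_freqs({"only": dict(query.annotations)})
        frame = score_all(corpus, query, ont, ic)
        assert len(frame) == len(frame["method"].unique())

    def test_unknown_method_is_error(self, planted):
        corpus, query, ont, ic = planted
        with pytest.raises(ConfigError, match="lin"):
            score_all(corpus, query, ont, ic, methods=("jaccard", "lin"))

    def test_scores_within_bounds(self, planted):
        corpus, query, ont, ic = planted
        frame = score_all(corpus, query, ont, ic, methods=("jaccard", "graphic", "tfidf", "tfidf_qe"))
        assert ((frame["score"] >= 0) & (frame["score"] <= 1 + 1e-12)).all()
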