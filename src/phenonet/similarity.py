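"""Five disease-similarity measures between a query profile and a corpus.

Given a query profile :math:`A = \\{x_1, ..., x_N\\}` and a disease profile
:math:`B = \\{x_1, ..., x_M\\}` over a phenotype ontology:

* **Jaccard** — :math:`|A \\cap B| / |A \\cup B|`, plain term overlap.
* **Resnik** — term-pair similarity is the information content of the most
  informative common ancestor, :math:`sim(x_1, x_2) = \\max_{y \\in C(x_1,x_2)}
  IC(y)`; profile similarity aggregates pairs either as the plain average over
  the full pair grid or as the best-match average (BMA), which averages each
  profile's best match in the other and prevents a few high-IC terms from
  dominating.  BMA is the headline variant.
* **GraphIC** — expand both term sets with all their ancestors and take the
  ratio of summed IC over the intersection versus the union.
* **TF-IDF cosine** — each disease is a document, its terms are words, term
  frequency is the annotation frequency, and cosine similarity compares the
  weighted vectors.
* **TF-IDF with query expansion** — the query is first expanded over the whole
  ontology, giving every term :math:`y` the decayed frequency
  :math:`f_y = f_x \\alpha^{d(x,y)}` of its nearest query seed :math:`x`
  (undirected graph distance :math:`d`), which removes the zero-similarity
  floor of exact-overlap measures.

Frequencies weight only the TF-IDF vectors and the query expansion; Jaccard,
Resnik and GraphIC see bare term sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .corpus import DiseaseCorpus
from .errors import ConfigError, DataError
from .ontology import ICTable, Ontology
from .profile import QueryProfile

logger = logging.getLogger(__name__)

#: Headline method set; ``resnik_avg`` is additionally available for the
#: rank-correlation study.
DEFAULT_METHODS = ("jaccard", "resnik_bma", "graphic", "tfidf", "tfidf_qe")
ALL_METHODS = ("jaccard", "resnik_avg", "resnik_bma", "graphic", "tfidf", "tfidf_qe")

DEFAULT_ALPHA = 0.5
#: Decay factors evaluated in the sensitivity sweep.
ALPHA_SWEEP = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)


def _terms(profile) -> frozenset[str]:
    if isinstance(profile, (set, frozenset)):
        return frozenset(profile)
    return frozenset(profile.terms)


# ---------------------------------------------------------------------------
# Set and IC based measures


def jaccard(a, b) -> float:
    """Jaccard index of two term sets; 0 when both are empty."""
    sa, sb = _terms(a), _terms(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def resnik_term(x1: str, x2: str, ic: ICTable, ontology: Ontology) -> float:
    """IC of the most informative common ancestor of two terms (nats)."""
    common = ontology.ancestors(x1) & ontology.ancestors(x2)
    if not common:
        return 0.0
    return max(ic.get_ic(t) for t in common)


class _PairCache:
    """Memoizes symmetric term-pair Resnik similarities across diseases."""

    def __init__(self, ic: ICTable, ontology: Ontology) -> None:
        self.ic = ic
        self.ontology = ontology
        self._cache: dict[frozenset[str], float] = {}

    def sim(self, x1: str, x2: str) -> float:
        key = frozenset((x1, x2))
        val = self._cache.get(key)
        if val is None:
            val = resnik_term(x1, x2, self.ic, self.ontology)
            self._cache[key] = val
        return val

    def matrix(self, a: Iterable[str], b: Iterable[str]) -> np.ndarray:
        a, b = list(a), list(b)
        return np.array([[self.sim(x, y) for y in b] for x in a])


def resnik_avg(a, b, ic: ICTable, ontology: Ontology, _cache: _PairCache | None = None) -> float:
    """Mean term-pair Resnik similarity over the full N×M pair grid."""
    sa, sb = sorted(_terms(a)), sorted(_terms(b))
    if not sa or not sb:
        raise DataError("resnik_avg requires two non-empty profiles")
    cache = _cache or _PairCache(ic, ontology)
    return float(cache.matrix(sa, sb).mean())


def resnik_bma(a, b, ic: ICTable, ontology: Ontology, _cache: _PairCache | None = None) -> float:
    """Best-match average: ½·(mean of A's best matches in B + vice versa)."""
    sa, sb = sorted(_terms(a)), sorted(_terms(b))
    if not sa or not sb:
        raise DataError("resnik_bma requires two non-empty profiles")
    cache = _cache or _PairCache(ic, ontology)
    m = cache.matrix(sa, sb)
    return float(0.5 * (m.max(axis=1).mean() + m.max(axis=0).mean()))


def _expanded_set(terms: Iterable[str], ontology: Ontology) -> frozenset[str]:
    out: set[str] = set()
    for t in terms:
        out |= ontology.ancestors(t)
    return frozenset(out)


def graphic(a, b, ic: ICTable, ontology: Ontology) -> float:
    """GraphIC similarity: shared vs total IC over ancestor-expanded sets."""
    sa, sb = _terms(a), _terms(b)
    if not sa or not sb:
        raise DataError("graphic requires two non-empty profiles")
    ea, eb = _expanded_set(sa, ontology), _expanded_set(sb, ontology)
    denom = sum(ic.get_ic(t) for t in ea | eb)
    if denom == 0.0:
        logger.warning("graphic denominator is zero (all expanded terms have ic 0)")
        return 0.0
    num = sum(ic.get_ic(t) for t in ea & eb)
    return num / denom


# ---------------------------------------------------------------------------
# TF-IDF vectors


@dataclass(frozen=True)
class SimilarityVector:
    """Sparse TF-IDF weight vector over ontology terms."""

    weights: Mapping[str, float]

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


def cosine(u: SimilarityVector, v: SimilarityVector) -> float:
    """Cosine similarity of two weight vectors; 0 when either norm is 0."""
    nu, nv = u.norm(), v.norm()
    if nu == 0.0 or nv == 0.0:
        return 0.0
    small, large = (u.weights, v.weights) if len(u.weights) <= len(v.weights) else (v.weights, u.weights)
    dot = sum(w * large.get(t, 0.0) for t, w in small.items())
    return dot / (nu * nv)


def tfidf_vectors(
    corpus: DiseaseCorpus,
    query,
    tf_mode: str = "frequency",
) -> tuple[dict[str, SimilarityVector], SimilarityVector]:
    """TF-IDF vectors for every corpus disease and for the query.

    ``tf`` is the stored annotation frequency (``tf_mode="frequency"``,
    default) or 1 per annotated term (``"binary"``).  ``idf`` is the smoothed
    inverse document frequency ``log((1+N)/(1+df)) + 1`` with ``N`` the corpus
    size and ``df`` the number of diseases *directly* annotated to the term;
    the smoothing keeps idf positive, and query terms absent from the corpus
    vocabulary are retained at the ``df = 0`` value.
    """
    if tf_mode not in ("frequency", "binary"):
        raise ConfigError(f"unknown tf mode {tf_mode!r}")
    if len(corpus) == 0:
        raise DataError("tfidf_vectors requires a non-empty corpus")
    n = len(corpus)
    df = corpus.document_frequency()

    def idf(term: str) -> float:
        return math.log((1 + n) / (1 + df.get(term, 0))) + 1.0

    def vec(freqs: Mapping[str, float]) -> SimilarityVector:
        if tf_mode == "binary":
            return SimilarityVector({t: idf(t) for t in freqs})
        return SimilarityVector({t: f * idf(t) for t, f in freqs.items()})

    disease_vectors = {
        d.disease_id: vec({t: fv.value for t, fv in d.annotations.items()}) for d in corpus
    }
    if isinstance(query, ExpandedQuery):
        qfreqs: Mapping[str, float] = query.frequencies
    else:
        qfreqs = query.annotations
    return disease_vectors, vec(qfreqs)


# ---------------------------------------------------------------------------
# Query expansion


@dataclass(frozen=True)
class ExpandedQuery:
    """A query profile expanded over the ontology with decayed frequencies.

    Every reachable ontology term ``y`` carries ``f_y = f_x * alpha**d`` where
    ``x`` is the nearest query seed under undirected graph distance ``d``
    (equidistant seeds resolved toward the larger resulting frequency).
    Zero frequencies (``alpha = 0`` at ``d >= 1``) are not stored, so the
    support at ``alpha = 0`` is exactly the seed set.
    """

    base: QueryProfile
    alpha: float
    frequencies: dict[str, float]
    nearest_seed: dict[str, tuple[str, int]]

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.frequencies)


def expand_query(query: QueryProfile, ontology: Ontology, alpha: float = DEFAULT_ALPHA) -> ExpandedQuery:
    """Expand a query over the ontology with the decay rule ``f_y = f_x·α^d``.

    Seed terms keep their own frequency (``d = 0``, including at ``alpha = 0``
    under the ``0**0 = 1`` convention).  Expansion covers every ontology term
    reachable from a seed; pass an ontology already restricted to the
    phenotypic-abnormality subtree to keep the expansion in corpus scope.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError(f"alpha must lie in [0, 1], got {alpha}")
    for t in query.terms:
        if t not in ontology:
            raise DataError(f"query term {t!r} is not in the ontology")
    best: dict[str, tuple[int, float, str]] = {}  # y -> (d, f_y, seed)
    for seed in sorted(query.terms):
        f_seed = query.annotations[seed]
        for y, d in ontology.distances_from(seed).items():
            f_y = f_seed * alpha**d if d else f_seed
            cur = best.get(y)
            if cur is None or (d, -f_y) < (cur[0], -cur[1]):
                best[y] = (d, f_y, seed)
    frequencies = {y: f for y, (d, f, _s) in best.items() if f > 0.0 or d == 0}
    nearest = {y: (s, d) for y, (d, _f, s) in best.items()}
    return ExpandedQuery(base=query, alpha=alpha, frequencies=frequencies, nearest_seed=nearest)


# ---------------------------------------------------------------------------
# Scoring


def score_all(
    corpus: DiseaseCorpus,
    query: QueryProfile,
    ontology: Ontology,
    ic: ICTable,
    methods: Iterable[str] = DEFAULT_METHODS,
    alpha: float = DEFAULT_ALPHA,
    tf_mode: str = "frequency",
) -> pd.DataFrame:
    """Score every corpus disease against the query under each method.

    Returns a tidy frame with columns ``disease_id``, ``method``, ``score``;
    deterministic for identical inputs.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ConfigError(f"unknown method(s): {sorted(unknown)}; choose from {ALL_METHODS}")
    if len(corpus) == 0:
        raise DataError("score_all requires a non-empty corpus")
    cache = _PairCache(ic, ontology)
    rows: list[tuple[str, str, float]] = []
    plain_vectors = qvec = None
    if "tfidf" in methods:
        plain_vectors, qvec = tfidf_vectors(corpus, query, tf_mode)
    qe_vectors = qe_vec = None
    if "tfidf_qe" in methods:
        expanded = expand_query(query, ontology, alpha)
        qe_vectors, qe_vec = tfidf_vectors(corpus, expanded, tf_mode)
    for d in corpus:
        for m in methods:
            if m == "jaccard":
                s = jaccard(query, d)
            elif m == "resnik_avg":
                s = resnik_avg(query, d, ic, ontology, _cache=cache)
            elif m == "resnik_bma":
                s = resnik_bma(query, d, ic, ontology, _cache=cache)
            elif m == "graphic":
                s = graphic(query, d, ic, ontology)
            elif m == "tfidf":
                s = cosine(qvec, plain_vectors[d.disease_id])
            else:  # tfidf_qe
                s = cosine(qe_vec, qe_vectors[d.disease_id])
            rows.append((d.disease_id, m, float(s)))
    frame = pd.DataFrame(rows, columns=["disease_id", "method", "score"])
    for m in methods:
        n_zero = int((frame.loc[frame["method"] == m, "score"] == 0.0).sum())
        logger.info("method %s: %d zero-score disease(s)", m, n_zero)
    return frame
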