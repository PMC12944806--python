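"""Rankings, weighted rank correlation, consensus aggregation and
high-level disease-category classification.

Rank agreement is measured with a weighted Kendall τ using additive
hyperbolic weights — rank ``r`` (0-based) is weighted ``1/(r+1)``, so
exchanges near the top of the rankings count more — symmetrized by averaging
the statistic computed with each ranking supplying the reference ranks.  The
pipeline uses :func:`scipy.stats.weightedtau`, whose default contract is
exactly this; :func:`weighted_tau_reference` is a direct O(n²) enumeration of
the same definition, kept as an independent check.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import weightedtau

from .errors import ConfigError, DataError
from .ontology import Ontology

logger = logging.getLogger(__name__)

#: Method set aggregated into the consensus: of the two TF-IDF rankings only
#: the query-expanded one is kept.
CONSENSUS_METHODS = ("jaccard", "resnik_bma", "graphic", "tfidf_qe")

#: Default number of top diseases classified into high-level categories.
DEFAULT_TOP_K = 50


@dataclass(frozen=True)
class MethodRanking:
    """Diseases ordered by one method's score, ranks 1..n without gaps.

    Tie policy: stable descending sort on score with ties broken by
    lexicographic disease id.
    """

    method: str
    entries: tuple[tuple[str, float, int], ...]  # (disease_id, score, rank)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def rank_of(self, disease_id: str) -> int:
        for did, _s, r in self.entries:
            if did == disease_id:
                return r
        raise KeyError(disease_id)

    def scores(self) -> dict[str, float]:
        return {did: s for did, s, _r in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["disease_id", "score", "rank"])

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("rank\tdisease_id\tscore\n")
        for did, s, r in self.entries:
            stream.write(f"{r}\t{did}\t{s:.10g}\n")


def rank(scores, method: str = "score") -> MethodRanking:
    """Order diseases by descending score with the deterministic tie policy.

    ``scores`` is a mapping or an iterable of (disease_id, score) pairs; a
    repeated disease id is an error.
    """
    pairs = list(scores.items()) if isinstance(scores, Mapping) else list(scores)
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"duplicate disease id(s) in score table: {dupes}")
    ordered = sorted(pairs, key=lambda kv: (-kv[1], kv[0]))
    entries = tuple((did, float(s), i + 1) for i, (did, s) in enumerate(ordered))
    return MethodRanking(method=method, entries=entries)


def rankings_from_scores(frame: pd.DataFrame) -> dict[str, MethodRanking]:
    """Split a tidy (disease_id, method, score) frame into per-method rankings."""
    out: dict[str, MethodRanking] = {}
    for m, sub in frame.groupby("method", sort=True):
        out[m] = rank(dict(zip(sub["disease_id"], sub["score"])), method=m)
    return out


# ---------------------------------------------------------------------------
# Weighted Kendall tau


def _aligned_rank_vectors(r1: MethodRanking, r2: MethodRanking) -> tuple[np.ndarray, np.ndarray]:
    s1, s2 = set(r1.disease_ids), set(r2.disease_ids)
    if s1 != s2:
        diff = sorted(s1 ^ s2)
        raise DataError(f"rankings cover different disease sets; symmetric difference {diff}")
    ids = sorted(s1)
    rank1 = {did: r for did, _s, r in r1.entries}
    rank2 = {did: r for did, _s, r in r2.entries}
    # negate so that larger = better, the orientation weightedtau expects
    x = np.array([-rank1[d] for d in ids], dtype=float)
    y = np.array([-rank2[d] for d in ids], dtype=float)
    return x, y


def weighted_kendall_tau(r1: MethodRanking, r2: MethodRanking) -> float:
    """Symmetrized hyperbolically weighted Kendall τ between two rankings."""
    x, y = _aligned_rank_vectors(r1, r2)
    if len(x) < 2:
        return 1.0
    return float(weightedtau(x, y, rank=True).statistic)


def weighted_tau_reference(x: Sequence[float], y: Sequence[float]) -> float:
    """O(n²) pair enumeration of the weighted τ definition (test oracle).

    ``x`` and ``y`` are score vectors over the same items.  For each choice of
    reference vector, items are ranked by decreasing value (ties broken by the
    other vector, then left as equal weight order), each pair (i, j) is
    weighted ``w(r_i) + w(r_j)`` with ``w(r) = 1/(r+1)`` on 0-based ranks, and
    τ is the weight-normalized sum of concordance signs; the two directed
    statistics are averaged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0

    def directed(a: np.ndarray, b: np.ndarray) -> float:
        order = sorted(range(n), key=lambda i: (-a[i], -b[i]))
        rnk = np.empty(n, dtype=int)
        for pos, i in enumerate(order):
            rnk[i] = pos
        w = 1.0 / (1.0 + rnk)
        num = den = 0.0
        for i, j in itertools.combinations(range(n), 2):
            wij = w[i] + w[j]
            num += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j]) * wij
            den += wij
        return num / den

    return 0.5 * (directed(x, y) + directed(y, x))


def tau_matrix(rankings: Mapping[str, MethodRanking]) -> pd.DataFrame:
    """Symmetric matrix of pairwise weighted τ between named rankings."""
    names = list(rankings)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        t = weighted_kendall_tau(rankings[a], rankings[b])
        mat.loc[a, b] = mat.loc[b, a] = t
    return mat


# ---------------------------------------------------------------------------
# Aggregation


@dataclass(frozen=True)
class ConsensusRanking:
    """Equal-weight aggregate of several method rankings, top score 1."""

    entries: tuple[tuple[str, float, int], ...]
    methods_used: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["disease_id", "score", "rank"])

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("rank\tdisease_id\tscore\n")
        for did, s, r in self.entries:
            stream.write(f"{r}\t{did}\t{s:.10g}\n")

    def as_method_ranking(self) -> MethodRanking:
        return MethodRanking(method="consensus", entries=self.entries)


def aggregate(
    rankings: Sequence[MethodRanking],
    scheme: str = "score",
) -> ConsensusRanking:
    """Aggregate ≥2 rankings with equal weight per method.

    ``scheme="score"`` (default): each method's scores are normalized by that
    method's maximum and averaged; the final scores are renormalized so the
    top disease has score 1.  ``scheme="borda"``: the per-method quantity
    averaged is ``1 - (rank-1)/(n-1)`` instead.  Invariant to the order in
    which the rankings are supplied.
    """
    if len(rankings) < 2:
        raise ConfigError("aggregation requires at least two rankings")
    if scheme not in ("score", "borda"):
        raise ConfigError(f"unknown aggregation scheme {scheme!r}")
    base = set(rankings[0].disease_ids)
    for r in rankings[1:]:
        if set(r.disease_ids) != base:
            raise DataError("rankings cover different disease sets")
    # canonical accumulation order makes the result invariant to supply order
    rankings = sorted(rankings, key=lambda r: r.method)
    agg: dict[str, float] = {d: 0.0 for d in base}
    for r in rankings:
        if scheme == "score":
            smax = max((s for _d, s, _r in r.entries), default=0.0)
            for did, s, _rk in r.entries:
                agg[did] += (s / smax if smax > 0 else 0.0)
        else:
            n = len(r)
            for did, _s, rk in r.entries:
                agg[did] += 1.0 - (rk - 1) / (n - 1) if n > 1 else 1.0
    nmeth = len(rankings)
    agg = {d: v / nmeth for d, v in agg.items()}
    ranked = rank(agg, method="consensus")
    top = ranked.entries[0][1] if ranked.entries else 0.0
    entries = tuple(
        (did, s / top if top > 0 else 0.0, rk) for did, s, rk in ranked.entries
    )
    return ConsensusRanking(entries=entries, methods_used=tuple(sorted(r.method for r in rankings)))


# ---------------------------------------------------------------------------
# Category classification


@dataclass(frozen=True)
class CategoryHistogram:
    """Counts of top-K diseases reaching each high-level disease category."""

    counts: dict[str, int]
    k: int
    n_unclassified: int = 0

    def to_frame(self, names: Mapping[str, str] | None = None) -> pd.DataFrame:
        rows = [
            (cat, (names or {}).get(cat, cat), n)
            for cat, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["category", "name", "count"])


def classify_categories(
    consensus: ConsensusRanking,
    mondo: Ontology,
    k: int = DEFAULT_TOP_K,
) -> CategoryHistogram:
    """Histogram the top-K consensus diseases over high-level disease classes.

    The category set is the set of direct children of the disease-ontology
    root (the "main disease classes").  Each disease contributes at most once
    per category, tracing every path from its term to the root; diseases whose
    ids are not in the ontology are skipped and counted separately.
    """
    if k > len(consensus):
        logger.warning("top-K %d exceeds ranking size %d; capping", k, len(consensus))
        k = len(consensus)
    categories = mondo.children(mondo.root)
    logger.info("using %d top-level disease categories", len(categories))
    xref_index: dict[str, str] = {}
    for term in mondo:
        for x in mondo.xrefs.get(term, ()):
            xref_index.setdefault(x, term)
    counts: dict[str, int] = {c: 0 for c in sorted(categories)}
    n_unclassified = 0
    for did, _s, _r in consensus.entries[:k]:
        cid = mondo.canonical(did)
        if cid not in mondo:
            cid = xref_index.get(did, "")
        if cid not in mondo:
            n_unclassified += 1
            continue
        for cat in mondo.ancestors(cid) & categories:
            counts[cat] += 1
    return CategoryHistogram(counts=counts, k=k, n_unclassified=n_unclassified)


# ---------------------------------------------------------------------------
# Alpha sensitivity


def alpha_sensitivity(
    corpus,
    query,
    ontology: Ontology,
    ic,
    alphas: Iterable[float] = None,
    tf_mode: str = "frequency",
) -> pd.DataFrame:
    """Pairwise weighted τ between query-expanded TF-IDF rankings across α.

    Reproduces the decay-factor sensitivity procedure: one ranking per α,
    compared pairwise; the result is a symmetric matrix with unit diagonal
    indexed by α.
    """
    from .similarity import ALPHA_SWEEP, score_all

    alphas = tuple(ALPHA_SWEEP if alphas is None else alphas)
    if not alphas:
        raise ConfigError("alpha_sensitivity requires at least one alpha")
    rankings: dict[str, MethodRanking] = {}
    for a in alphas:
        frame = score_all(corpus, query, ontology, ic, methods=("tfidf_qe",), alpha=a, tf_mode=tf_mode)
        sub = frame[frame["method"] == "tfidf_qe"]
        rankings[f"{a:g}"] = rank(dict(zip(sub["disease_id"], sub["score"])), method=f"tfidf_qe@{a:g}")
    return tau_matrix(rankings)
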