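"""Model/Results facade over the similarity-ranking pipeline.

:class:`PhenotypeSimilarity` is built from data (a disease corpus, a
phenotype ontology and a query profile, with optional disease-ontology for
identifier unification and category classification); ``fit()`` runs the
scoring and ranking stages and returns a :class:`PhenotypeSimilarityResults`
carrying the score table, the per-method rankings, the rank-correlation
matrix, the equal-weight consensus and diagnostics, with a ``summary()``
table in the usual statistical-modelling style.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable

import pandas as pd

from .corpus import DiseaseCorpus, build_corpus, filter_phenotypic, parse_hpoa
from .errors import ConfigError
from .ontology import ICTable, Ontology, compute_ic, parse_obo
from .profile import QueryProfile, load_profile
from .ranking import (
    CONSENSUS_METHODS,
    DEFAULT_TOP_K,
    CategoryHistogram,
    ConsensusRanking,
    MethodRanking,
    aggregate,
    alpha_sensitivity,
    classify_categories,
    rankings_from_scores,
    tau_matrix,
)
from .similarity import ALL_METHODS, DEFAULT_ALPHA, DEFAULT_METHODS, score_all


class PhenotypeSimilarity:
    """Phenotypic-similarity ranking of a disease corpus against a query.

    Parameters
    ----------
    corpus :
        Normalized disease corpus.
    ontology :
        Phenotype ontology (already restricted to the phenotypic-abnormality
        subtree where applicable).
    query :
        The query symptom profile with frequencies.
    mondo :
        Optional disease ontology for category classification of the top
        consensus diseases.
    methods, alpha, tf_mode :
        Similarity methods to run, query-expansion decay factor and TF-IDF
        term-frequency mode.
    """

    def __init__(
        self,
        corpus: DiseaseCorpus,
        ontology: Ontology,
        query: QueryProfile,
        mondo: Ontology | None = None,
        methods: Iterable[str] = DEFAULT_METHODS,
        alpha: float = DEFAULT_ALPHA,
        tf_mode: str = "frequency",
        ic: ICTable | None = None,
    ) -> None:
        self.corpus = corpus
        self.ontology = ontology
        self.query = query
        self.mondo = mondo
        self.methods = tuple(methods)
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ConfigError(f"unknown method(s) {sorted(unknown)}")
        self.alpha = alpha
        self.tf_mode = tf_mode
        self.ic = ic if ic is not None else compute_ic(ontology, corpus)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        hpoa: IO[str] | str,
        hp_obo: IO[str] | str,
        profile: IO[str] | str,
        mondo_obo: IO[str] | str | None = None,
        phenotype_subroot: str | None = None,
        unknown_default: float = 0.5,
        **kwargs,
    ) -> "PhenotypeSimilarity":
        """Build the model from raw input files (OBO, HPOA, profile TSV)."""
        ontology = parse_obo(hp_obo)
        if phenotype_subroot is not None:
            ontology = ontology.restrict_to_subtree(phenotype_subroot)
        mondo = parse_obo(mondo_obo) if mondo_obo is not None else None
        annotations = filter_phenotypic(parse_hpoa(hpoa), ontology)
        corpus = build_corpus(
            annotations, ontology, mondo=mondo, unknown_default=unknown_default
        )
        query = load_profile(profile)
        return cls(corpus, ontology, query, mondo=mondo, **kwargs)

    @classmethod
    def from_synthetic(cls, config=None, seed: int | None = None, **kwargs) -> "PhenotypeSimilarity":
        """Build the model from the seeded synthetic benchmark generator."""
        from .synthetic_data import SyntheticConfig, generate_all

        if config is None:
            config = SyntheticConfig(seed=0 if seed is None else seed)
        elif seed is not None:
            raise ConfigError("pass either a config or a seed, not both")
        bundle = generate_all(config)
        annotations = filter_phenotypic(parse_hpoa(bundle["corpus_text"]), bundle["ontology"])
        corpus = build_corpus(annotations, bundle["ontology"])
        model = cls(corpus, bundle["ontology"], bundle["query"], mondo=bundle["mondo"], **kwargs)
        model.answer_key = bundle["answer_key"]
        return model

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "PhenotypeSimilarityResults":
        """Score every disease under every method and rank the results."""
        scores = score_all(
            self.corpus,
            self.query,
            self.ontology,
            self.ic,
            methods=self.methods,
            alpha=self.alpha,
            tf_mode=self.tf_mode,
        )
        rankings = rankings_from_scores(scores)
        return PhenotypeSimilarityResults(model=self, scores=scores, rankings=rankings)


@dataclass
class PhenotypeSimilarityResults:
    """Fitted similarity rankings with diagnostics.

    Attributes
    ----------
    scores : pandas.DataFrame
        Tidy (disease_id, method, score) table.
    rankings : dict[str, MethodRanking]
        One deterministic ranking per method.
    """

    model: PhenotypeSimilarity
    scores: pd.DataFrame
    rankings: dict[str, MethodRanking]
    _consensus: ConsensusRanking | None = field(default=None, repr=False)

    def tau_matrix(self) -> pd.DataFrame:
        """Pairwise weighted Kendall τ between the method rankings."""
        return tau_matrix(self.rankings)

    def consensus(self, methods: Iterable[str] | None = None, scheme: str = "score") -> ConsensusRanking:
        """Equal-weight consensus over the headline methods (cached for defaults)."""
        if methods is None:
            methods = [m for m in CONSENSUS_METHODS if m in self.rankings]
            if scheme == "score" and self._consensus is not None:
                return self._consensus
            result = aggregate([self.rankings[m] for m in methods], scheme=scheme)
            if scheme == "score":
                self._consensus = result
            return result
        return aggregate([self.rankings[m] for m in methods], scheme=scheme)

    def categories(self, k: int = DEFAULT_TOP_K) -> CategoryHistogram:
        """Top-K consensus diseases histogrammed over disease categories."""
        if self.model.mondo is None:
            raise ConfigError("category classification requires a disease ontology")
        return classify_categories(self.consensus(), self.model.mondo, k=k)

    def alpha_sensitivity(self, alphas: Iterable[float] | None = None) -> pd.DataFrame:
        """τ matrix between query-expanded TF-IDF rankings across decay factors."""
        return alpha_sensitivity(
            self.model.corpus,
            self.model.query,
            self.model.ontology,
            self.model.ic,
            alphas=alphas,
            tf_mode=self.model.tf_mode,
        )

    def zero_score_counts(self) -> dict[str, int]:
        """Number of zero-score diseases per method (the query-expansion diagnostic)."""
        out: dict[str, int] = {}
        for m in self.model.methods:
            sub = self.scores[self.scores["method"] == m]
            out[m] = int((sub["score"] == 0.0).sum())
        return out

    def top(self, method: str, n: int = 10) -> pd.DataFrame:
        return self.rankings[method].to_frame().head(n)

    def summary(self, top_n: int = 5) -> str:
        """Human-readable run summary: setup, diagnostics, top hits, τ matrix."""
        m = self.model
        buf = io.StringIO()
        buf.write("Phenotype similarity ranking\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"Query:            {m.query.label} ({len(m.query)} terms)\n")
        buf.write(f"Corpus:           {len(m.corpus)} diseases, ")
        buf.write(f"{sum(len(d.annotations) for d in m.corpus)} annotations\n")
        buf.write(f"Ontology:         {len(m.ontology)} terms, {m.ontology.n_edges} edges\n")
        buf.write(f"Methods:          {', '.join(m.methods)}\n")
        buf.write(f"Decay factor α:   {m.alpha:g}\n")
        buf.write("\nZero-score diseases per method:\n")
        for meth, nz in self.zero_score_counts().items():
            buf.write(f"  {meth:<12s} {nz}\n")
        for meth in m.methods:
            buf.write(f"\nTop {top_n} ({meth}):\n")
            for did, s, r in self.rankings[meth].entries[:top_n]:
                name = m.corpus[did].name if did in m.corpus else did
                buf.write(f"  {r:>3d}. {did:<16s} {s:8.4f}  {name}\n")
        cons = self.consensus()
        buf.write(f"\nConsensus (equal weight over {', '.join(cons.methods_used)}):\n")
        for did, s, r in cons.entries[:top_n]:
            name = m.corpus[did].name if did in m.corpus else did
            buf.write(f"  {r:>3d}. {did:<16s} {s:8.4f}  {name}\n")
        buf.write("\nWeighted Kendall τ between method rankings:\n")
        buf.write(self.tau_matrix().round(3).to_string())
        buf.write("\n")
        return buf.getvalue()
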