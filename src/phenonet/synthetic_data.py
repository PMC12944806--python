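"""Seeded generators for ontologies, annotation corpora and query profiles.

These emulate the statistical structure of the real inputs — a rooted
multi-parent DAG of phenotype terms, diseases annotated to 3-50 terms drawn
with a popularity bias (power law with exponent 1 over term index, which
reproduces the broad document-frequency spread TF-IDF needs), and frequency
cells in the four real-world formats (fractions with denominators 5-200,
percentages, frequency-class terms, absent) — without downloading any
ontology release.  "Planted" diseases with controlled overlap against the
query (exact clone, fractional overlap, ancestor-shifted) provide known
answers for recovery tests.  Every generator is a pure function of its
configuration and seed: identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .corpus import load_frequency_classes
from .errors import ConfigError
from .ontology import Ontology
from .profile import QueryProfile

_CLASS_TERMS = tuple(
    t for t, (lo, hi) in sorted(load_frequency_classes().items()) if hi > 0
)

HPOA_HEADER = (
    "database_id\tdisease_name\tqualifier\thpo_id\treference\tevidence\t"
    "onset\tfrequency\tsex\tmodifier\taspect\tbiocuration"
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults follow the recovery-benchmark conditions used throughout the
    package: a 150-term DAG with up to 2 parents per term, 200 background
    diseases annotated with 3-50 terms each, the four frequency formats in
    realistic proportions, 10% conflicting duplicate annotations, and a
    12-term query with one planted clone, one 50%-overlap disease and one
    ancestor-shifted disease.
    """

    n_terms: int = 150
    max_parents: int = 2
    n_diseases: int = 200
    annotations_per_disease: tuple[int, int] = (3, 50)
    frequency_mix: dict = field(
        default_factory=lambda: {"fraction": 0.4, "percent": 0.25, "class": 0.15, "absent": 0.2}
    )
    duplicate_fraction: float = 0.1
    n_query_terms: int = 12
    planted: tuple[tuple[str, float], ...] = (
        ("clone", 1.0),
        ("overlap", 0.5),
        ("ancestor_shift", 1.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.frequency_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("frequency_mix proportions must sum to 1")
        for kind, q in self.planted:
            if kind not in ("clone", "overlap", "ancestor_shift"):
                raise ConfigError(f"unknown planted kind {kind!r}")
            if not 0.0 <= q <= 1.0:
                raise ConfigError(f"planted overlap fraction {q} outside [0, 1]")


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def generate_ontology(config: SyntheticConfig) -> Ontology:
    """Random rooted DAG: term i > 0 draws 1..max_parents parents among 0..i-1.

    Acyclic by construction (edges only point toward lower indices).
    """
    if config.n_terms < 2:
        raise ConfigError("need at least 2 terms (root + one child)")
    rng = np.random.default_rng(config.seed)
    parents: dict[str, list[str]] = {_term_id(0): []}
    names = {_term_id(0): "synthetic phenotypic abnormality (root)"}
    for i in range(1, config.n_terms):
        k = int(rng.integers(1, min(config.max_parents, i) + 1))
        ps = rng.choice(i, size=k, replace=False)
        parents[_term_id(i)] = [_term_id(int(p)) for p in sorted(ps)]
        names[_term_id(i)] = f"synthetic term {i}"
    return Ontology(parents, names=names)


def _format_frequency(v: float, fmt: str, rng: np.random.Generator) -> str:
    if fmt == "absent":
        return ""
    if fmt == "fraction":
        den = int(rng.integers(5, 201))
        num = min(den, max(1, round(v * den)))
        return f"{num}/{den}"
    if fmt == "percent":
        return f"{v * 100:.1f}%"
    # class: the shipped class whose interval contains v, else the nearest
    table = load_frequency_classes()
    for term in _CLASS_TERMS:
        lo, hi = table[term]
        if lo <= v <= hi:
            return term
    return min(_CLASS_TERMS, key=lambda t: abs(v - (table[t][0] + table[t][1]) / 2))


def _popularity_weights(n_terms: int) -> np.ndarray:
    # power law with exponent 1 over term index; root (index 0) excluded
    w = 1.0 / np.arange(1, n_terms)
    return w / w.sum()


def _sample_profile(
    rng: np.random.Generator, ontology: Ontology, config: SyntheticConfig
) -> list[str]:
    lo, hi = config.annotations_per_disease
    if hi >= config.n_terms:
        raise ConfigError("annotations_per_disease upper bound must be below n_terms")
    n_ann = int(rng.integers(lo, hi + 1))
    weights = _popularity_weights(config.n_terms)
    idx = rng.choice(np.arange(1, config.n_terms), size=n_ann, replace=False, p=weights)
    return [_term_id(int(i)) for i in sorted(idx)]


def _annotation_rows(
    disease_id: str,
    name: str,
    term_freqs: Iterable[tuple[str, str]],
) -> list[str]:
    return [
        f"{disease_id}\t{name}\t\t{term}\tPMID:0\tTAS\t\t{freq}\t\t\tP\tsynthetic[2026]"
        for term, freq in term_freqs
    ]


def generate_corpus(ontology: Ontology, config: SyntheticConfig) -> str:
    """HPOA-dialect annotation text for ``n_diseases`` synthetic diseases.

    Frequencies are drawn from Beta(2, 2) and emitted in the four formats per
    ``frequency_mix``; a ``duplicate_fraction`` of disease-term pairs gets a
    second row with an independently drawn frequency so duplicate merging is
    exercised.  The output parses losslessly through ``parse_hpoa``.
    """
    rng = np.random.default_rng(config.seed + 1)
    fmts = sorted(config.frequency_mix)
    probs = np.array([config.frequency_mix[f] for f in fmts])
    lines = ["# synthetic disease-phenotype annotations", HPOA_HEADER]
    for j in range(config.n_diseases):
        did = f"OMIM:{600000 + j}"
        name = f"synthetic disease {j}"
        terms = _sample_profile(rng, ontology, config)
        rows: list[tuple[str, str]] = []
        for t in terms:
            v = float(rng.beta(2, 2))
            fmt = str(rng.choice(fmts, p=probs))
            rows.append((t, _format_frequency(v, fmt, rng)))
            if rng.random() < config.duplicate_fraction:
                v2 = float(rng.beta(2, 2))
                fmt2 = str(rng.choice(fmts, p=probs))
                rows.append((t, _format_frequency(v2, fmt2, rng)))
        lines.extend(_annotation_rows(did, name, rows))
    return "\n".join(lines) + "\n"


def plant_query(
    corpus_text: str,
    ontology: Ontology,
    config: SyntheticConfig,
) -> tuple[QueryProfile, str, dict]:
    """Draw a query profile and append planted diseases to the corpus text.

    Planted kinds: ``clone`` (identical term set and frequencies),
    ``overlap`` (fraction q of the query terms, the rest random non-query
    terms), ``ancestor_shift`` (every query term replaced by its nearest
    strict ancestor outside the query, so exact-overlap similarity vanishes
    while ancestor-aware similarity survives).  Returns the profile, the
    augmented corpus text and an answer key recording the planted ids and the
    intended ordering clone > overlap > background.
    """
    rng = np.random.default_rng(config.seed + 2)
    deep = sorted(t for t in ontology if ontology.depth(t) >= 2)
    if len(deep) < config.n_query_terms:
        raise ConfigError("ontology too shallow for the requested query size")
    q_terms = [deep[int(i)] for i in rng.choice(len(deep), size=config.n_query_terms, replace=False)]
    q_terms.sort()
    freqs = {t: round(float(rng.beta(2, 2)), 6) for t in q_terms}
    query = QueryProfile(label="synthetic query", annotations=freqs)

    lines = corpus_text.rstrip("\n").split("\n")
    key: dict = {"query_terms": q_terms, "planted": {}, "background": []}
    for ln in lines:
        if ln.startswith("#") or ln.startswith("database_id"):
            continue
        did = ln.split("\t", 1)[0]
        if did not in key["background"]:
            key["background"].append(did)

    non_query = sorted(set(ontology.terms) - set(q_terms) - {ontology.root})
    for idx, (kind, q) in enumerate(config.planted):
        did = f"OMIM:{900000 + idx}"
        name = f"planted {kind}"
        if kind == "clone":
            terms = list(q_terms)
            rows = [(t, f"{freqs[t] * 100:.4f}%") for t in terms]
        elif kind == "overlap":
            n_keep = max(1, math.ceil(q * len(q_terms)))
            if q * len(q_terms) < 1:
                logging.getLogger(__name__).warning(
                    "overlap fraction %g keeps less than one term; rounding up", q
                )
            keep = [q_terms[int(i)] for i in rng.choice(len(q_terms), size=n_keep, replace=False)]
            n_fill = len(q_terms) - n_keep
            fill = [non_query[int(i)] for i in rng.choice(len(non_query), size=n_fill, replace=False)]
            terms = sorted(set(keep) | set(fill))
            rows = [(t, f"{float(rng.beta(2, 2)) * 100:.1f}%") for t in terms]
        else:  # ancestor_shift
            shifted: set[str] = set()
            for t in q_terms:
                anc = _nearest_outside_ancestor(ontology, t, set(q_terms))
                shifted.add(anc)
            terms = sorted(shifted - set(q_terms))
            rows = [(t, f"{float(rng.beta(2, 2)) * 100:.1f}%") for t in terms]
        lines.extend(_annotation_rows(did, name, rows))
        key["planted"][kind] = {"disease_id": did, "q": q, "terms": terms}
    return query, "\n".join(lines) + "\n", key


def _nearest_outside_ancestor(ontology: Ontology, term: str, exclude: set[str]) -> str:
    """Closest strict ancestor of ``term`` not in ``exclude`` (root fallback)."""
    frontier = [term]
    seen = {term}
    while frontier:
        nxt: list[str] = []
        for t in frontier:
            for p in sorted(ontology.parents(t)):
                if p in seen:
                    continue
                if p not in exclude:
                    return p
                seen.add(p)
                nxt.append(p)
        frontier = nxt
    return ontology.root


def generate_mondo(
    disease_ids: Iterable[str],
    n_categories: int = 6,
    seed: int = 0,
) -> Ontology:
    """Synthetic disease-ontology stand-in for category classification.

    A root, ``n_categories`` top-level category terms, and one term per
    supplied disease id attached under 1-2 categories with an xref back to
    the source id (so identifier unification is exercised too).
    """
    rng = np.random.default_rng(seed)
    root = "MONDO:0000001"
    parents: dict[str, list[str]] = {root: []}
    names = {root: "synthetic disease or disorder (root)"}
    xrefs: dict[str, tuple[str, ...]] = {}
    cats = []
    for c in range(n_categories):
        cid = f"MONDO:{1000 + c:07d}"
        parents[cid] = [root]
        names[cid] = f"synthetic disease category {c}"
        cats.append(cid)
    for i, did in enumerate(sorted(disease_ids)):
        mid = f"MONDO:{100000 + i:07d}"
        k = int(rng.integers(1, 3))
        chosen = rng.choice(n_categories, size=k, replace=False)
        parents[mid] = [cats[int(c)] for c in sorted(chosen)]
        names[mid] = f"synthetic disease for {did}"
        xrefs[mid] = (did,)
    return Ontology(parents, names=names, xrefs=xrefs)


def generate_all(config: SyntheticConfig) -> dict:
    """One-call benchmark bundle: ontology, corpus text, query, answer key, mondo."""
    ontology = generate_ontology(config)
    corpus_text = generate_corpus(ontology, config)
    query, corpus_text, key = plant_query(corpus_text, ontology, config)
    all_ids = key["background"] + [v["disease_id"] for v in key["planted"].values()]
    mondo = generate_mondo(all_ids, seed=config.seed + 3)
    return {
        "ontology": ontology,
        "corpus_text": corpus_text,
        "query": query,
        "answer_key": key,
        "mondo": mondo,
    }
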