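"""Rooted DAG of phenotype terms with ancestor, path and information-content services.

The ontology is a directed acyclic graph whose nodes are terms (e.g. phenotypic
abnormalities) and whose edges are ``is_a`` relations pointing from a child to
its parents.  A term may have several parents, so ancestor sets are computed by
graph reachability rather than by walking a tree.  Two conventions used
throughout the package are fixed here:

* ancestor sets are **self-inclusive**: ``x in ancestors(x)``;
* path distances are **undirected** edge counts, so a path may ascend through a
  common ancestor and descend again.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx
import obonet

from .errors import DataError

#: Sentinel returned by :meth:`Ontology.shortest_path_length` for disconnected
#: term pairs.  ``math.inf`` compares greater than every integer distance.
UNREACHABLE = math.inf


class Ontology:
    """A rooted DAG of terms linked by ``is_a`` edges.

    Parameters
    ----------
    parents :
        Mapping from each term to the ids of its parents.  The (single) term
        with no parents is the root.
    names :
        Optional display names per term.
    alt_ids :
        Mapping from alternative (merged) ids to primary ids; lookups through
        :meth:`canonical` resolve them transparently.
    xrefs :
        Cross-references per term, kept verbatim so a disease ontology can be
        used to unify external disease identifiers.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
        alt_ids: Mapping[str, str] | None = None,
        xrefs: Mapping[str, tuple[str, ...]] | None = None,
    ) -> None:
        graph = nx.DiGraph()
        for term, ps in parents.items():
            graph.add_node(term)
            for p in ps:
                graph.add_edge(term, p)  # child -> parent
        if graph.number_of_nodes() == 0:
            raise DataError("ontology has no terms")
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise DataError(f"is_a cycle detected involving term {cycle[0][0]!r}")
        roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise DataError(f"expected exactly one root term, found {sorted(roots)!r}")
        self._graph = graph
        self.root: str = roots[0]
        self.names: dict[str, str] = {t: (names or {}).get(t, t) for t in graph.nodes}
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self.xrefs: dict[str, tuple[str, ...]] = {
            t: tuple((xrefs or {}).get(t, ())) for t in graph.nodes
        }
        self._undirected = graph.to_undirected(as_view=True)
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- basic queries ------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def __iter__(self) -> Iterator[str]:
        return iter(self._graph.nodes)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def canonical(self, term: str) -> str:
        """Resolve an alt_id to its primary id; primary ids pass through."""
        return self.alt_ids.get(term, term)

    def _require(self, term: str) -> str:
        term = self.canonical(term)
        if term not in self._graph:
            raise DataError(f"unknown ontology term {term!r}")
        return term

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._graph.successors(self._require(term)))

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._graph.predecessors(self._require(term)))

    # -- reachability -------------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable via parent edges, *including* ``term`` itself."""
        term = self._require(term)
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term)) | {term}
            self._ancestor_cache[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        """All terms whose ancestor set contains ``term`` (self-inclusive)."""
        term = self._require(term)
        return frozenset(nx.ancestors(self._graph, term)) | {term}

    def shortest_path_length(self, x: str, y: str) -> int | float:
        """Edge count of the shortest path between two terms, edges undirected.

        A path may climb to a shared ancestor and descend again, matching how
        distances between sibling branches of the DAG are measured.  Returns
        :data:`UNREACHABLE` for disconnected pairs (possible only in synthetic
        multi-component graphs; a rooted ontology is always connected).
        """
        x, y = self._require(x), self._require(y)
        try:
            return nx.shortest_path_length(self._undirected, x, y)
        except nx.NetworkXNoPath:
            return UNREACHABLE

    def distances_from(self, seed: str) -> dict[str, int]:
        """Undirected BFS distances from ``seed`` to every reachable term."""
        seed = self._require(seed)
        return dict(nx.single_source_shortest_path_length(self._undirected, seed))

    def depth(self, term: str) -> int:
        """Minimal number of parent edges from ``term`` up to the root."""
        term = self._require(term)
        return nx.shortest_path_length(self._graph, term, self.root)

    def restrict_to_subtree(self, subroot: str) -> "Ontology":
        """Induced sub-DAG on the descendants of ``subroot`` (which becomes root)."""
        subroot = self._require(subroot)
        keep = self.descendants(subroot)
        parents = {
            t: [p for p in self._graph.successors(t) if p in keep] for t in keep
        }
        alt = {a: p for a, p in self.alt_ids.items() if p in keep}
        return Ontology(
            parents,
            names={t: self.names[t] for t in keep},
            alt_ids=alt,
            xrefs={t: self.xrefs[t] for t in keep},
        )

    # -- i/o ----------------------------------------------------------------

    @classmethod
    def from_obo(cls, stream: IO[str] | str) -> "Ontology":
        return parse_obo(stream)

    def to_obo(self, stream: IO[str]) -> None:
        """Write the ontology back out as OBO 1.2 ``[Term]`` stanzas."""
        stream.write("format-version: 1.2\nontology: phenonet-synthetic\n")
        primary_alts: dict[str, list[str]] = {}
        for alt, primary in self.alt_ids.items():
            primary_alts.setdefault(primary, []).append(alt)
        for term in sorted(self._graph.nodes):
            stream.write(f"\n[Term]\nid: {term}\nname: {self.names[term]}\n")
            for alt in sorted(primary_alts.get(term, ())):
                stream.write(f"alt_id: {alt}\n")
            for xref in self.xrefs[term]:
                stream.write(f"xref: {xref}\n")
            for parent in sorted(self._graph.successors(term)):
                stream.write(f"is_a: {parent} ! {self.names[parent]}\n")

    def summary(self) -> dict:
        """Term/edge counts and depth, serializable as JSON."""
        max_depth = max(self.depth(t) for t in self._graph.nodes)
        return {
            "n_terms": len(self),
            "n_edges": self.n_edges,
            "root": self.root,
            "max_depth": max_depth,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), sort_keys=True)


def parse_obo(stream: IO[str] | str) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Recognized tags: ``id``, ``name``, ``is_a``, ``alt_id``, ``xref`` and
    ``is_obsolete`` (obsolete stanzas are dropped).  Other relationship types,
    logical definitions and imports are ignored.  A stanza without an ``id``
    or an ``is_a`` cycle is a hard error.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    _check_stanza_ids(text)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            graph = obonet.read_obo(io.StringIO(text))
        except KeyError as exc:  # pragma: no cover - guarded by _check_stanza_ids
            raise DataError(f"OBO stanza missing mandatory tag {exc}") from exc
    parents: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    xrefs: dict[str, tuple[str, ...]] = {}
    for term, data in graph.nodes(data=True):
        parents[term] = list(data.get("is_a", ()))
        names[term] = data.get("name", term)
        for alt in data.get("alt_id", ()):
            alt_ids[alt] = term
        xrefs[term] = tuple(data.get("xref", ()))
    return Ontology(parents, names=names, alt_ids=alt_ids, xrefs=xrefs)


def _check_stanza_ids(text: str) -> None:
    """Raise with a line number if any [Term] stanza lacks an ``id`` tag."""
    stanza_line = None
    has_id = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("["):
            if stanza_line is not None and not has_id:
                raise DataError(f"[Term] stanza at line {stanza_line} has no id tag")
            stanza_line = lineno if stripped == "[Term]" else None
            has_id = False
        elif stanza_line is not None and stripped.startswith("id:"):
            has_id = True
    if stanza_line is not None and not has_id:
        raise DataError(f"[Term] stanza at line {stanza_line} has no id tag")


# ---------------------------------------------------------------------------
# Information content


@dataclass(frozen=True)
class ICTable:
    """Per-term annotation probability and information content (nats).

    ``p[x]`` is the fraction of corpus diseases annotated to ``x`` or to any
    descendant of ``x`` (implicit annotation propagation, the standard Resnik
    convention), so ``p`` is monotone non-decreasing from a term to each of its
    ancestors and ``ic = -log p`` is antitone along parent edges.
    """

    p: dict[str, float]
    ic: dict[str, float]
    corpus_size: int
    smoothing: str = "add_one"

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def get_ic(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise DataError(f"no information content for term {term!r}") from None


def compute_ic(
    ontology: Ontology,
    corpus,
    smoothing: str = "add_one",
) -> ICTable:
    """Information content of every ontology term from corpus annotation counts.

    ``ic(x) = -log p(x)`` with ``p(x)`` the fraction of diseases annotated to
    ``x`` or any of its descendants.  Terms with zero (even propagated)
    annotations get ``p = 1/(N+1)`` under ``smoothing="add_one"`` so their ic
    stays finite; under ``smoothing="exclude"`` they are left out of the table.

    Parameters
    ----------
    corpus :
        A :class:`~phenonet.corpus.DiseaseCorpus` or any object with a
        ``term_sets()`` method yielding ``(disease_id, set_of_terms)``.
    """
    if smoothing not in ("add_one", "exclude"):
        raise ValueError(f"unknown smoothing mode {smoothing!r}")
    term_sets = list(corpus.term_sets())
    n = len(term_sets)
    if n == 0:
        raise DataError("cannot compute information content from an empty corpus")
    counts: dict[str, int] = {t: 0 for t in ontology.terms}
    for _disease, terms in term_sets:
        propagated: set[str] = set()
        for t in terms:
            propagated |= ontology.ancestors(t)
        for t in propagated:
            counts[t] += 1
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    for t, c in counts.items():
        if c > 0:
            p[t] = c / n
        elif smoothing == "add_one":
            p[t] = 1.0 / (n + 1)
        else:
            continue
        ic[t] = -math.log(p[t])
    return ICTable(p=p, ic=ic, corpus_size=n, smoothing=smoothing)
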