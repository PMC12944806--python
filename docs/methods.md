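# Methods

## Data model

The phenotype ontology is a rooted directed acyclic graph whose nodes are
terms and whose edges are `is_a` relations from child to parent; terms may
have several parents.  Two conventions are fixed package-wide:

* **Ancestor sets are self-inclusive** (`x ∈ ancestors(x)`).  GraphIC sums
  information content over ancestor-expanded sets that must contain the
  original symptoms, and Resnik's "common ancestor" of a term with itself
  must be the term itself; self-inclusion gives both for free.
* **Path distance is the undirected edge count.**  Query expansion measures
  the distance from a query seed to any ontology term, and the relevant
  routes ascend to a shared ancestor and descend again (e.g. hypotonia →
  abnormal muscle tone → hypertonia → limb hypertonia → lower limb
  hypertonia, distance 4).  A directed reading would make most sibling
  branches unreachable.  Disconnected pairs (possible only in synthetic
  multi-component graphs) return `inf`, distinct from every real distance.

OBO parsing is delegated to `obonet` (obsolete stanzas dropped, `alt_id`
merged identifiers resolved to primary ids at parse time, `xref`s retained
for disease-identifier unification); the package validates acyclicity,
single-rootedness and stanza ids on top, since a malformed ontology must be
a hard error rather than a silently odd graph.

## Information content

`IC(x) = −log p(x)` in natural log (the base only rescales Resnik scores
and cancels entirely in GraphIC's ratio).  `p(x)` is the fraction of corpus
diseases annotated to `x` **or to any descendant of `x`** — implicit
annotation propagation, the standard Resnik convention, which guarantees
`p` is monotone non-decreasing toward the root, `ic` antitone along parent
edges, and `ic(root) = 0` whenever every disease has at least one
annotation.  The corpus used for IC is a parameter; by default it is the
full corpus being ranked.

Terms with zero propagated annotations receive `p = 1/(N+1)` (add-one
smoothing on disease counts, `N` = corpus size) so their ic is finite and
still larger than any annotated term's; an `exclude` mode leaves them out
of the table instead, in which case querying them is an error.

## Frequency normalization

Annotation frequencies arrive as fractions (`7/11`, carrying sample size
11), percentages (`30%`, sample size unknown), frequency-class terms
(e.g. *Occasional* = 5–29% of patients), or missing.  Missing values
default to **0.5**, the mean of a uniform prior over [0, 1]; 0.01
("very rare") and 1.0 ("obligate") are named presets for sensitivity
analysis.  The shipped class table covers the six standard classes
(Obligate [1, 1], Very frequent [0.80, 0.99], Frequent [0.30, 0.79],
Occasional [0.05, 0.29], Very rare [0.01, 0.04], Excluded [0, 0]).

Conflicting duplicates of one disease–term pair merge by three ordered
rules: all fractions → denominator-weighted mean (`7/11` + `3/5` →
`10/16 = 0.625`); any interval present → midpoint of the smallest interval
compatible with all values, where "compatible" means the intersection when
non-empty and otherwise the spanning hull (intersection-first preserves
information when annotations agree; points are degenerate intervals);
otherwise → arithmetic mean.  Percentages carry no weight, so a
percentage–fraction mix falls to the mean rule.  Identifier unification
through the disease ontology's xrefs happens **before** duplicate
resolution, so the cross-source duplicates that motivate the rules are
actually merged; an id claimed by several disease-ontology terms resolves
deterministically to the lexicographically smallest, with a warning.
`NOT`-qualified annotations are dropped by default (configurable), and
aspect filtering requires both the phenotypic-abnormality aspect code and
membership in the supplied ontology (belt and braces).

## Similarity measures

Frequencies weight only the TF-IDF vectors and the query expansion;
Jaccard, Resnik and GraphIC operate on bare term sets.  The headline Resnik
variant is the best-match average; the plain pair-grid average is exposed
as `resnik_avg` for the rank-correlation study, where its tendency to let
a single high-IC term dominate is itself informative.

The TF-IDF weighting is `tf · idf` with `tf` the stored annotation
frequency (binary occurrence available as an option) and
`idf = log((1+N)/(1+df)) + 1`, `df` counting diseases *directly* annotated
to the term.  The smoothing keeps idf positive everywhere, gives universal
terms the floor value 1, and lets query terms outside the corpus vocabulary
participate at the `df = 0` ceiling rather than erroring.

Query expansion assigns every ontology term the frequency
`f_y = f_x · α^d(x,y)` of its nearest seed; seeds keep their own frequency
(`d = 0`, with `0⁰ = 1` so `α = 0` degenerates exactly to the unexpanded
query, which is asserted in tests as score equality with plain TF-IDF).
Equidistant seeds resolve toward the larger resulting frequency — the
stronger evidence — which is permutation-invariant.  Expansion is scoped to
the ontology passed in; pass the phenotypic-abnormality subtree to keep the
expanded vocabulary inside corpus scope.  Default `α = 0.5`; the sweep
preset is {0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0}.

## Rankings, τ, consensus, categories

Rankings sort scores descending with ties broken by lexicographic disease
id (deterministic and reproducible across runs).  Rank agreement uses the
weighted Kendall τ with additive hyperbolic weights `w(r) = 1/(r+1)`
(0-based ranks), symmetrized over which ranking supplies the reference
ranks — exactly the contract of `scipy.stats.weightedtau`, which the
pipeline calls.  An O(n²) pair-enumeration of the same definition ships as
`weighted_tau_reference` and is the oracle the tests compare against
(to 1e-12, exhaustively over all permutations of six items).

The consensus aggregates the headline rankings (Jaccard, Resnik BMA,
GraphIC, and of the two TF-IDF rankings only the query-expanded one) with
equal weight: each method's scores are normalized by that method's maximum,
averaged, re-ranked, and renormalized so the top disease scores 1.
Score-based aggregation is the default because the consensus is presented
as a continuous normalized score; a rank-based Borda scheme is available
behind a flag.  Aggregation is invariant to the order the rankings are
supplied (they are accumulated in canonical method order).

Category classification traces each top-K consensus disease through every
path to the disease-ontology root and counts each reached top-level
category (the root's direct children) once per disease.  K defaults to 50
and is configurable; the category set is computed from the loaded file
rather than hard-coded, so synthetic stand-ins work and the real file's
count is simply logged.  Ids not present in the ontology are first looked
up through its xrefs (covering corpora ingested without unification) and
otherwise counted as unclassified.

## Synthetic benchmark

The generator emulates the statistical shape of the real inputs: a rooted
DAG where term *i* draws 1–2 parents uniformly among earlier terms (acyclic
by construction); 200 diseases annotated to 3–50 terms sampled with a
power-law popularity bias (exponent 1 over term index, giving the broad
document-frequency spread TF-IDF needs); frequencies drawn from Beta(2, 2)
and emitted as 40% fractions (denominators 5–200, exercising unequal
weights), 25% percentages, 15% class terms and 20% absent; 10% of pairs
duplicated with a conflicting second value; and a 12-term query (depth ≥ 2,
so ancestor-shifting never lands on the root) with three planted diseases:
an exact clone, a 50%-overlap disease, and an ancestor-shifted disease
whose every term is replaced by its nearest out-of-query ancestor.  These
defaults are the package's benchmark conditions; tests and the recovery
analysis run against them unchanged, across 20 seeds for the recovery
property.

What the benchmark does **not** emulate: the real HPO's depth and branching
statistics, term co-occurrence structure driven by organ systems, the
heavy-tailed disease-size distribution of OMIM/Orphanet, or textual
annotation noise.  Passing the recovery tests therefore shows the pipeline
is internally correct and discriminates planted structure under realistic
format heterogeneity — not that its ranking of real diseases is clinically
validated.

The packaged Minamata query profile is likewise a synthetic stand-in: the
documented cohort values (0.37% intellectual disability after correcting
the source tables' contradiction, n = 269, presence of the spasticity and
hypotonia terms) are pinned, and the remaining frequencies were drawn once
from a seeded Beta(2, 2); it exists so the worked examples and tests are
executable end-to-end without the original survey.

## Numerical and degenerate-input choices

* Jaccard of two empty sets is 0, not 1 — annotation-free diseases must not
  outrank genuine matches.
* GraphIC with an all-zero-IC union returns 0 with a warning.
* Cosine with a zero-norm vector returns 0.
* A single-element or empty ranking has τ = 1 by convention (no pairs).
* Scores are deterministic: identical inputs give byte-identical score
  tables, rankings and serialized corpora.

## Problem sizes

The default benchmark (150 terms, 200 + 3 diseases, 12-term query) fits the
package's intended test-and-demonstration scale; the full test suite,
including the 20-seed recovery analysis and the 7-point α sweep, runs in
well under a minute.  The pipeline itself is corpus-size agnostic — the
`from_files` constructor accepts full ontology and annotation releases —
but reproducing published full-corpus rankings requires those pinned
releases and a fully digitized survey profile, which are deliberately not
bundled.

## Known limitations

* Only `is_a` relations are honoured; other OBO relationship types, logical
  definitions and imports are ignored.
* Evidence codes, onset, sex and modifier columns are parsed but unused.
* Whether the original TF-IDF formulation used frequencies or binary
  occurrence as term frequency is not documented; both are implemented,
  frequency is the default.
* The consensus operator (score-based vs rank-based equal-weight
  aggregation) is a design choice; both are provided, score-based is
  default.
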