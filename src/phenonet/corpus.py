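"""Disease-phenotype annotation handling: HPOA parsing, filtering, frequency
normalization, duplicate merging and disease-identifier unification.

Annotation frequencies arrive in four heterogeneous formats — fractions like
``7/11`` (carrying an implicit sample size), percentages like ``30%``,
frequency-class ontology terms encoding an interval (e.g. *Occasional*,
5–29% of patients), or missing entirely — and are normalized here to a single
probability per disease-term pair.  Missing frequencies default to 0.5, the
mean of a uniform prior over [0, 1]; the extreme settings 0.01 and 1.0 are
named presets for sensitivity analysis.  Conflicting duplicates (the same
disease-term pair annotated twice, typically once per source ontology) are
merged by three rules, in order:

1. all values are fractions → weighted mean with the denominators as weights;
2. any value carries an interval → midpoint of the smallest interval
   compatible with all values (intersection when non-empty, otherwise the
   spanning hull);
3. otherwise → arithmetic mean.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .errors import DataError
from .ontology import Ontology

logger = logging.getLogger(__name__)

#: Named presets for the frequency assigned to annotations with no reported
#: frequency: the uniform-prior mean plus the two extreme sensitivity settings.
UNKNOWN_FREQUENCY_PRESETS = {"prior-mean": 0.5, "very-rare": 0.01, "obligate": 1.0}

#: Aspect code marking a phenotypic-abnormality annotation in HPOA files.
PHENOTYPE_ASPECT = "P"

HPOA_COLUMNS = (
    "database_id",
    "disease_name",
    "qualifier",
    "hpo_id",
    "reference",
    "evidence",
    "onset",
    "frequency",
    "sex",
    "modifier",
    "aspect",
    "biocuration",
)
_MANDATORY = ("database_id", "hpo_id", "frequency", "aspect")

_FRACTION_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")
_PERCENT_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*%\s*$")
_CLASS_RE = re.compile(r"^\s*([A-Za-z]+:\d+)\s*$")


def load_frequency_classes() -> dict[str, tuple[float, float]]:
    """The shipped frequency-class table: class term id -> (lo, hi) interval."""
    text = resources.files("phenonet.data").joinpath("frequency_classes.tsv").read_text()
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("term\t"):
            continue
        term, _name, lo, hi = line.split("\t")
        table[term] = (float(lo), float(hi))
    return table


@dataclass(frozen=True)
class RawAnnotation:
    """One row of a disease-phenotype annotation file, unnormalized."""

    disease_id: str
    term: str
    frequency_raw: str | None = None
    aspect: str = PHENOTYPE_ASPECT
    disease_name: str = ""
    qualifier: str = ""


@dataclass(frozen=True)
class FrequencyValue:
    """A normalized annotation frequency.

    ``value`` is a probability; ``weight`` is the effective sample size when
    the source was a fraction; ``interval`` is the [lo, hi] range when the
    source was a frequency-class term (or a merge involving one).
    """

    value: float
    weight: float | None = None
    interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise DataError(f"frequency {self.value} outside [0, 1]")
        if self.interval is not None:
            lo, hi = self.interval
            if not lo <= self.value <= hi:
                raise DataError(f"frequency {self.value} outside interval {self.interval}")


@dataclass
class DiseaseProfile:
    """A disease with one normalized frequency per annotated term."""

    disease_id: str
    name: str
    annotations: dict[str, FrequencyValue]

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.annotations)

    def frequency(self, term: str) -> float:
        return self.annotations[term].value


@dataclass
class DiseaseCorpus:
    """A collection of disease profiles with unique (unified) identifiers."""

    profiles: dict[str, DiseaseProfile]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[DiseaseProfile]:
        return iter(self.profiles.values())

    def __getitem__(self, disease_id: str) -> DiseaseProfile:
        return self.profiles[disease_id]

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.profiles

    @property
    def disease_ids(self) -> list[str]:
        return list(self.profiles)

    def term_sets(self) -> Iterator[tuple[str, frozenset[str]]]:
        for d in self:
            yield d.disease_id, d.terms

    def document_frequency(self) -> dict[str, int]:
        """Number of diseases directly annotated to each term."""
        df: dict[str, int] = {}
        for d in self:
            for t in d.terms:
                df[t] = df.get(t, 0) + 1
        return df

    def vocabulary(self) -> frozenset[str]:
        vocab: set[str] = set()
        for d in self:
            vocab |= d.terms
        return frozenset(vocab)

    # -- i/o ----------------------------------------------------------------

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("disease_id\tdisease_name\tterm\tfrequency\n")
        for did in sorted(self.profiles):
            d = self.profiles[did]
            for term in sorted(d.annotations):
                stream.write(f"{did}\t{d.name}\t{term}\t{d.annotations[term].value:.10g}\n")

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, sort_keys=True, indent=2)

    @classmethod
    def read_tsv(cls, stream: IO[str]) -> "DiseaseCorpus":
        reader = csv.DictReader(stream, delimiter="\t")
        profiles: dict[str, DiseaseProfile] = {}
        for row in reader:
            did = row["disease_id"]
            prof = profiles.setdefault(did, DiseaseProfile(did, row.get("disease_name", ""), {}))
            prof.annotations[row["term"]] = FrequencyValue(float(row["frequency"]))
        return cls(profiles)


# ---------------------------------------------------------------------------
# Parsing


def parse_hpoa(stream: IO[str] | str) -> list[RawAnnotation]:
    """Read the HPOA tab-separated dialect into raw annotations.

    Leading ``#`` comment lines are skipped; the first non-comment line is the
    header.  A missing mandatory column is a hard error; a malformed frequency
    cell keeps the annotation with its frequency absent and logs a warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln for ln in stream.read().splitlines() if ln.strip()]
    data_lines = [ln for ln in lines if not ln.startswith("#")]
    if not data_lines:
        raise DataError("annotation file has no header line")
    header = data_lines[0].rstrip("\n").split("\t")
    colidx = {name.strip().lower(): i for i, name in enumerate(header)}
    missing = [c for c in _MANDATORY if c not in colidx]
    if missing:
        raise DataError(f"annotation file missing mandatory column(s): {', '.join(missing)}")
    out: list[RawAnnotation] = []
    n_malformed = 0
    for ln in data_lines[1:]:
        cells = ln.split("\t")

        def cell(name: str) -> str:
            i = colidx.get(name)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        freq: str | None = cell("frequency") or None
        if freq is not None and not _classify_frequency(freq):
            n_malformed += 1
            freq = None
        out.append(
            RawAnnotation(
                disease_id=cell("database_id"),
                term=cell("hpo_id"),
                frequency_raw=freq,
                aspect=cell("aspect") or PHENOTYPE_ASPECT,
                disease_name=cell("disease_name"),
                qualifier=cell("qualifier"),
            )
        )
    if n_malformed:
        logger.warning("%d malformed frequency cell(s) treated as absent", n_malformed)
    return out


def _classify_frequency(raw: str) -> str | None:
    if _FRACTION_RE.match(raw):
        return "fraction"
    if _PERCENT_RE.match(raw):
        return "percent"
    if _CLASS_RE.match(raw):
        return "class"
    return None


def filter_phenotypic(
    annotations: Iterable[RawAnnotation],
    ontology: Ontology,
    drop_negated: bool = True,
) -> list[RawAnnotation]:
    """Keep phenotypic-abnormality annotations whose term lies in the ontology.

    Both signals are required: the aspect column must mark a phenotypic
    abnormality (dropping inheritance-mode and clinical-course rows) *and* the
    term must belong to the supplied (phenotypic-abnormality) ontology.
    ``NOT``-qualified annotations are dropped by default.  Drops are counted
    and logged, never fatal.
    """
    kept: list[RawAnnotation] = []
    n_aspect = n_subtree = n_not = 0
    for a in annotations:
        if drop_negated and a.qualifier.upper() == "NOT":
            n_not += 1
            continue
        if a.aspect != PHENOTYPE_ASPECT:
            n_aspect += 1
            continue
        term = ontology.canonical(a.term)
        if term not in ontology:
            n_subtree += 1
            continue
        kept.append(a if term == a.term else replace(a, term=term))
    if n_aspect or n_subtree or n_not:
        logger.info(
            "filter_phenotypic dropped %d by aspect, %d outside subtree, %d negated",
            n_aspect, n_subtree, n_not,
        )
    return kept


# ---------------------------------------------------------------------------
# Frequency normalization


def resolve_frequency(
    raw: str | None,
    unknown_default: float = 0.5,
    class_table: Mapping[str, tuple[float, float]] | None = None,
) -> FrequencyValue:
    """Normalize one raw frequency cell to a :class:`FrequencyValue`.

    fraction ``n/d`` → value n/d with weight d; percentage ``q%`` → q/100
    (weightless — the sample size is unknown); frequency-class term → the
    class interval with its midpoint as value; absent → ``unknown_default``.
    """
    if raw is None or raw == "":
        return FrequencyValue(unknown_default)
    m = _FRACTION_RE.match(raw)
    if m:
        num, den = int(m.group(1)), int(m.group(2))
        if den == 0 or num > den:
            raise DataError(f"invalid fraction frequency {raw!r}")
        return FrequencyValue(num / den, weight=float(den))
    m = _PERCENT_RE.match(raw)
    if m:
        q = float(m.group(1))
        if q > 100:
            raise DataError(f"percentage frequency {raw!r} above 100%")
        return FrequencyValue(q / 100.0)
    m = _CLASS_RE.match(raw)
    if m:
        table = class_table if class_table is not None else load_frequency_classes()
        term = m.group(1)
        if term not in table:
            raise DataError(f"unknown frequency-class term {term!r}")
        lo, hi = table[term]
        return FrequencyValue((lo + hi) / 2.0, interval=(lo, hi))
    raise DataError(f"unparseable frequency cell {raw!r}")


def merge_duplicates(values: Sequence[FrequencyValue]) -> FrequencyValue:
    """Collapse conflicting frequencies for one disease-term pair.

    Permutation-invariant.  See the module docstring for the three rules.
    """
    if not values:
        raise DataError("merge_duplicates requires at least one value")
    if len(values) == 1:
        return values[0]
    if all(v.weight is not None for v in values):
        total_w = sum(v.weight for v in values)  # type: ignore[misc]
        mean = sum(v.value * v.weight for v in values) / total_w  # type: ignore[operator]
        return FrequencyValue(mean, weight=total_w)
    if any(v.interval is not None for v in values):
        intervals = [v.interval if v.interval is not None else (v.value, v.value) for v in values]
        lo = max(i[0] for i in intervals)
        hi = min(i[1] for i in intervals)
        if lo > hi:  # disjoint: smallest interval containing all
            lo = min(i[0] for i in intervals)
            hi = max(i[1] for i in intervals)
        return FrequencyValue((lo + hi) / 2.0, interval=(lo, hi))
    return FrequencyValue(sum(v.value for v in values) / len(values))


# ---------------------------------------------------------------------------
# Disease identifier unification


class MondoMap:
    """Cross-reference index of a disease ontology for identifier unification.

    Maps source-prefixed ids (e.g. OMIM:/ORPHA:/DECIPHER:) to the disease
    ontology term that cross-references them.  When several terms claim the
    same xref the lexicographically smallest id wins, deterministically, with
    a warning.
    """

    def __init__(self, mondo: Ontology) -> None:
        self.mondo = mondo
        index: dict[str, list[str]] = {}
        for term in mondo:
            for xref in mondo.xrefs.get(term, ()):
                index.setdefault(xref, []).append(term)
        self._index = {x: sorted(ts) for x, ts in index.items()}
        self.n_unmapped = 0

    def map_id(self, disease_id: str) -> str:
        hits = self._index.get(disease_id)
        if not hits:
            self.n_unmapped += 1
            return disease_id
        if len(hits) > 1:
            logger.warning(
                "disease id %s matches %d ontology terms; using %s",
                disease_id, len(hits), hits[0],
            )
        return hits[0]


def map_to_mondo(disease_id: str, mondo: Ontology) -> str:
    """One-shot identifier unification; see :class:`MondoMap` for batch use."""
    return MondoMap(mondo).map_id(disease_id)


# ---------------------------------------------------------------------------
# Corpus assembly


def build_corpus(
    annotations: Iterable[RawAnnotation],
    ontology: Ontology,
    mondo: Ontology | None = None,
    unknown_default: float = 0.5,
    class_table: Mapping[str, tuple[float, float]] | None = None,
    provenance: dict | None = None,
) -> DiseaseCorpus:
    """Group filtered annotations into a corpus of unique disease profiles.

    Disease ids are unified through ``mondo`` *before* duplicate resolution,
    so records of the same disease from different source ontologies are
    actually merged: their annotations are unioned and conflicting
    frequencies resolved by :func:`merge_duplicates`.  Diseases left with no
    annotations are excluded and counted.
    """
    mapper = MondoMap(mondo) if mondo is not None else None
    grouped: dict[str, dict[str, list[FrequencyValue]]] = {}
    names: dict[str, str] = {}
    for a in annotations:
        did = mapper.map_id(a.disease_id) if mapper else a.disease_id
        term = ontology.canonical(a.term)
        grouped.setdefault(did, {}).setdefault(term, []).append(
            resolve_frequency(a.frequency_raw, unknown_default, class_table)
        )
        if did not in names or (mapper and did.startswith("MONDO")):
            name = mapper.mondo.names.get(did, a.disease_name) if mapper else a.disease_name
            names[did] = name or a.disease_name
    profiles: dict[str, DiseaseProfile] = {}
    n_empty = 0
    for did in sorted(grouped):
        ann = {t: merge_duplicates(vals) for t, vals in grouped[did].items()}
        if not ann:
            n_empty += 1
            continue
        profiles[did] = DiseaseProfile(did, names.get(did, did), ann)
    if n_empty:
        logger.info("%d disease(s) with no surviving annotations excluded", n_empty)
    prov = dict(provenance or {})
    prov.setdefault("unknown_default", unknown_default)
    prov["n_diseases"] = len(profiles)
    prov["n_annotations"] = sum(len(p.annotations) for p in profiles.values())
    if mapper is not None:
        prov["n_unmapped_ids"] = mapper.n_unmapped
    return DiseaseCorpus(profiles, provenance=prov)
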