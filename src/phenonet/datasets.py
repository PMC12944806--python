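"""Small built-in fixtures used in examples, tests and acceptance checks."""

from __future__ import annotations

from .ontology import Ontology, parse_obo
from .profile import QueryProfile, load_minamata_profile  # re-export

#: Real HPO identifiers for the muscle-tone neighbourhood used in the
#: query-expansion worked example.
SPASTICITY = "HP:0001257"
HYPERTONIA = "HP:0001276"
LIMB_HYPERTONIA = "HP:0002509"
LOWER_LIMB_HYPERTONIA = "HP:0006895"
HYPOTONIA = "HP:0001252"
ABNORMAL_MUSCLE_TONE = "HP:0003808"
PHENOTYPIC_ABNORMALITY = "HP:0000118"

MUSCLE_TONE_OBO = f"""format-version: 1.2
ontology: phenonet-muscle-tone-fixture

[Term]
id: {PHENOTYPIC_ABNORMALITY}
name: Phenotypic abnormality

[Term]
id: {ABNORMAL_MUSCLE_TONE}
name: Abnormal muscle tone
is_a: {PHENOTYPIC_ABNORMALITY} ! Phenotypic abnormality

[Term]
id: {HYPERTONIA}
name: Hypertonia
is_a: {ABNORMAL_MUSCLE_TONE} ! Abnormal muscle tone

[Term]
id: {HYPOTONIA}
name: Hypotonia
is_a: {ABNORMAL_MUSCLE_TONE} ! Abnormal muscle tone

[Term]
id: {SPASTICITY}
name: Spasticity
is_a: {HYPERTONIA} ! Hypertonia

[Term]
id: {LIMB_HYPERTONIA}
name: Limb hypertonia
is_a: {HYPERTONIA} ! Hypertonia

[Term]
id: {LOWER_LIMB_HYPERTONIA}
name: Lower limb hypertonia
is_a: {LIMB_HYPERTONIA} ! Limb hypertonia
"""


def muscle_tone_ontology() -> Ontology:
    """Seven-term DAG around the muscle-tone branch of the phenotype ontology.

    Encodes the two chains of the query-expansion worked example:
    Spasticity is_a Hypertonia is_a Abnormal muscle tone, Limb hypertonia
    is_a Hypertonia, Lower limb hypertonia is_a Limb hypertonia, and
    Hypotonia is_a Abnormal muscle tone — so the undirected distance from
    Spasticity to Lower limb hypertonia is 3 and from Hypotonia (up through
    Abnormal muscle tone, down through Hypertonia and Limb hypertonia) is 4.
    """
    return parse_obo(MUSCLE_TONE_OBO)


def muscle_tone_query(f_spasticity: float = 0.4088, f_hypotonia: float = 0.4292) -> QueryProfile:
    """A two-seed query on the muscle-tone fixture (spasticity + hypotonia)."""
    return QueryProfile(
        label="muscle-tone worked example",
        annotations={SPASTICITY: f_spasticity, HYPOTONIA: f_hypotonia},
    )
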