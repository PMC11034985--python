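"""Compilation of spectral-library records into an ontology-based RDF model.

Each library record becomes a *mass spectrometry experiment* (SIO) that takes
the measured compound as its input and produces the mass spectrum as its
output; the spectrum node carries its peak list as a typed ``ms:spectrum``
literal.  Experiment parameters, chemical qualities, compound identifiers and
the SPLASH become attribute entities — each with an rdf:type drawn from the
PSI-MS or CHEMINF vocabularies, a value, and optionally a UO unit — linked to
their bearer.  Provenance is kept by organising experiments into datasets and
connecting them to the submitting person (vCard).

Compounds are interlinked across datasets by exact InChI string equality
(skos:closeMatch) and may be supplemented with external classifications
(MeSH/ChEBI) through a pre-extracted cross-reference table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import DCTERMS, RDF, XSD

from .config import Config
from .records_io import IdentifierScheme, SpectrumRecord
from .spectrum_core import serialize_spectrum_literal

logger = logging.getLogger(__name__)

__all__ = [
    "SIO",
    "OBO",
    "SKOS",
    "VCARD",
    "Vocabulary",
    "IriPolicy",
    "Triple",
    "TripleSet",
    "record_to_triples",
    "interlink_by_inchi",
    "supplement_classification",
    "write_graph",
    "to_graph",
]

SIO = Namespace("http://semanticscience.org/resource/")
OBO = Namespace("http://purl.obolibrary.org/obo/")
SKOS = Namespace("http://www.w3.org/2004/02/skos/core#")
VCARD = Namespace("http://www.w3.org/2006/vcard/ns#")

Triple = tuple[URIRef, URIRef, "URIRef | Literal"]
TripleSet = set  # set[Triple]


@dataclass(frozen=True)
class Vocabulary:
    """The IRI constants of the data model.

    Class and property terms default to the SIO / PSI-MS / SKOS / vCard
    terms of the model; the attribute-link direction (attribute → bearer)
    is isolated here so it can be flipped by configuration if a different
    rendering is needed.
    """

    # classes
    experiment_class: URIRef = SIO.SIO_001180   # mass spectrometry experiment
    compound_class: URIRef = SIO.SIO_011125     # chemical substance
    spectrum_class: URIRef = OBO.MS_1000294     # mass spectrum
    peak_class: URIRef = OBO.MS_1000231         # peak
    annotation_class: URIRef = SIO.SIO_001166   # annotation
    dataset_class: URIRef = SIO.SIO_000089      # dataset
    person_class: URIRef = VCARD.Individual
    # properties
    has_input: URIRef = SIO.SIO_000230
    has_output: URIRef = SIO.SIO_000229
    has_value: URIRef = SIO.SIO_000300
    has_unit: URIRef = SIO.SIO_000221
    is_param_in: URIRef = SIO.SIO_000553
    is_attribute_of: URIRef = SIO.SIO_000011
    is_identifier_of: URIRef = SIO.SIO_000672
    is_component_part_of: URIRef = SIO.SIO_000313
    position: URIRef = SIO.SIO_000056
    is_annotation_of: URIRef = SIO.SIO_000254
    in_dataset: URIRef = SIO.SIO_001278
    has_agent: URIRef = SIO.SIO_000066
    close_match: URIRef = SKOS.closeMatch
    title: URIRef = DCTERMS.title
    formatted_name: URIRef = VCARD.fn
    email: URIRef = VCARD.hasEmail
    # reverse the attribute-link direction (bearer → attribute) if needed
    attribute_points_to_bearer: bool = True

    def link(self, attribute: URIRef, prop: URIRef, bearer: URIRef) -> Triple:
        if self.attribute_points_to_bearer:
            return (attribute, prop, bearer)
        return (bearer, prop, attribute)


# PSI-MS terms for the common experiment parameters; anything unmapped is
# typed with the generic parameter class below.
PSI_MS_PARAM_TYPES: Mapping[str, URIRef] = {
    "ion mode": OBO.MS_1000465,        # scan polarity
    "collision energy": OBO.MS_1000045,
    "instrument": OBO.MS_1000031,
    "instrument type": OBO.MS_1000031,
    "precursor m/z": OBO.MS_1000744,   # selected ion m/z
    "precursor type": OBO.MS_1000792,  # isolation window attribute
}

# CHEMINF terms for compound qualities and identifiers
CHEMINF_QUALITY_TYPES: Mapping[str, URIRef] = {
    "molecular formula": OBO.CHEMINF_000042,
    "smiles": OBO.CHEMINF_000018,
    "total exact mass": OBO.CHEMINF_000338,
    "molecular weight": OBO.CHEMINF_000334,
}

CHEMINF_IDENTIFIER_TYPES: Mapping[IdentifierScheme, URIRef] = {
    IdentifierScheme.PUBCHEM_CID: OBO.CHEMINF_000140,
    IdentifierScheme.CHEBI: OBO.CHEMINF_000407,
    IdentifierScheme.CAS: OBO.CHEMINF_000446,
}

INCHI_TYPE: URIRef = OBO.CHEMINF_000113
INCHIKEY_TYPE: URIRef = OBO.CHEMINF_000059

UO_UNITS: Mapping[str, URIRef] = {
    "electronvolt": OBO.UO_0000266,
    "ev": OBO.UO_0000266,
    "dalton": OBO.UO_0000221,
    "da": OBO.UO_0000221,
    "second": OBO.UO_0000010,
    "minute": OBO.UO_0000031,
    "volt": OBO.UO_0000218,
}


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in text)


@dataclass(frozen=True)
class IriPolicy:
    """Deterministic node-IRI minting.

    Every node of a record's graph gets an IRI derived only from the record
    id (plus an ordinal for attribute/peak nodes), so repeated compilation of
    the same record yields the same IRIs.
    """

    base: str = Config().base_iri

    def experiment(self, record_id: str) -> URIRef:
        return URIRef(f"{self.base}experiment/{_slug(record_id)}")

    def compound(self, record_id: str) -> URIRef:
        return URIRef(f"{self.base}compound/{_slug(record_id)}")

    def spectrum(self, record_id: str) -> URIRef:
        return URIRef(f"{self.base}spectrum/{_slug(record_id)}")

    def attribute(self, record_id: str, ordinal: int) -> URIRef:
        return URIRef(f"{self.base}attribute/{_slug(record_id)}/{ordinal}")

    def peak(self, record_id: str, ordinal: int) -> URIRef:
        return URIRef(f"{self.base}peak/{_slug(record_id)}/{ordinal}")

    def dataset(self, name: str) -> URIRef:
        return URIRef(f"{self.base}dataset/{_slug(name)}")

    def person(self, name: str) -> URIRef:
        return URIRef(f"{self.base}person/{_slug(name)}")


def _value_literal(value: str | float) -> Literal:
    if isinstance(value, float):
        return Literal(value, datatype=XSD.double)
    return Literal(str(value))


def _unit_term(unit: str) -> "URIRef | Literal":
    iri = UO_UNITS.get(unit.lower())
    if iri is None:
        logger.warning("unknown unit %r rendered as a plain literal", unit)
        return Literal(unit)
    return iri


def record_to_triples(
    record: SpectrumRecord,
    policy: IriPolicy = IriPolicy(),
    vocab: Vocabulary = Vocabulary(),
    config: Config = Config(),
) -> TripleSet:
    """Compile one record into its RDF triples.

    The backbone is always present: the experiment typed as a mass
    spectrometry experiment, the compound linked as its input, the spectrum
    linked as its output and bearing the peak list as an ``ms:spectrum``
    literal.  Every other record field adds attribute, peak, annotation,
    dataset or person nodes as described in the module docstring.
    """
    triples: TripleSet = set()
    minted: dict[URIRef, str] = {}

    def mint(iri: URIRef, what: str) -> URIRef:
        if iri in minted and minted[iri] != what:
            raise ValueError(f"IRI policy collision: {iri} for {minted[iri]} and {what}")
        minted[iri] = what
        return iri

    exp = mint(policy.experiment(record.record_id), "experiment")
    cmp_ = mint(policy.compound(record.record_id), "compound")
    spec = mint(policy.spectrum(record.record_id), "spectrum")

    triples.add((exp, RDF.type, vocab.experiment_class))
    triples.add((cmp_, RDF.type, vocab.compound_class))
    triples.add((spec, RDF.type, vocab.spectrum_class))
    triples.add((exp, vocab.has_input, cmp_))
    triples.add((exp, vocab.has_output, spec))
    lexical = serialize_spectrum_literal(record.spectrum)
    triples.add(
        (spec, vocab.has_value, Literal(lexical, datatype=URIRef(config.spectrum_datatype)))
    )

    ordinal = 0

    def attribute_node() -> URIRef:
        nonlocal ordinal
        node = mint(policy.attribute(record.record_id, ordinal), f"attribute {ordinal}")
        ordinal += 1
        return node

    generic_param = URIRef(config.ms_namespace + "parameter")
    splash_type = URIRef(config.ms_namespace + "SPLASH")

    for param in record.params:
        node = attribute_node()
        triples.add((node, RDF.type, PSI_MS_PARAM_TYPES.get(param.name, generic_param)))
        triples.add((node, vocab.has_value, _value_literal(param.value)))
        if param.unit is not None:
            triples.add((node, vocab.has_unit, _unit_term(param.unit)))
        triples.add(vocab.link(node, vocab.is_param_in, exp))

    for quality in record.compound.qualities:
        node = attribute_node()
        triples.add(
            (node, RDF.type, CHEMINF_QUALITY_TYPES.get(quality.kind.lower(), generic_param))
        )
        triples.add((node, vocab.has_value, _value_literal(quality.value)))
        if quality.unit is not None:
            triples.add((node, vocab.has_unit, _unit_term(quality.unit)))
        triples.add(vocab.link(node, vocab.is_attribute_of, cmp_))

    identifier_values: list[tuple[URIRef, str]] = [
        (CHEMINF_IDENTIFIER_TYPES[i.scheme], i.value)
        if i.scheme is not IdentifierScheme.OTHER
        else (generic_param, i.value)
        for i in record.compound.identifiers
    ]
    if record.compound.inchi is not None:
        identifier_values.append((INCHI_TYPE, record.compound.inchi))
    if record.compound.inchikey is not None:
        identifier_values.append((INCHIKEY_TYPE, record.compound.inchikey))
    for type_iri, value in identifier_values:
        node = attribute_node()
        triples.add((node, RDF.type, type_iri))
        triples.add((node, vocab.has_value, Literal(value)))
        triples.add(vocab.link(node, vocab.is_identifier_of, cmp_))

    if record.splash is not None:
        node = attribute_node()
        triples.add((node, RDF.type, splash_type))
        triples.add((node, vocab.has_value, Literal(record.splash)))
        triples.add(vocab.link(node, vocab.is_identifier_of, spec))

    for tag in record.tags:
        node = attribute_node()
        triples.add((node, RDF.type, vocab.annotation_class))
        triples.add((node, vocab.has_value, Literal(tag)))
        triples.add(vocab.link(node, vocab.is_annotation_of, exp))

    for i, annotation in enumerate(record.peak_annotations):
        peak = mint(policy.peak(record.record_id, i), f"peak {i}")
        triples.add((peak, RDF.type, vocab.peak_class))
        triples.add(vocab.link(peak, vocab.is_component_part_of, spec))
        triples.add((peak, vocab.position, Literal(annotation.mz, datatype=XSD.double)))
        node = attribute_node()
        triples.add((node, RDF.type, vocab.annotation_class))
        triples.add((node, vocab.has_value, Literal(annotation.text)))
        triples.add(vocab.link(node, vocab.is_annotation_of, peak))

    if record.library is not None:
        dataset = mint(policy.dataset(record.library.name), "dataset")
        triples.add((exp, vocab.in_dataset, dataset))
        triples.add((dataset, RDF.type, vocab.dataset_class))
        triples.add((dataset, vocab.title, Literal(record.library.name)))
        if record.library.description is not None:
            triples.add(
                (dataset, DCTERMS.description, Literal(record.library.description))
            )

    if record.submitter is not None:
        person = mint(policy.person(record.submitter.name), "person")
        triples.add((exp, vocab.has_agent, person))
        triples.add((person, RDF.type, vocab.person_class))
        triples.add((person, vocab.formatted_name, Literal(record.submitter.name)))
        if record.submitter.email is not None:
            triples.add((person, vocab.email, Literal(record.submitter.email)))

    return triples


def interlink_by_inchi(
    local: Sequence[tuple[str, str]],
    external: Sequence[tuple[str, str]],
    vocab: Vocabulary = Vocabulary(),
) -> TripleSet:
    """One ``skos:closeMatch`` triple (local → external) per pair of
    compounds whose full InChI strings are byte-identical; Cartesian within
    each match group."""
    by_inchi: dict[str, list[str]] = {}
    for iri, inchi in external:
        by_inchi.setdefault(inchi, []).append(iri)
    triples: TripleSet = set()
    for iri, inchi in local:
        for target in by_inchi.get(inchi, ()):
            triples.add((URIRef(iri), vocab.close_match, URIRef(target)))
    return triples


def supplement_classification(
    compound_classes: Sequence[tuple[str, str]],
    xrefs: Mapping[str, Sequence[str]],
    vocab: Vocabulary = Vocabulary(),
) -> TripleSet:
    """Type compounds with the MeSH/ChEBI equivalents of their source
    classification classes; classes missing from the cross-reference map are
    logged and skipped."""
    triples: TripleSet = set()
    for compound_iri, class_id in compound_classes:
        targets = xrefs.get(class_id)
        if targets is None:
            logger.info("classification %r has no cross-reference; skipped", class_id)
            continue
        for target in targets:
            triples.add((URIRef(compound_iri), RDF.type, URIRef(target)))
    return triples


def to_graph(triples: Iterable[Triple]) -> Graph:
    graph = Graph()
    graph.bind("sio", SIO)
    graph.bind("obo", OBO)
    graph.bind("skos", SKOS)
    graph.bind("vcard", VCARD)
    graph.bind("dcterms", DCTERMS)
    for triple in triples:
        graph.add(triple)
    return graph


def write_graph(triples: TripleSet, format: str, stream: IO[str]) -> None:
    """Serialize as Turtle or canonical N-Triples.

    N-Triples output is sorted lexicographically so identical triple sets
    always produce byte-identical files.
    """
    if format == "turtle":
        stream.write(to_graph(triples).serialize(format="turtle"))
    elif format == "ntriples":
        lines = sorted(f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in triples)
        for line in lines:
            stream.write(line + "\n")
    else:
        raise ValueError(f"unsupported format {format!r} (use 'turtle' or 'ntriples')")
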