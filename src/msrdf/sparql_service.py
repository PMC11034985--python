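"""In-memory SPARQL store with mass-spectrum similarity extension functions.

The store holds the union of compiled record graphs and indexes every
spectrum node that carries an ``ms:spectrum`` literal.  Three extension
functions are registered under the configurable ``ms:`` namespace so SPARQL
FILTER expressions can rank and threshold spectra by similarity:

* ``ms:cosineGreedy(specA, specB [, tolerance])``
* ``ms:cosineHungarian(specA, specB [, tolerance])``
* ``ms:modifiedCosine(specA, precursorA, specB, precursorB [, tolerance])``

Arguments are ``ms:spectrum`` literals (precursors are plain doubles — the
spectrum literal itself carries peaks only); each function returns an
``xsd:double`` in [0, 1].  A malformed literal makes the expression error for
that binding row, which standard SPARQL semantics then filter out.

``similarity_search`` offers the same ranking as a direct API without going
through the query engine: a linear scan over the indexed spectra with an
optional precursor-window prefilter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD
from rdflib.plugins.sparql.operators import register_custom_function
from rdflib.plugins.sparql.sparql import SPARQLError

from .config import Config
from .rdf_model import OBO, PSI_MS_PARAM_TYPES, TripleSet, Vocabulary, to_graph
from .similarity import (
    SimilarityParams,
    cosine_greedy,
    cosine_hungarian,
    modified_cosine,
)
from .spectrum_core import Spectrum, SpectrumCodecError, parse_spectrum_literal

logger = logging.getLogger(__name__)

__all__ = [
    "Store",
    "SearchHit",
    "SimilarityFunction",
    "StoreError",
    "QueryError",
    "QueryResult",
    "load_store",
    "register_ms_functions",
    "execute_query",
    "similarity_search",
]


class SimilarityFunction(str, Enum):
    GREEDY = "greedy"
    HUNGARIAN = "hungarian"
    MODIFIED = "modified"


class StoreError(ValueError):
    pass


class QueryError(ValueError):
    pass


@dataclass(frozen=True)
class SearchHit:
    spectrum_iri: str
    score: float
    matched_peaks: int


@dataclass
class QueryResult:
    """A column-named row table (SELECT) or a boolean (ASK)."""

    columns: list[str]
    rows: list[dict[str, object]]
    boolean: bool | None = None

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class Store:
    graph: Graph
    spectrum_index: dict[str, tuple[Spectrum, float | None]]
    config: Config = field(default_factory=Config)


def _recover_precursor(graph: Graph, spectrum_node: URIRef, vocab: Vocabulary) -> float | None:
    """Follow spectrum → experiment → its parameter attributes and read a
    ``precursor m/z``-typed attribute value, if any."""
    precursor_type = PSI_MS_PARAM_TYPES["precursor m/z"]
    for exp in graph.subjects(vocab.has_output, spectrum_node):
        for attr in graph.subjects(vocab.is_param_in, exp):
            if (attr, RDF.type, precursor_type) in graph:
                for value in graph.objects(attr, vocab.has_value):
                    try:
                        return float(value)
                    except (TypeError, ValueError):
                        continue
    return None


def load_store(
    graphs: Iterable[TripleSet | Graph],
    config: Config = Config(),
    vocab: Vocabulary = Vocabulary(),
) -> Store:
    """Union the given graphs and index their spectra.

    Every ``has_value`` triple whose object is typed ``ms:spectrum`` defines
    an indexed spectrum; the precursor m/z is recovered from the owning
    experiment's parameter attributes when present.  In strict mode a
    malformed spectrum literal is a load error naming the node; in lenient
    mode the node is skipped with a logged warning.
    """
    union = Graph()
    for graph in graphs:
        for triple in graph:
            union.add(triple)
    datatype = URIRef(config.spectrum_datatype)
    index: dict[str, tuple[Spectrum, float | None]] = {}
    for subject, obj in union.subject_objects(vocab.has_value):
        if not isinstance(obj, Literal) or obj.datatype != datatype:
            continue
        try:
            spectrum = parse_spectrum_literal(str(obj))
        except SpectrumCodecError as exc:
            if config.strict:
                raise StoreError(f"malformed spectrum literal on {subject}: {exc}") from exc
            logger.warning("skipping malformed spectrum literal on %s", subject)
            continue
        precursor = _recover_precursor(union, subject, vocab)
        if precursor is not None:
            spectrum = Spectrum(spectrum.peaks, precursor_mz=precursor)
        index[str(subject)] = (spectrum, precursor)
    store = Store(graph=union, spectrum_index=index, config=config)
    register_ms_functions(store)
    return store


def _term_to_spectrum(term: object, argument: str) -> Spectrum:
    if not isinstance(term, Literal):
        raise SPARQLError(f"{argument}: expected an ms:spectrum literal, got {term!r}")
    try:
        return parse_spectrum_literal(str(term))
    except SpectrumCodecError as exc:
        logger.warning("%s: malformed spectrum literal in query: %s", argument, exc)
        raise SPARQLError(f"{argument}: malformed spectrum literal: {exc}") from exc


def _term_to_float(term: object, argument: str) -> float:
    try:
        return float(term)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise SPARQLError(f"{argument}: expected a number, got {term!r}") from exc


def register_ms_functions(store: Store) -> None:
    """Register the three similarity functions under the store's ``ms:``
    namespace.  Registration is global to the SPARQL engine and idempotent
    for a given namespace."""
    ns = store.config.ms_namespace
    default_tolerance = store.config.tolerance

    def params(tolerance: Sequence[object]) -> SimilarityParams:
        if tolerance:
            return SimilarityParams(tolerance=_term_to_float(tolerance[0], "tolerance"))
        return SimilarityParams(tolerance=default_tolerance)

    def ms_cosine_greedy(a, b, *tol):
        score = cosine_greedy(
            _term_to_spectrum(a, "argument 1"), _term_to_spectrum(b, "argument 2"), params(tol)
        ).score
        return Literal(score, datatype=XSD.double)

    def ms_cosine_hungarian(a, b, *tol):
        score = cosine_hungarian(
            _term_to_spectrum(a, "argument 1"), _term_to_spectrum(b, "argument 2"), params(tol)
        ).score
        return Literal(score, datatype=XSD.double)

    def ms_modified_cosine(a, prec_a, b, prec_b, *tol):
        spectrum_a = Spectrum(
            _term_to_spectrum(a, "argument 1").peaks,
            precursor_mz=_term_to_float(prec_a, "argument 2"),
        )
        spectrum_b = Spectrum(
            _term_to_spectrum(b, "argument 3").peaks,
            precursor_mz=_term_to_float(prec_b, "argument 4"),
        )
        score = modified_cosine(spectrum_a, spectrum_b, params(tol)).score
        return Literal(score, datatype=XSD.double)

    register_custom_function(URIRef(ns + "cosineGreedy"), ms_cosine_greedy, override=True)
    register_custom_function(URIRef(ns + "cosineHungarian"), ms_cosine_hungarian, override=True)
    register_custom_function(URIRef(ns + "modifiedCosine"), ms_modified_cosine, override=True)


def execute_query(store: Store, sparql: str) -> QueryResult:
    """Run a SPARQL 1.1 SELECT or ASK query over the store.

    The ``ms:``, ``sio:``, ``obo:``, ``rdf:`` ... prefixes are pre-bound,
    and the similarity functions are available in expressions.
    """
    try:
        result = store.graph.query(
            sparql, initNs={"ms": store.config.ms_namespace}
        )
    except Exception as exc:  # rdflib raises pyparsing errors on bad syntax
        raise QueryError(f"SPARQL query failed to parse or evaluate: {exc}") from exc
    if result.type == "ASK":
        return QueryResult(columns=[], rows=[], boolean=bool(result.askAnswer))
    columns = [str(v) for v in result.vars or []]
    rows = [
        {column: row[i] for i, column in enumerate(columns)}
        for row in result
    ]
    return QueryResult(columns=columns, rows=rows)


_FUNCTIONS = {
    SimilarityFunction.GREEDY: cosine_greedy,
    SimilarityFunction.HUNGARIAN: cosine_hungarian,
    SimilarityFunction.MODIFIED: modified_cosine,
}


def similarity_search(
    store: Store,
    query: Spectrum,
    function: SimilarityFunction | str,
    threshold: float,
    params: SimilarityParams = SimilarityParams(),
) -> list[SearchHit]:
    """Rank the indexed spectra by similarity to ``query``.

    Returns every indexed spectrum scoring at least ``threshold``, sorted by
    score descending with ties broken by IRI.  In modified mode, indexed
    spectra lacking a precursor are skipped (logged); a precursor-less query
    is an error.
    """
    function = SimilarityFunction(function)
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if function is SimilarityFunction.MODIFIED and query.precursor_mz is None:
        raise ValueError("modified-cosine search requires a query precursor m/z")
    score_fn = _FUNCTIONS[function]
    window = store.config.precursor_window
    hits: list[SearchHit] = []
    for iri, (spectrum, precursor) in store.spectrum_index.items():
        if function is SimilarityFunction.MODIFIED and precursor is None:
            logger.info("skipping %s: no precursor m/z indexed", iri)
            continue
        if (
            window is not None
            and query.precursor_mz is not None
            and precursor is not None
            and abs(query.precursor_mz - precursor) > window
        ):
            continue
        result = score_fn(query, spectrum, params)
        if result.score >= threshold:
            hits.append(SearchHit(iri, result.score, result.matched_peaks))
    hits.sort(key=lambda h: (-h.score, h.spectrum_iri))
    return hits
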