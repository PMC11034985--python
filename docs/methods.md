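# Methods

## Scope and shape

`msrdf` is a desk-scale library-plus-CLI, not a hosted endpoint: graphs live
in an in-memory `rdflib` store, similarity search is a linear scan, and all
I/O is plain text (MSP, JSON, TSV, Turtle, N-Triples). The package has six
modules mirroring its pipeline: `spectrum_core` (peak lists and the
`ms:spectrum` literal codec), `similarity` (the three scores),
`records_io` (MSP/JSON readers, JSON writer), `rdf_model` (triple
compilation, interlinking, classification, serialization),
`sparql_service` (store, extension functions, query, search) and
`synthetic_fixtures` (seeded corpus generation).

## The spectrum literal

Spectra travel inside RDF as typed literals whose lexical form is a
single-space-separated list of `mz:intensity` pairs with m/z ascending —
the same textual encoding MoNA uses for its spectrum strings. The canonical
serialization uses the shortest decimal representation that round-trips
through an IEEE double (trailing `.0` stripped), so `parse(serialize(s))`
reproduces peaks bit-for-bit and `serialize∘parse` is a fixed point. Plain
and scientific notation are accepted on input; NaN/Inf, non-positive m/z
and negative intensities are rejected with the offending token index. The
precursor m/z is deliberately *not* part of the literal: it is record
metadata, and the modified-cosine SPARQL function therefore takes explicit
precursor arguments.

## Similarity scores

All three scores share one kernel: candidate peak pairs within an inclusive
m/z tolerance (default 0.1 Da), pair score `w(a)·w(b)` with
`w(p) = mz^mz_power · intensity^intensity_power` (defaults 0 and 1,
mirroring the reference implementation this family of scores comes from),
an injective matching, and normalisation by the product of the full
weight-vector norms.

Numerical and policy choices:

* **Greedy tie-break** — candidates sorted by pair score descending, ties
  by ascending `(index_a, index_b)`; deterministic where sort stability is
  otherwise unspecified.
* **Optimal assignment** — `scipy.optimize.linear_sum_assignment` over the
  dense weight matrix restricted to peaks that occur in candidate pairs;
  assignment cells that are not admissible candidates are dropped
  afterwards (they contribute zero weight, so the total is unaffected).
  The solver is deterministic for a given input but does not guarantee any
  particular optimum when several matchings tie exactly; with continuous
  random intensities ties have measure zero, and every score-level contract
  (symmetry, dominance, oracle-equal totals) is independent of which
  optimum is returned. An exhaustive `brute_force_best_matching` oracle
  (≤ ~16 candidate pairs) backs the correctness tests.
* **Modified cosine** — the candidate set is the union of zero-shift pairs
  and pairs offset by `precursor(A) − precursor(B)`; a pair admissible
  under both shifts is counted once, as zero-shift, which prevents double
  matching when precursors nearly coincide. Assignment is greedy, matching
  the ported reference (verified against it to ~1e-16 in tests).
* **Zero-norm spectra** score 0 instead of raising, keeping SPARQL filter
  evaluation total. Scores are clamped to [0, 1] against last-bit
  round-off.
* `matched_peaks` counts every accepted candidate pair, including
  zero-weight ones — consistent with the injective-matching definition and
  with the reference implementation's match counts.

## RDF data model

Each record compiles to: an experiment node (`sio:SIO_001180`) with the
compound as input (`sio:SIO_000230`) and the spectrum (`obo:MS_1000294`) as
output (`sio:SIO_000229`); the spectrum bears its peak list via
`sio:SIO_000300` as an `ms:spectrum` literal. Every parameter, quality,
identifier and the SPLASH is a separate attribute node with exactly one
`rdf:type`, one value, and an optional UO unit, linked *from the attribute
to its bearer* (`sio:SIO_000553` to the experiment, `sio:SIO_000011` /
`sio:SIO_000672` to the compound, `sio:SIO_000672` to the spectrum for the
SPLASH) — the "is … of" reading of the SIO property labels. The direction
is isolated in the `Vocabulary` dataclass (`attribute_points_to_bearer`)
and can be flipped wholesale. Annotated peaks become `obo:MS_1000231`
nodes, component parts of the spectrum at a plain decimal `sio:SIO_000056`
position, each carrying an `sio:SIO_001166` annotation; tags are
annotations of the experiment. Experiments are organised into
`sio:SIO_000089` datasets (`dcterms:title`) and linked to `vcard:Individual`
submitters.

Term-mapping tables are deliberately small and overridable: PSI-MS types
for the common parameters (scan polarity MS:1000465, collision energy
MS:1000045, instrument MS:1000031, selected ion m/z MS:1000744), CHEMINF
types for identifiers (InChI CHEMINF:000113, InChIKey CHEMINF:000059,
PubChem CID / ChEBI / CAS) and common qualities, and UO IRIs for
electronvolt and dalton. Parameters and qualities without a mapping are
typed with a generic parameter class under the configurable `ms:`
namespace, and unknown units degrade to plain literals with a warning —
wrong-but-confident ontology ids are worse than explicitly local ones.

Node IRIs are minted deterministically from the record id (plus an ordinal
for attribute/peak nodes), so compilation is a pure function and N-Triples
output — serialized as lexicographically sorted lines — is byte-stable
across runs. Compound names and classification strings are carried by the
record model and the JSON round trip but are not compiled into triples;
classification enters the graph through the explicit cross-reference step
instead.

Interlinking is exact, byte-level InChI string equality, emitted one
direction only (local → external) as `skos:closeMatch`, Cartesian within a
match group. Classification supplementation consumes a pre-extracted
source-class → MeSH/ChEBI table; producing that table from a classification
ontology is outside this package's scope.

## SPARQL surface

The three functions are registered with `rdflib`'s custom-function
registry under the configurable `ms:` namespace (default a placeholder
IRI — point it at a production endpoint's function namespace for portable
queries). Signatures: `cosineGreedy(a, b[, tol])`,
`cosineHungarian(a, b[, tol])`, `modifiedCosine(a, precA, b, precB[, tol])`;
the optional tolerance defaults to the configured 0.1 Da, and the weighting
powers are fixed at their defaults on the SPARQL surface (full
parameterisation is available through the direct API — this keeps the
function IRIs simple). A malformed literal raises a SPARQL expression
error for that binding row only; standard error semantics drop the row, a
warning is logged, and the query completes.

The direct `similarity_search` API scans the spectrum index (built from
`has_value` triples carrying the `ms:spectrum` datatype, with precursors
recovered from the owning experiment's parameter attributes) and returns
hits sorted score-descending, ties by IRI. An optional precursor window
(± Da) prefilters candidates without scoring them; it is off by default.
Filter-query and direct-search results are asserted equal in the
acceptance tests for all three functions at thresholds 0.3/0.7/0.9.

## Synthetic corpus

The generator emulates the record *shape* of aggregated metabolite
libraries, not their chemistry: 5–20 fragment peaks uniform in 50–1000 Da,
exponential(1) intensities normalised to base peak 1 (long-tailed, as real
fragment intensity distributions are), precursor 1–50 Da above the highest
fragment. About 30% of records are perturbed family members of an earlier
record (0.01 Da m/z jitter, 10% dropout — comfortably inside the 0.1 Da
tolerance, so family members score ≥ 0.99 against their template), giving
similarity search realistic near-duplicates. 10% of compounds share their
(grammatically plausible, chemically meaningless) InChI with a planted
external compound table; classifications draw from an eight-class pool of
which the generated cross-reference map resolves half. All structure is
recorded in a `CorpusTruth` object so tests assert exact recovery.

What passing these tests does *not* show: robustness to real libraries'
metadata heterogeneity (free-text units, inconsistent field names),
profile-mode or noise-heavy spectra, or performance at repository scale
(millions of spectra) — the store is a linear-scan, in-memory design by
intent.

## Problem sizes and determinism

Test and acceptance runs use 100-record corpora, 200 random kernel
instances for the oracle comparison and 100 pairs for the reference
comparison — sizes at which the exhaustive oracle is exact and the full
suite runs in well under a minute. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; the acceptance script
derives per-stage sub-seeds from its single `--seed` argument, and repeated
runs with the same seed are bit-identical.

## Known limitations

* No neutral-loss or spectral-entropy scores; no spectral preprocessing
  (noise removal, top-K filtering).
* SPARQL federation (`SERVICE`), HTTP endpoint hosting and
  structure-based (substructure/similarity) compound search are out of
  scope; the identifier-join query archetype stands in for the
  structure-search leg.
* MSP support covers the common header set; exotic dialect extensions
  (multi-value comments, inline annotations) pass through as generic
  parameters.
* InChI equality is string equality: records whose InChIs differ only in
  normalisation will not link.
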