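# msrdf — spectral libraries as RDF, searchable by spectrum similarity

Tandem mass-spectral libraries (MoNA-style aggregating repositories,
in-silico spectral databases) are rich but poorly interoperable: each ships
its own record format, and searching them by spectral similarity usually
means a dedicated tool cut off from the rest of the semantic web. `msrdf`
addresses both problems at desk scale. It

* reads spectral-library records (NIST-style **MSP** text and a MoNA-style
  **JSON** dialect) into typed `SpectrumRecord` values;
* compiles them into an **RDF data model** built from established
  ontologies — SIO for the experiment/attribute pattern, the PSI-MS
  controlled vocabulary for experiment parameters, CHEMINF for compound
  identifiers and qualities, UO for units, Dublin Core, vCard and SKOS for
  provenance and cross-links — so the graphs join naturally with other
  semantic chemistry datasets;
* **interlinks compounds** across datasets by exact InChI string equality
  (`skos:closeMatch`) and can supplement compounds with MeSH/ChEBI classes
  through a classification cross-reference table;
* makes the graphs queryable with **SPARQL 1.1**, with three peak-matching
  similarity scores registered as extension functions usable inside
  `FILTER` expressions: `ms:cosineGreedy`, `ms:cosineHungarian` and
  `ms:modifiedCosine`.

It is aimed at metabolomics/proteomics informaticians who want spectral
similarity search *combined* with arbitrary graph criteria (identifiers,
classifications, provenance) in one declarative query.

## The similarity model

Spectra are centroided peak lists. For two spectra *A*, *B* every peak pair
(*a*, *b*) with |*m/z*(a) − *m/z*(b)| ≤ *tol* is a candidate, with pair score
w(a)·w(b) where w(p) = *m/z*(p)^α · I(p)^β (defaults α = 0, β = 1,
*tol* = 0.1 Da). An injective matching *M* (each peak used at most once)
gives the score

    S(A, B) = ( Σ_{(a,b)∈M} w(a)·w(b) ) / ( ‖w(A)‖ · ‖w(B)‖ )

so S(A, A) = 1 by Cauchy–Schwarz and S is invariant under intensity
rescaling. The three variants differ in how *M* is chosen:

* **cosine greedy** — accept candidates highest pair-score first;
* **cosine Hungarian** — the exact maximum-weight assignment
  (`scipy.optimize.linear_sum_assignment`);
* **modified cosine** — candidates may additionally be offset by the
  precursor-mass difference Δ = *prec*(A) − *prec*(B), capturing shared
  fragmentation between structurally related compounds; greedy assignment.

Because the spectrum literal carries peaks only, `ms:modifiedCosine` takes
the two precursor m/z values as explicit arguments.

## Worked example

The canonical divergence case between greedy and optimal matching: two
two-peak spectra whose central peaks (both intensity 1.0) are 0.05 Da apart,
with flanking 0.9-intensity peaks that only match *across* the pair.

```python
from msrdf import Spectrum, cosine_greedy, cosine_hungarian

a = Spectrum([(99.94, 0.9), (100.0, 1.0)])
b = Spectrum([(100.0, 1.0), (100.05, 0.9)])
print(cosine_greedy(a, b))
print(cosine_hungarian(a, b))
```

prints

```
SimilarityResult(score=0.5524861878453038, matched_peaks=1)
SimilarityResult(score=0.9944751381215469, matched_peaks=2)
```

Greedy locks onto the single 1.0·1.0 pair, blocking both 0.9 pairs
(score 1/1.81 ≈ 0.552); the Hungarian assignment takes the two 0.9 pairs
instead (score 1.8/1.81 ≈ 0.994). Both norms are √1.81.

The same search runs end to end from the shell — generate a synthetic
corpus, then rank its spectra against a query:

```bash
msrdf synth --seed 7 --n 50 --out corpus/
msrdf search --store corpus/ --spectrum "100.0:1 250.5:0.4" \
             --fn hungarian --threshold 0.7
```

which prints a TSV of spectrum IRIs with scores and matched-peak counts,
best first; a spectrum identical to the query scores 1.000000. Inside
SPARQL the same ranking is a filter:

```sparql
PREFIX sio: <http://semanticscience.org/resource/>
SELECT ?cmp ?spec WHERE {
  ?exp sio:SIO_000230 ?cmp ; sio:SIO_000229 ?spec .
  ?spec sio:SIO_000300 ?lit .
  FILTER(ms:cosineGreedy(?lit, "100.0:1 250.5:0.4"^^ms:spectrum) >= 0.7)
}
```

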