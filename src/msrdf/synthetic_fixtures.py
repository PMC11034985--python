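"""Seeded generators of synthetic spectra, records and corpora.

The generator emulates the *shape* of aggregated spectral-library exports —
centroided peak lists with long-tailed fragment intensities, precursor m/z
above the fragment range, experiment parameters, submitter/library
provenance, compound blocks with InChI strings — so that record readers,
the RDF compiler, interlinking and similarity search are all testable
without downloading any real library.

Chemistry is deliberately absent: InChI strings are grammatically plausible
but meaningless, and fragment m/z values are random.  Interlinking works by
exact string equality and peak matching by geometry, so neither needs real
chemistry to be exercised faithfully.  Alongside every corpus a
:class:`CorpusTruth` records the planted structure (perturbation families,
shared InChIs, classification cross-references) for tests to assert against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO

import numpy as np

from .records_io import (
    CompoundInfo,
    ExperimentParam,
    LibraryInfo,
    PeakAnnotation,
    Quality,
    SpectrumRecord,
    Submitter,
)
from .spectrum_core import Peak, Spectrum

__all__ = [
    "GeneratorConfig",
    "RecordTruth",
    "CorpusTruth",
    "generate_spectrum",
    "perturb_spectrum",
    "generate_corpus",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    Defaults emulate small-molecule MS/MS libraries: 5–20 fragment peaks per
    spectrum across 50–1000 Da, exponentially distributed intensities
    (long-tailed, base peak normalised to 1), m/z jitter of 0.01 Da and 10%
    peak dropout for perturbed family members, and 10% of compounds sharing
    an InChI with the external compound table.
    """

    seed: int = 0
    n_records: int = 100
    peaks_per_spectrum: tuple[int, int] = (5, 20)
    mz_range: tuple[float, float] = (50.0, 1000.0)
    intensity_model: str = "exponential"  # or "uniform"
    jitter_sd: float = 0.01
    dropout_rate: float = 0.1
    duplicate_inchi_rate: float = 0.1
    perturbed_family_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.peaks_per_spectrum[0] > self.peaks_per_spectrum[1]:
            raise ValueError("empty peak-count range")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("empty m/z range")
        for rate in (self.dropout_rate, self.duplicate_inchi_rate, self.perturbed_family_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.intensity_model not in ("exponential", "uniform"):
            raise ValueError(f"unknown intensity model {self.intensity_model!r}")


@dataclass(frozen=True)
class RecordTruth:
    record_id: str
    inchi: str
    parent_id: str | None = None
    expected_links: tuple[str, ...] = ()  # external compound IRIs sharing the InChI


@dataclass
class CorpusTruth:
    """Planted structure of a generated corpus."""

    records: dict[str, RecordTruth] = field(default_factory=dict)
    external_compounds: list[tuple[str, str]] = field(default_factory=list)
    xrefs: dict[str, list[str]] = field(default_factory=dict)
    classifications: list[tuple[str, str]] = field(default_factory=list)  # (record_id, class)

    def expected_link_set(self, compound_iri_of) -> set[tuple[str, str]]:
        """The exact cross-link set interlinking must produce, as
        (local compound IRI, external IRI) pairs."""
        return {
            (str(compound_iri_of(t.record_id)), external)
            for t in self.records.values()
            for external in t.expected_links
        }

    def to_json(self, stream: IO[str]) -> None:
        json.dump(
            {
                "records": [
                    {
                        "record_id": t.record_id,
                        "inchi": t.inchi,
                        "parent_id": t.parent_id,
                        "expected_links": list(t.expected_links),
                    }
                    for t in self.records.values()
                ],
                "external_compounds": self.external_compounds,
                "xrefs": self.xrefs,
                "classifications": self.classifications,
            },
            stream,
            indent=1,
        )

    @classmethod
    def from_json(cls, stream: IO[str]) -> "CorpusTruth":
        data = json.load(stream)
        return cls(
            records={
                r["record_id"]: RecordTruth(
                    r["record_id"], r["inchi"], r["parent_id"], tuple(r["expected_links"])
                )
                for r in data["records"]
            },
            external_compounds=[tuple(pair) for pair in data["external_compounds"]],
            xrefs=data["xrefs"],
            classifications=[tuple(pair) for pair in data["classifications"]],
        )


def generate_spectrum(config: GeneratorConfig, rng: np.random.Generator) -> Spectrum:
    """One synthetic centroided spectrum: i.i.d. uniform m/z (sorted),
    model-distributed intensities normalised to base peak 1, precursor m/z
    just above the fragment range."""
    low, high = config.peaks_per_spectrum
    n_peaks = int(rng.integers(low, high + 1))
    mz = np.sort(rng.uniform(config.mz_range[0], config.mz_range[1], size=n_peaks))
    if config.intensity_model == "exponential":
        intensities = rng.exponential(1.0, size=n_peaks)
    else:
        intensities = rng.uniform(0.0, 1.0, size=n_peaks)
    intensities = np.maximum(intensities, 1e-6)
    intensities /= intensities.max()
    precursor = float(mz[-1] + rng.uniform(1.0, 50.0))
    return Spectrum(
        [Peak(float(m), float(i)) for m, i in zip(mz, intensities)],
        precursor_mz=precursor,
    )


def perturb_spectrum(
    spectrum: Spectrum,
    jitter_sd: float,
    dropout_rate: float,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> Spectrum:
    """Gaussian m/z jitter plus independent peak dropout, keeping
    intensities; retries (up to ``max_retries``) if every peak drops out."""
    for _ in range(max_retries):
        kept = [p for p in spectrum.peaks if rng.random() >= dropout_rate]
        if not kept:
            continue
        jittered = sorted(
            (
                Peak(max(p.mz + float(rng.normal(0.0, jitter_sd)), 1e-6), p.intensity)
                for p in kept
            ),
            key=lambda p: p.mz,
        )
        return Spectrum(jittered, precursor_mz=spectrum.precursor_mz)
    raise ValueError(f"all peaks dropped out in {max_retries} attempts")


def _fake_inchi(rng: np.random.Generator) -> str:
    c = int(rng.integers(5, 40))
    h = int(rng.integers(4, 60))
    o = int(rng.integers(0, 10))
    n = int(rng.integers(0, 5))
    formula = f"C{c}H{h}" + (f"N{n}" if n else "") + (f"O{o}" if o else "")
    backbone = "-".join(str(int(v)) for v in rng.integers(1, c + 1, size=min(c, 6)))
    return f"InChI=1S/{formula}/c{backbone}/h{h}H"


_INSTRUMENTS = ["Q-TOF", "Orbitrap", "ion trap", "triple quadrupole"]
_SUBMITTERS = [
    ("Alex Doe", "alex@example.org"),
    ("Kim Lee", None),
    ("Sam Novak", "sam@example.org"),
]
_LIBRARIES = [
    LibraryInfo("synlib-A", "synthetic spectral library A"),
    LibraryInfo("synlib-B", "synthetic spectral library B"),
]
_TAG_POOL = ["LC-MS/MS", "in silico", "validated", "plant metabolite"]
_CLASS_POOL = [f"CLS:{i:04d}" for i in range(1, 9)]
_MESH = "http://id.nlm.nih.gov/mesh/"
_CHEBI = "http://purl.obolibrary.org/obo/CHEBI_"


def _splash(rng: np.random.Generator) -> str:
    digits = "".join(rng.choice(list("0123456789abcdef"), size=20))
    return f"splash10-{digits[:4]}-{digits[4:13]}-{digits[13:]}"


def _record(
    index: int,
    spectrum: Spectrum,
    inchi: str,
    rng: np.random.Generator,
) -> SpectrumRecord:
    record_id = f"SYN{index:06d}"
    params: list[ExperimentParam] = [
        ExperimentParam("precursor m/z", float(spectrum.precursor_mz))
    ]
    n_extra = int(rng.integers(0, 4))
    extras = rng.choice(3, size=n_extra, replace=False)
    ion_mode = "positive" if rng.random() < 0.5 else "negative"
    for extra in extras:
        if extra == 0:
            params.append(ExperimentParam("ion mode", ion_mode))
            spectrum = Spectrum(
                spectrum.peaks, precursor_mz=spectrum.precursor_mz, ion_mode=ion_mode
            )
        elif extra == 1:
            params.append(
                ExperimentParam("collision energy", float(rng.integers(10, 60)), "electronvolt")
            )
        else:
            params.append(
                ExperimentParam("instrument", _INSTRUMENTS[int(rng.integers(0, 4))])
            )
    qualities = ()
    if rng.random() < 0.5:
        qualities = (
            Quality(
                "total exact mass", float(np.round(spectrum.precursor_mz - 1.007, 4)), "dalton"
            ),
        )
    compound = CompoundInfo(
        inchi=inchi,
        names=(f"synthetic compound {index}",),
        qualities=qualities,
    )
    tags = tuple(
        str(t) for t in rng.choice(_TAG_POOL, size=int(rng.integers(0, 3)), replace=False)
    )
    annotations = ()
    if rng.random() < 0.3 and spectrum.peaks:
        peak = spectrum.peaks[int(rng.integers(0, len(spectrum.peaks)))]
        annotations = (PeakAnnotation(mz=peak.mz, text="fragment ion"),)
    name, email = _SUBMITTERS[int(rng.integers(0, len(_SUBMITTERS)))]
    return SpectrumRecord(
        record_id=record_id,
        spectrum=spectrum,
        compound=compound,
        params=tuple(params),
        splash=_splash(rng),
        submitter=Submitter(name, email),
        library=_LIBRARIES[int(rng.integers(0, 2))],
        tags=tags,
        peak_annotations=annotations,
    )


def generate_corpus(config: GeneratorConfig) -> tuple[list[SpectrumRecord], CorpusTruth]:
    """Generate ``n_records`` records plus the planted-structure truth.

    A ``perturbed_family_rate`` fraction of records are jittered/dropped-out
    copies of an earlier record's spectrum (analogue families for similarity
    search); a ``duplicate_inchi_rate`` fraction share their InChI with an
    entry of the external compound table (for interlinking); every compound
    carries 0–2 classification classes, half of which the generated
    cross-reference map resolves to MeSH/ChEBI targets.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SpectrumRecord] = []
    truth = CorpusTruth()

    # cross-reference map over half the classification pool
    for k, class_id in enumerate(_CLASS_POOL[: len(_CLASS_POOL) // 2]):
        targets = [f"{_MESH}D{9000 + k}"]
        if k % 2 == 0:
            targets.append(f"{_CHEBI}{70000 + k}")
        truth.xrefs[class_id] = targets

    templates: list[tuple[str, Spectrum]] = []
    for i in range(config.n_records):
        parent_id: str | None = None
        if templates and rng.random() < config.perturbed_family_rate:
            parent_id, parent_spectrum = templates[int(rng.integers(0, len(templates)))]
            spectrum = perturb_spectrum(
                parent_spectrum, config.jitter_sd, config.dropout_rate, rng
            )
        else:
            spectrum = generate_spectrum(config, rng)
        inchi = _fake_inchi(rng)
        record = _record(i, spectrum, inchi, rng)
        if parent_id is None:
            templates.append((record.record_id, spectrum))

        expected_links: tuple[str, ...] = ()
        if rng.random() < config.duplicate_inchi_rate:
            external_iri = f"http://example.org/external/compound/{i}"
            truth.external_compounds.append((external_iri, inchi))
            expected_links = (external_iri,)
        truth.records[record.record_id] = RecordTruth(
            record.record_id, inchi, parent_id, expected_links
        )
        for class_id in rng.choice(_CLASS_POOL, size=int(rng.integers(0, 3)), replace=False):
            truth.classifications.append((record.record_id, str(class_id)))
        records.append(record)

    # unlinkable external decoys
    for j in range(max(2, config.n_records // 20)):
        truth.external_compounds.append(
            (f"http://example.org/external/decoy/{j}", _fake_inchi(rng))
        )
    return records, truth
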