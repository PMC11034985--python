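import numpy as np
import pytest

from msrdf.config import Config
from msrdf.records_io import (
    CompoundInfo,
    ExperimentParam,
    LibraryInfo,
    Quality,
    SpectrumRecord,
    Submitter,
)
from msrdf.rdf_model import IriPolicy, Vocabulary, record_to_triples
from msrdf.spectrum_core import Spectrum
from msrdf.synthetic_fixtures import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def policy():
    return IriPolicy()


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary()


@pytest.fixture
def rng():
    return np.random.default_rng(20240321)


@pytest.fixture(scope="session")
def full_record():
    """A record exercising every compiled field: two experiment parameters
    (one with a unit), one compound quality, the InChI as the single
    compound identifier, a SPLASH, a titled library and a named submitter —
    no tags or peak annotations."""
    return SpectrumRecord(
        record_id="FIX0001",
        spectrum=Spectrum([(100.0, 0.5), (250.5, 1.0)], precursor_mz=300.2),
        compound=CompoundInfo(
            inchi="InChI=1S/C6H6/c1-2-4-6-5-3-1/h1-6H",
            qualities=(Quality("molecular formula", "C6H6"),),
        ),
        params=(
            ExperimentParam("collision energy", 45.0, "electronvolt"),
            ExperimentParam("ion mode", "positive"),
        ),
        splash="splash10-0002-0900000000-aaaaaaaaaaaaaaaaaaaa",
        submitter=Submitter("Alex Doe"),
        library=LibraryInfo("synthetic-library"),
    )


@pytest.fixture(scope="session")
def minimal_record():
    return SpectrumRecord(record_id="MIN0001", spectrum=Spectrum([(100.0, 1.0)]))


@pytest.fixture(scope="session")
def corpus():
    """A 100-record seeded synthetic corpus with its planted truth."""
    return generate_corpus(GeneratorConfig(seed=42, n_records=100))


@pytest.fixture(scope="session")
def corpus_graphs(corpus, policy, vocab, config):
    records, _ = corpus
    return [record_to_triples(r, policy, vocab, config) for r in records]
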