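import pytest

from nidphen.config import PipelineConfig
from nidphen.lexicon import load_demo_lexicon
from nidphen.pipeline import NIDPhenotypingModel
from nidphen.synth import SynthConfig, generate_corpus
from nidphen.textprep import load_default_stopwords


@pytest.fixture(scope="session")
def lexicon():
    return load_demo_lexicon()


@pytest.fixture(scope="session")
def stopwords():
    return load_default_stopwords()


@pytest.fixture(scope="session")
def small_corpus():
    """~370 notes from 300 patients; enough structure for every stage."""
    return generate_corpus(SynthConfig(n_patients=300, seed=7))


@pytest.fixture(scope="session")
def small_run(small_corpus):
    """A fitted pipeline on the small corpus (cheap bootstrap)."""
    cfg = PipelineConfig(seed=7, bootstrap_iterations=200)
    return NIDPhenotypingModel(small_corpus, config=cfg).fit()


@pytest.fixture(scope="session")
def default_run():
    """The default study-regime corpus (2469 patients, seed 1) fitted with
    the default configuration; shared across end-to-end assertions."""
    notes = generate_corpus(SynthConfig(seed=1))
    results = NIDPhenotypingModel(notes, config=PipelineConfig(seed=1)).fit()
    return notes, results
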