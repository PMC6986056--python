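import pytest
from hypothesis import HealthCheck, settings

from substispace import (
    CalibrationModel,
    CorpusConfig,
    annotate_catalog,
    fragment_corpus,
    generate_corpus,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """Deterministic 120-molecule synthetic corpus with ground-truth manifest."""
    return generate_corpus(CorpusConfig(seed=17, n_molecules=120))


@pytest.fixture(scope="session")
def small_catalog(small_corpus):
    return fragment_corpus(small_corpus.records, min_molecule_freq=2)


@pytest.fixture(scope="session")
def identity_model():
    """A fixed positive-slope calibration (unit slope, zero intercept)."""
    return CalibrationModel(slope=1.0, intercept=0.0, r_squared=1.0, n_train=2)


@pytest.fixture(scope="session")
def annotated_catalog(small_catalog, identity_model):
    return annotate_catalog(small_catalog, identity_model)
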