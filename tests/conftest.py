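import numpy as np
import pytest

from birex.documents import ENTITY_TYPES
from birex.fixtures import FixtureConfig, ToyEncoder, make_toy_corpus, make_toy_kb
from birex.tagger import build_label_schema, build_transition_mask, CrfParams


@pytest.fixture(scope="session")
def encoder() -> ToyEncoder:
    return ToyEncoder()


@pytest.fixture(scope="session")
def small_corpus():
    return make_toy_corpus(FixtureConfig(n_docs=30, seed=11))


@pytest.fixture(scope="session")
def toy_kb_bundle(encoder):
    cfg = FixtureConfig(n_docs=30, seed=11)
    return make_toy_kb(cfg, encoder)


@pytest.fixture(scope="session")
def six_type_schema():
    return build_label_schema(ENTITY_TYPES)


@pytest.fixture()
def random_crf_params(six_type_schema):
    """Factory: random masked CRF parameters over a small label space."""

    def make(rng: np.random.Generator, n_types: int = 2) -> CrfParams:
        schema = build_label_schema(ENTITY_TYPES[:n_types])
        mask, start, end = build_transition_mask(schema)
        return CrfParams(rng.normal(size=mask.shape), mask, start, end)

    return make
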