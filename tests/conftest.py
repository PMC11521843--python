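import pytest

from epletatlas import build_atlas, cohort_pairs, cohort_registry, example_registry


@pytest.fixture(scope="session")
def registry():
    return example_registry()


@pytest.fixture(scope="session")
def atlas(registry):
    return build_atlas(registry)


@pytest.fixture(scope="session")
def cohort():
    return cohort_registry(), cohort_pairs()
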