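import numpy as np
import pytest

from miniars.presets import preset
from miniars.synthetic import build_locus, fragment_library, truths_for_library


@pytest.fixture(scope="session")
def ars317_spec():
    return preset("ars317_like")


@pytest.fixture(scope="session")
def ars317_locus(ars317_spec):
    return build_locus(ars317_spec, seed=7)


@pytest.fixture(scope="session")
def ars317_fragments(ars317_locus):
    return fragment_library(ars317_locus, 200, (100, 200), seed=11)


@pytest.fixture(scope="session")
def ars317_truths(ars317_fragments, ars317_locus, ars317_spec):
    return truths_for_library(ars317_fragments, ars317_locus, ars317_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
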