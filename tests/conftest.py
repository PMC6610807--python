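import numpy as np
import pytest

from foldna.energy import builtin_model
from foldna.synthetic import FixtureSpec, make_corpus


@pytest.fixture(scope="session")
def model():
    return builtin_model()


@pytest.fixture(scope="session")
def small_corpus():
    """Mixed knotted/unknotted corpus, short sequences to keep folding cheap."""
    corpus, manifest = make_corpus(
        FixtureSpec(n_records=12, knot_probability=0.5, seed=11, length_min=18, length_max=26)
    )
    return corpus


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
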