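import numpy as np
import pytest

from superfam import TMScale, tm_tendency_scale

TOY_VALUES = {r: (1.0 if r == "A" else -1.0) for r in "ACDEFGHIKLMNPQRSTVWY"}


@pytest.fixture(scope="session")
def toy_scale() -> TMScale:
    """Two-valued scale: A = +1, everything else = -1."""
    return TMScale(values=dict(TOY_VALUES), name="toy")


@pytest.fixture(scope="session")
def published_scale() -> TMScale:
    return tm_tendency_scale()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
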