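import numpy as np
import pytest

from scqp import synthetic_data as sd


@pytest.fixture(scope="session")
def fixture_bundle() -> sd.FixtureBundle:
    """The deterministic worked fixture: one chip imaged under
    2 illuminations x 2 distances, plus a 30-subject cohort."""
    return sd.generate_worked_fixture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def random_colors() -> np.ndarray:
    """1e4 random 8-bit RGB triples, fixed seed, max channel > 0."""
    gen = np.random.default_rng(12345)
    cols = gen.integers(0, 256, size=(10_000, 3))
    cols[cols.max(axis=1) == 0] = (1, 0, 0)
    return cols
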