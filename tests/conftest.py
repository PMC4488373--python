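import numpy as np
import pytest

from streamsdm.units import SampleUnitGrid


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study system shared across pipeline tests."""
    from streamsdm.pipeline import simulate_study

    return simulate_study(3, nrows=120, ncols=120, accum_threshold_cells=50,
                          n_records=200, n_survey_units=15)


@pytest.fixture
def full_lattice():
    """A 20x20 all-units lattice (200 m cells) for label-module tests."""
    n = 20
    ids = {(r, c) for r in range(n) for c in range(n)}
    return SampleUnitGrid((0.0, n * 200.0), 200.0, n, n, ids)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
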