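import pytest

from aptamin import default_parameters, gol1_sequence, mfe_fold
from aptamin.synth import SyntheticAptamerSpec, make_synthetic_aptamer


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def gol1():
    return gol1_sequence()


@pytest.fixture(scope="session")
def gol1_fold(gol1, params):
    return mfe_fold(gol1, params)


@pytest.fixture(scope="session")
def synthetic_parent(params):
    """A U2-like three-way-junction parent with known coordinates."""
    spec = SyntheticAptamerSpec(seed=1)
    seq, pt, coords = make_synthetic_aptamer(spec, params)
    return spec, seq, pt, coords
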