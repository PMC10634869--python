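import numpy as np
import pytest

from midzone.filaments import Filament, FilamentNetwork


def straight(fid, start, end, n=2, plus_end="end"):
    """Straight filament from start to end with n points."""
    pts = np.linspace(np.asarray(start, float), np.asarray(end, float), n)
    return Filament(id=fid, points=pts, plus_end=plus_end)


@pytest.fixture
def parallel_pair():
    """Two parallel 500 nm filaments spaced 50 nm apart."""
    return FilamentNetwork(filaments=(
        straight(0, (0, 0, 0), (500, 0, 0), n=6),
        straight(1, (0, 50, 0), (500, 50, 0), n=6),
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
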