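import numpy as np
import pandas as pd
import pytest

from wbsleep.io import Connectome, RegionTable
from wbsleep.synth import make_connectome, make_regions


@pytest.fixture(scope="session")
def regions4() -> RegionTable:
    """Four regions, two homotopic pairs, last pair thalamic."""
    return make_regions(4, n_thalamus_pairs=1)


@pytest.fixture(scope="session")
def regions30() -> RegionTable:
    return make_regions(30)


@pytest.fixture(scope="session")
def connectome30() -> Connectome:
    return make_connectome(30, seed=0)


@pytest.fixture(scope="session")
def small_connectome() -> Connectome:
    """Deterministic 4-node ring with homotopic links."""
    w = np.array(
        [
            [0.0, 0.3, 0.5, 0.2],
            [0.3, 0.0, 0.2, 0.5],
            [0.5, 0.2, 0.0, 0.3],
            [0.2, 0.5, 0.3, 0.0],
        ]
    )
    return Connectome(weights=w, regions=make_regions(4))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
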