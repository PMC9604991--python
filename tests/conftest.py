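import numpy as np
import pytest

from oanet.connectome import Connectome, synthesize_connectome
from oanet.model import ModelParams


@pytest.fixture(scope="session")
def single_region() -> Connectome:
    """One isolated ensemble (no coupling possible)."""
    return Connectome(1, np.zeros((1, 1)), np.zeros((1, 1)))


@pytest.fixture(scope="session")
def two_region() -> Connectome:
    """Two ensembles joined by a unit edge 17.1 mm apart (5 ms at 3.42 m/s)."""
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    D = np.array([[0.0, 17.1], [17.1, 0.0]])
    return Connectome(2, A, D)


@pytest.fixture(scope="session")
def small_connectome() -> Connectome:
    return synthesize_connectome(8, 3)


@pytest.fixture(scope="session")
def connectome16() -> Connectome:
    return synthesize_connectome(16, 7)


def short_params(**kw) -> ModelParams:
    defaults = dict(t_total=5.0, t_transient=0.0)
    defaults.update(kw)
    return ModelParams(**defaults)
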