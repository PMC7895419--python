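import numpy as np
import pytest

from pggchoice import GameEnsemble, MutationRates


@pytest.fixture
def fig1_ensemble() -> GameEnsemble:
    """The canonical two-resource parameter set (g=10, r=(4.4, 2.8), c=pi0=1)."""
    return GameEnsemble(n=2, r=(4.4, 2.8), g=10)


@pytest.fixture
def fig1_rates() -> MutationRates:
    return MutationRates.symmetric(1e-3)


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    """A uniform draw on the 2n-simplex, shaped (2, n)."""
    return rng.dirichlet(np.ones(2 * n)).reshape(2, n)
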