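import numpy as np
import pytest

from tnaswitch.model_core import DEFAULT_PARAMS, Environment, ReducedParams


@pytest.fixture(scope="session")
def params() -> ReducedParams:
    """Reference (calibrated) parameter set."""
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def experimental_grid() -> list[Environment]:
    """The 5x5 (W_e, G_e) condition grid used in the experiments."""
    return [
        Environment(G_e=g, W_e=w)
        for w in (0.0, 6.0, 12.0, 24.0, 48.0)
        for g in (0.0, 3.75, 7.5, 15.0, 30.0)
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
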