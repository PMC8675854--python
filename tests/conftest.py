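import numpy as np
import pytest

from bgct import ModelParameters


@pytest.fixture(scope="session")
def table_params() -> ModelParameters:
    """The typical operating point of the loop."""
    return ModelParameters()


@pytest.fixture(scope="session")
def decoupled_params() -> ModelParameters:
    """All connection weights and dopamine zero: 7 independent leaks."""
    zeros = {name: 0.0 for name in
             ("T16", "T21", "T26", "T31", "T36", "T42", "T45",
              "T47", "T53", "T57", "T64", "T71", "T75")}
    return ModelParameters().replace(Dinput=0.0, **zeros)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210416)
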