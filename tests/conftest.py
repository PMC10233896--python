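import numpy as np
import pytest

from caimnet import (
    CalciumRenderSpec,
    DynamicsSpec,
    NetworkSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A short control-like co-culture recording with ground truth."""
    rec, truth = generate_dataset(
        NetworkSpec(n_neurons=40, n_modules=4),
        DynamicsSpec(duration_s=120.0),
        CalciumRenderSpec(),
        condition="control_like",
        seed=7,
    )
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
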