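import numpy as np
import pytest

from itnsim import ModelParams


def single_params(**overrides) -> ModelParams:
    """One parameter set with neutral defaults, overridable per test."""
    base = dict(
        N=1e6, b=1.0, d=0.5, x_f=0.0, x_m=0.0, m1=0.5, m2=0.5,
        f0_A=1e-3, f0_B=1e-3, r_A=0.5, r_B=0.5, hr_A=0.5, hr_B=0.5,
        c_A=0.0, c_B=0.0, hc_A=0.5, hc_B=0.5,
    )
    base.update(overrides)
    return ModelParams.from_dict(base)


@pytest.fixture
def params_factory():
    return single_params


@pytest.fixture
def rng():
    return np.random.default_rng(42)
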