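import numpy as np
import pytest

from rtrbm.model_core import RBMParams, RTRBMParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rbm(rng, nv=3, nh=2, scale=1.0) -> RBMParams:
    return RBMParams(
        rng.normal(0, scale, (nh, nv)),
        rng.normal(0, scale, nv),
        rng.normal(0, scale, nh),
    )


def random_rtrbm(rng, nv=3, nh=2, scale=1.0) -> RTRBMParams:
    return RTRBMParams(
        rng.normal(0, scale, (nh, nv)),
        rng.normal(0, scale, (nh, nh)),
        rng.normal(0, scale, nv),
        rng.normal(0, scale, nh),
        rng.normal(0, scale, nh),
    )
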