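import numpy as np
import pytest
from hypothesis import settings

from nichecomp import CompetitionParams, DensityState

settings.register_profile("suite", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def classic_params() -> CompetitionParams:
    """Shared rate set of the classic-family panels (strict hierarchy)."""
    return CompetitionParams(beta1=0.2, beta2=0.8, mu1=0.1, mu2=0.1, k=1.0, v=0.0)


@pytest.fixture
def general_params() -> CompetitionParams:
    """Partial mutual displacement: invader evicts 90%, resident evicts 10%."""
    return CompetitionParams(beta1=0.2, beta2=0.8, mu1=0.1, mu2=0.1, k=0.9, v=0.1)


def random_params(rng: np.random.Generator, k=None, v=None) -> CompetitionParams:
    """A valid random rate set (rates on the scale of the built-in panels)."""
    return CompetitionParams(
        beta1=float(rng.uniform(0.05, 2.0)),
        beta2=float(rng.uniform(0.05, 2.0)),
        mu1=float(rng.uniform(0.0, 1.0)),
        mu2=float(rng.uniform(0.0, 1.0)),
        k=float(rng.uniform(0.0, 1.0)) if k is None else k,
        v=float(rng.uniform(0.0, 1.0)) if v is None else v,
    )


def random_state(rng: np.random.Generator) -> DensityState:
    r1 = float(rng.uniform(0.0, 1.0))
    r2 = float(rng.uniform(0.0, 1.0 - r1))
    return DensityState(r1, r2)
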