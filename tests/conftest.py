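import numpy as np
import pytest

from nucleitrack.gmm_core import GaussianComponent, MixtureParams, NucleusPriors


@pytest.fixture
def priors() -> NucleusPriors:
    return NucleusPriors(d_nuc=10.0, w_nuc=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_mixture(rng: np.random.Generator, K: int, shape=(16, 16)) -> MixtureParams:
    """Random well-conditioned mixture for oracle comparisons."""
    h, w = shape
    comps = []
    for _ in range(K):
        s1 = rng.uniform(1.5, 6.0)
        s2 = rng.uniform(1.5, 6.0)
        r = rng.uniform(-0.5, 0.5)
        s12 = r * np.sqrt(s1 * s2)
        comps.append(
            GaussianComponent(
                w=rng.uniform(0.3, 2.0),
                mu=np.array([rng.uniform(0, w - 1), rng.uniform(0, h - 1)]),
                S=np.array([[s1, s12], [s12, s2]]),
            )
        )
    return MixtureParams(comps)
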