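import numpy as np
import pytest

from antactivity import ModelParams, harvester_ant_params


@pytest.fixture
def paper_params() -> ModelParams:
    """Calibrated rates at N=500 with beta0 = 10 gamma0 (strong contagion)."""
    return harvester_ant_params(500, beta0_ratio=10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20241125)


def random_params(rng: np.random.Generator, rate_range=(1e-2, 1e2)) -> ModelParams:
    """Log-uniform rates, uniform alpha in [1, 2], log-uniform N in [10, 1000]."""
    lo, hi = np.log(rate_range[0]), np.log(rate_range[1])
    b0, g0, d, e0 = np.exp(rng.uniform(lo, hi, size=4))
    return ModelParams(
        beta0=float(b0),
        gamma0=float(g0),
        delta=float(d),
        E0=float(e0),
        alpha=float(rng.uniform(1.0, 2.0)),
        N=int(np.exp(rng.uniform(np.log(10), np.log(1000)))),
    )
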