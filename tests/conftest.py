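import numpy as np
import pytest

from hetnetcc import PipelineConfig, SyntheticScenario, generate


@pytest.fixture(scope="session")
def small_bundle():
    """Two-block unit-test dataset (g=30, m=20, n=10)."""
    return generate(SyntheticScenario.small(seed=0))


@pytest.fixture(scope="session")
def recovery_bundle():
    """Three-block parameter-recovery dataset (g=90, m=60, n=20)."""
    return generate(SyntheticScenario.recovery(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def fast_config():
    """Short training budget for unit tests."""
    return PipelineConfig(k=2, epochs=60, max_iter=150, seed=0)


def random_awcc_instance(seed, g=8, m=6, n=5, k=2, v=2):
    """A random non-negative co-clustering problem for optimizer tests."""
    r = np.random.default_rng(seed)
    W_list = [r.uniform(size=(g, m)) for _ in range(v)]
    X11 = r.uniform(size=(g, n))
    X21 = r.uniform(size=(m, n))
    return W_list, X11, X21
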