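import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pchiassoc import GenotypeDataset, nat2_panel

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def nat2():
    return nat2_panel()


@pytest.fixture
def make_dataset():
    """Random polymorphic case-control dataset factory (HWE genotypes)."""

    def _make(n=80, q=4, seed=0, maf=None):
        rng = np.random.default_rng(seed)
        f = np.full(q, maf) if maf is not None else rng.uniform(0.2, 0.5, q)
        while True:
            g = rng.binomial(2, f, size=(n, q))
            if all(g[:, k].min() < g[:, k].max() for k in range(q)):
                break
        y = np.zeros(n, dtype=int)
        y[: n // 2] = 1
        return GenotypeDataset(g, y, [f"S{k + 1}" for k in range(q)])

    return _make
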