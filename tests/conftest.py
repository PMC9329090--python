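import numpy as np
import pytest

import evoscreen as ev


@pytest.fixture(scope="session")
def toy_genome():
    return ev.gen_toy_genome(2, 30000, 20, seed=1)


@pytest.fixture(scope="session")
def ems_variant_set(toy_genome):
    """Large EMS-biased set for spectrum/zygosity convergence checks."""
    return ev.gen_variant_set(
        toy_genome, 1000, ems_fraction=0.9, het_fraction=0.97, seed=7
    )


@pytest.fixture
def daily_grid():
    return np.arange(0.0, 169.0, 24.0)
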