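import numpy as np
import pytest

from prognet.core import ExpressionMatrix
from prognet.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A scaled-down study for fast end-to-end tests."""
    return SimConfig(
        seed=7,
        n_probes=200,
        n_planted=15,
        n_patients=200,
        n_genes=60,
        peaks_per_factor=80,
        chrom_len=200_000,
        n_fpkm_genes=400,
        n_de_up=20,
        n_de_down=20,
    )


@pytest.fixture
def random_matrix(rng):
    values = rng.normal(5.0, 1.0, size=(20, 8))
    return ExpressionMatrix(
        [f"F{i}" for i in range(20)], [f"S{j}" for j in range(8)], values
    )
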