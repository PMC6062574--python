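import numpy as np
import pytest

from umisense.ercc import SpikeInDesign, geometric_ladder
from umisense.simdata import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_cells=12,
        gene_means=np.full(100, 3.0),
        gene_dispersions=np.full(100, 0.4),
        capture_efficiency=0.2,
        reads_per_cell=3000,
        seed=7,
    )


@pytest.fixture(scope="session")
def ladder():
    return geometric_ladder()


@pytest.fixture(scope="session")
def small_bundle(small_config, ladder):
    return simulate_experiment(small_config, ladder)


@pytest.fixture
def tiny_design():
    return SpikeInDesign(["ERCC-A", "ERCC-B", "ERCC-C"], np.array([1.0, 10.0, 100.0]))
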