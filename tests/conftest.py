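import numpy as np
import pytest

from aavbench import SimulationConfig, generate_barcode_library, simulate_reads


@pytest.fixture(scope="session")
def library():
    """14-variant, 44-mer barcode library with the default anchors."""
    return generate_barcode_library(n_variants=14, seed=11)


@pytest.fixture(scope="session")
def small_library():
    return generate_barcode_library(n_variants=3, seed=7)


@pytest.fixture(scope="session")
def clean_reads(library):
    """2000 error-free read pairs with per-read ground truth."""
    return simulate_reads(library, SimulationConfig(seed=21, n_reads=2000,
                                                    base_error_rate=0.0))


@pytest.fixture(scope="session")
def noisy_reads(library):
    """2000 read pairs at the platform-realistic 0.3% substitution rate."""
    return simulate_reads(library, SimulationConfig(seed=22, n_reads=2000,
                                                    base_error_rate=0.003))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
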