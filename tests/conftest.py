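import numpy as np
import pytest

from clipchimera.detect import MiRNACatalog, MiRNAEntry
from clipchimera.duplex import default_params
from clipchimera.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def catalog():
    """Small hand-built catalogue with one two-member seed family."""
    return MiRNACatalog([
        MiRNAEntry("miR-a", "TGAGGTAGTAGGTTGTATAGTT"),
        # same positions 1-12, divergent 3' end (seed family with miR-a)
        MiRNAEntry("miR-b", "TGAGGTAGTAGGAATGCCTACA"),
        MiRNAEntry("miR-c", "TAAGGCACGCGGTGAATGCCAA"),
    ])


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def sim_small():
    """A reduced synthetic experiment shared across pipeline tests."""
    return simulate_experiment(SimConfig(rng_seed=11, n_reads=8000, n_genes=60,
                                         n_sites=150))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
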