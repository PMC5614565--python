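import numpy as np
import pytest

from wrcbind import MechanismSpec
from wrcbind.synthetic_data import NoiseSpec, make_titration, simulate_isotherm

# generating constants used throughout: intact-complex (sequential fit),
# A-site-dead (single site), and D-site-dead (GST-dimer avidity) conditions
WT_SEQUENTIAL = {"K_D_D": 0.169, "K_D_A_D": 0.262}
A_DEAD_SINGLE = {"K_D_D": 0.265}
D_DEAD_GST = {"K_D_A": 11.52, "K_D_Aprime": 0.033}


@pytest.fixture(scope="session")
def wt_isotherm():
    """Noise-free 24-point isotherm under the sequential two-site mechanism."""
    return simulate_isotherm(MechanismSpec("sequential_two_site", WT_SEQUENTIAL))


@pytest.fixture(scope="session")
def noisy_single_site_isotherm():
    """Single-site isotherm with gel-level noise, fixed seed."""
    return simulate_isotherm(
        MechanismSpec("single_site", A_DEAD_SINGLE),
        noise=NoiseSpec(sd=0.02, seed=42),
    )


@pytest.fixture(scope="session")
def titration():
    return make_titration()
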