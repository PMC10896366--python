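import numpy as np
import pytest

import pingmf as pm


@pytest.fixture(scope="session")
def reference():
    """Calibrated reference configuration (healthy couplings)."""
    return pm.reference_config()


@pytest.fixture(scope="session")
def uncoupled():
    """Single homogeneous population: no synapses, no heterogeneity."""
    return pm.ReducedParams(
        tau=10.0,
        coupling=pm.CouplingParams(),
        drive=pm.DriveParams(Ibar_e=2.0, Delta_e=0.0, Ibar_i=0.0, Delta_i=0.0),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
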