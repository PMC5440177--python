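"""Shared fixtures: the standard schedule, a noiseless analytic input
function, and a noiseless two-tissue test TAC with known VT."""

import numpy as np
import pytest

from petquant import (CompartmentalParams, build_frame_schedule,
                      simulate_tissue_tac, uniform_weights)
from petquant.synthetic import generate_input_function

#: two-tissue truth used across modules: VT = K1/k2*(1+k3/k4) = 8.0
TRUE_4K = CompartmentalParams(K1=0.45, k2=0.30, k3=0.65, k4=0.15, bv=0.0)
TRUE_4K_VT = 8.0 + 1e-14  # guard against exact-representation assumptions


@pytest.fixture(scope="session")
def schedule():
    return build_frame_schedule()


@pytest.fixture(scope="session")
def noiseless_if(schedule):
    """(ground-truth ppIF, noise-free blood sample table)."""
    rng = np.random.default_rng(42)
    return generate_input_function(rng, schedule, noise_scale=0.0)


@pytest.fixture(scope="session")
def ppif(noiseless_if):
    return noiseless_if[0]


@pytest.fixture(scope="session")
def equal_weights(schedule):
    return uniform_weights(schedule)


@pytest.fixture(scope="session")
def tac_4k(ppif, schedule):
    """Noiseless frame TAC of the VT=8 two-tissue truth (bv = 0)."""
    return simulate_tissue_tac(TRUE_4K, ppif, schedule, label="truth_vt8")
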