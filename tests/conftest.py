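"""Shared fixtures.

The expensive session fixtures (reduced-theory context, standard rate
curves) are computed once and reused by the unit and acceptance tests.
"""

import numpy as np
import pytest

from gainswitch.params import NeuronParams, reduced_params
from gainswitch.rates import compute_rate_curve, default_r_E_grid
from gainswitch.theory import build_context


@pytest.fixture(scope="session")
def reduced_ctx():
    """Reduced-model theory context at the standard drive
    (g_synE = 3, g_synI = 5, r_I = 50), with the paper-scale dead time."""
    return build_context(reduced_params(), r_I=50.0, R=10.0,
                         b_duration=60_000.0, seed=1234)


@pytest.fixture(scope="session")
def fig2_curves():
    """Standard full-model rate curves (g_synE = 0.5, g_synI = 1,
    r_I = 50 Hz) at the divisive and subtractive endpoints g_A = 20, 40."""
    out = {}
    for g_A in (20.0, 40.0):
        p = NeuronParams(g_A=g_A, g_syn_E=0.5, g_syn_I=1.0)
        out[g_A] = compute_rate_curve(p, default_r_E_grid(), r_I=50.0,
                                      duration=20_000.0, seed=77)
    return out
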