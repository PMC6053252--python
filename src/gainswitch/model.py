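"""Membrane equations: ionic currents, gating kinetics and right-hand sides.

The point neuron carries leak, delayed-rectifier potassium, A-type potassium
and sodium currents,

    C V' = -I_L - I_K - I_A - I_Na - g_synE s_E (V - V_E) - g_synI s_I (V - V_I)

with I_L = g_L (V - V_L), I_K = g_K n^4 (V - V_K), I_A = g_A a^3 b (V - V_K)
and I_Na = g_Na m_inf(V)^3 (1 - n) (V - V_Na).  Gates n, a, b follow
first-order kinetics X' = phi_X (X_inf(V) - X) / tau_X.  In the reduced model
the fast activation gate is slaved to voltage, a = a_inf(V).

The cable variant chains nine passive compartments onto the soma; only the
soma carries voltage-gated currents.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .params import CableParams, InvalidParameterError, NeuronParams


class IntegrationFailureError(RuntimeError):
    """Raised when a right-hand side is evaluated on a non-finite state."""


# --------------------------------------------------------------------------
# gating functions
# --------------------------------------------------------------------------

_GATE_DIR = {"n": 1.0, "a": 1.0, "b": -1.0}


def m_inf(V):
    """Instantaneous sodium activation."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) + 30.0) / 15.0))


def gate_steady_state(gate: str, V, params: NeuronParams = NeuronParams()):
    """Steady-state sigmoid of gate ``n``, ``a`` or ``b``.

    Monotone increasing for the activation gates (n, a), decreasing for the
    inactivation gate (b); equals 1/2 at the half-activation voltage.
    """
    if gate not in _GATE_DIR:
        raise InvalidParameterError(f"unknown gate {gate!r}")
    theta = getattr(params, f"theta_{gate}")
    sigma = getattr(params, f"sigma_{gate}")
    V = np.asarray(V, float)
    return 1.0 / (1.0 + np.exp(-_GATE_DIR[gate] * (V - theta) / sigma))


def tau_n(V):
    """Voltage-dependent time constant of potassium activation (ms)."""
    return 1.0 + 100.0 / (1.0 + np.exp((np.asarray(V, float) + 80.0) / 26.0))


def gate_tau(gate: str, V, params: NeuronParams = NeuronParams()):
    if gate == "n":
        return tau_n(V)
    if gate == "a":
        return params.tau_a
    if gate == "b":
        return params.tau_b
    raise InvalidParameterError(f"unknown gate {gate!r}")


# --------------------------------------------------------------------------
# currents and right-hand sides
# --------------------------------------------------------------------------

def ionic_currents(state, params: NeuronParams):
    """(I_L, I_K, I_A, I_Na) in uA/cm^2 for state ``(V, n, a, b)``.

    When ``params.instantaneous_a`` the stored ``a`` is ignored and replaced
    by ``a_inf(V)``.
    """
    V, n, a, b = state
    if params.instantaneous_a:
        a = gate_steady_state("a", V, params)
    I_L = params.g_L * (V - params.V_L)
    I_K = params.g_K * n ** 4 * (V - params.V_K)
    I_A = params.g_A * a ** 3 * b * (V - params.V_K)
    I_Na = params.g_Na * m_inf(V) ** 3 * (1.0 - n) * (V - params.V_Na)
    return I_L, I_K, I_A, I_Na


def point_rhs(t, state, params: NeuronParams, s_E: float, s_I: float):
    """Time derivatives (V', n', a', b') of the point neuron.

    ``s_E`` and ``s_I`` are the synaptic gate values at time ``t``; they are
    inputs, not state, because their resets are handled outside the ODE.
    """
    state = np.asarray(state, float)
    if not np.all(np.isfinite(state)):
        raise IntegrationFailureError(f"non-finite state at t={t}")
    V, n, a, b = state
    I_L, I_K, I_A, I_Na = ionic_currents(state, params)
    I_syn = (params.g_syn_E * s_E * (V - params.V_E)
             + params.g_syn_I * s_I * (V - params.V_I))
    dV = -(I_L + I_K + I_A + I_Na + I_syn) / params.C
    dn = params.phi_n * (gate_steady_state("n", V, params) - n) / tau_n(V)
    if params.instantaneous_a:
        da = 0.0
    else:
        da = params.phi_a * (gate_steady_state("a", V, params) - a) / params.tau_a
    db = params.phi_b * (gate_steady_state("b", V, params) - b) / params.tau_b
    return np.array([dV, dn, da, db])


def axial_currents(V, cable: CableParams):
    """Discrete-divergence axial stencil; sums to zero over compartments."""
    V = np.asarray(V, float)
    I = np.empty_like(V)
    I[0] = cable.g_ax * (V[0] - V[1])
    I[1:-1] = cable.g_ax * (-V[:-2] + 2.0 * V[1:-1] - V[2:])
    I[-1] = cable.g_ax * (V[-1] - V[-2])
    return I


def cable_rhs(t, state, params: NeuronParams, cable: CableParams,
              s_E: float, s_I: float):
    """Derivatives of the 13-dimensional cable state
    ``(V_1..V_10, n, a, b)``; gating lives in the soma (compartment 1)."""
    state = np.asarray(state, float)
    if not np.all(np.isfinite(state)):
        raise IntegrationFailureError(f"non-finite state at t={t}")
    V = state[:10]
    n, a, b = state[10:]
    I_ax = axial_currents(V, cable)
    soma_state = np.array([V[0], n, a, b])
    I_L, I_K, I_A, I_Na = ionic_currents(soma_state, params)

    dV = np.empty(10)
    dV[0] = -(I_L + I_K + I_A + I_Na + I_ax[0]) / params.C
    dV[1:] = -(cable.g_L_dend * (V[1:] - params.V_L) + I_ax[1:]) / params.C

    j_exc = cable.cpt_in  # dendritic site k lives at compartment k+1 = index k
    dV[j_exc] -= params.g_syn_E * s_E * (V[j_exc] - params.V_E) / params.C
    j_inh = cable.cpt_inhib  # 0 = soma
    dV[j_inh] -= params.g_syn_I * s_I * (V[j_inh] - params.V_I) / params.C

    dn = params.phi_n * (gate_steady_state("n", V[0], params) - n) / tau_n(V[0])
    if params.instantaneous_a:
        da = 0.0
    else:
        da = params.phi_a * (gate_steady_state("a", V[0], params) - a) / params.tau_a
    db = params.phi_b * (gate_steady_state("b", V[0], params) - b) / params.tau_b
    return np.concatenate([dV, [dn, da, db]])


# --------------------------------------------------------------------------
# resting state
# --------------------------------------------------------------------------

def resting_state(params: NeuronParams) -> np.ndarray:
    """Input-free equilibrium ``(V, n, a, b)`` with gates at steady state.

    Found by root-finding the total membrane current with each gate slaved to
    voltage (at equilibrium X = X_inf(V) exactly).
    """
    def total_current(V):
        n = gate_steady_state("n", V, params)
        a = gate_steady_state("a", V, params)
        b = gate_steady_state("b", V, params)
        return sum(ionic_currents((V, n, a, b), params))

    # the model can have rest, threshold and depolarized equilibria; rest is
    # the lowest-V zero, so bracket the first sign change scanning upward
    grid = np.arange(-95.0, -40.0, 0.5)
    vals = np.array([total_current(v) for v in grid])
    idx = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    if idx.size == 0:
        raise InvalidParameterError("no resting equilibrium found below -40 mV")
    V0 = optimize.brentq(total_current, grid[idx[0]], grid[idx[0] + 1], xtol=1e-10)
    return np.array([V0,
                     gate_steady_state("n", V0, params),
                     gate_steady_state("a", V0, params),
                     gate_steady_state("b", V0, params)])


def resting_state_cable(params: NeuronParams, cable: CableParams) -> np.ndarray:
    """Input-free cable equilibrium (13-vector)."""
    def F(V):
        y = np.concatenate([V, [gate_steady_state("n", V[0], params),
                                gate_steady_state("a", V[0], params),
                                gate_steady_state("b", V[0], params)]])
        return cable_rhs(0.0, y, params, cable, 0.0, 0.0)[:10]

    V = optimize.fsolve(F, np.full(10, params.V_L), xtol=1e-12)
    return np.concatenate([V, [gate_steady_state("n", V[0], params),
                               gate_steady_state("a", V[0], params),
                               gate_steady_state("b", V[0], params)]])
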