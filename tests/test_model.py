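"""Membrane model: gating curves, currents, right-hand sides, cable."""

import numpy as np
import pytest

from gainswitch.inputs import EventTrain
from gainswitch.model import (axial_currents, cable_rhs, gate_steady_state,
                              ionic_currents, m_inf, point_rhs, resting_state,
                              resting_state_cable, tau_n)
from gainswitch.params import CableParams, InvalidParameterError, NeuronParams
from gainswitch.simulate import simulate

P = NeuronParams()


class TestGatingCurves:
    @pytest.mark.parametrize("gate,theta", [("n", -32.0), ("a", -50.0),
                                            ("b", -70.0)])
    def test_half_activation_at_theta(self, gate, theta):
        assert gate_steady_state(gate, theta, P) == pytest.approx(0.5)

    def test_tau_n_at_minus_80(self):
        assert tau_n(-80.0) == pytest.approx(51.0)

    def test_monotone_directions(self):
        V = np.linspace(-100, 20, 200)
        assert np.all(np.diff(gate_steady_state("n", V, P)) > 0)
        assert np.all(np.diff(gate_steady_state("a", V, P)) > 0)
        assert np.all(np.diff(gate_steady_state("b", V, P)) < 0)
        assert np.all(np.diff(m_inf(V)) > 0)


class TestIonicCurrents:
    def test_potassium_currents_vanish_at_reversal(self):
        I_L, I_K, I_A, I_Na = ionic_currents((-80.0, 0.4, 0.3, 0.5), P)
        assert I_K == 0.0 and I_A == 0.0

    def test_leak_vanishes_at_leak_reversal(self):
        assert ionic_currents((-70.0, 0.4, 0.3, 0.5), P)[0] == 0.0

    def test_no_A_current_without_conductance(self):
        p = P.replace(g_A=0.0)
        assert ionic_currents((-30.0, 0.2, 0.9, 0.9), p)[2] == 0.0


class TestPointRhs:
    def test_resting_equilibrium_is_fixed_point(self):
        rest = resting_state(P)
        dy = point_rhs(0.0, rest, P, 0.0, 0.0)
        assert np.all(np.abs(dy) < 1e-8)

    def test_gate_derivative_signs_follow_first_order_kinetics(self):
        V = -55.0
        for i, gate in enumerate(("n", "a", "b"), start=1):
            x_inf = gate_steady_state(gate, V, P)
            below = np.array([V, 0.0, 0.0, 0.0])
            below[i] = x_inf - 0.1
            above = np.array([V, 0.0, 0.0, 0.0])
            above[i] = x_inf + 0.1
            assert point_rhs(0.0, below, P, 0.0, 0.0)[i] > 0
            assert point_rhs(0.0, above, P, 0.0, 0.0)[i] < 0

    def test_nonfinite_state_raises(self):
        from gainswitch.model import IntegrationFailureError
        with pytest.raises(IntegrationFailureError):
            point_rhs(0.0, [np.nan, 0.1, 0.1, 0.1], P, 0.0, 0.0)

    def test_reduced_and_full_agree_without_A_current(self):
        p_full = P.replace(g_A=0.0)
        p_red = P.replace(g_A=0.0, instantaneous_a=True)
        y = np.array([-55.0, 0.2, 0.3, 0.6])
        d_full = point_rhs(0.0, y, p_full, 0.5, 0.2)
        d_red = point_rhs(0.0, y, p_red, 0.5, 0.2)
        np.testing.assert_allclose(d_full[[0, 1, 3]], d_red[[0, 1, 3]])


def test_gating_variables_stay_in_unit_interval():
    # strong drive for half a second; all gates must remain in [0, 1]
    p = NeuronParams(g_A=40.0, g_syn_E=1.0, g_syn_I=2.0)
    exc = EventTrain(times=np.arange(5.0, 500.0, 10.0), kind="excitatory",
                     rate=100.0, duration=500.0, mode="periodic")
    inh = EventTrain(times=np.arange(0.0, 500.0, 20.0), kind="inhibitory",
                     rate=50.0, duration=500.0, mode="periodic")
    res = simulate(p, exc, inh, 500.0, record_stride=5)
    for trace in (res.n, res.a, res.b):
        assert trace.min() >= 0.0 and trace.max() <= 1.0


def test_fast_activation_limit_converges_to_reduced_model():
    # as tau_A -> 0 the full model approaches the instantaneous-a variant
    exc = EventTrain(times=np.arange(10.0, 2000.0, 40.0), kind="excitatory",
                     rate=25.0, duration=2000.0, mode="periodic")
    inh = EventTrain(times=np.arange(0.0, 2000.0, 20.0), kind="inhibitory",
                     rate=50.0, duration=2000.0, mode="periodic")
    base = dict(g_A=20.0, g_syn_E=3.0, g_syn_I=5.0)
    ref = simulate(NeuronParams(instantaneous_a=True, **base), exc, inh,
                   2000.0, record_stride=0)
    gaps = []
    for tau in (0.5, 0.1, 0.01):
        res = simulate(NeuronParams(tau_a=tau, **base), exc, inh, 2000.0,
                       dt=min(0.005, tau / 5), record_stride=0)
        if len(res.spike_times) == len(ref.spike_times):
            gap = np.max(np.abs(res.spike_times - ref.spike_times))
        else:
            gap = np.inf
        gaps.append(gap)
    assert gaps[-1] < 0.5            # spike-for-spike agreement in the limit
    assert gaps[2] <= gaps[0] + 1e-9  # and monotone approach


class TestCable:
    CABLE = CableParams(cpt_in=4, cpt_inhib=0)

    def test_axial_stencil_is_conservative(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(-80, 0, size=10)
        assert axial_currents(V, self.CABLE).sum() == pytest.approx(0.0, abs=1e-9)

    def test_rest_is_common_and_near_leak_reversal(self):
        y = resting_state_cable(P, self.CABLE)
        assert np.all(np.abs(y[:10] - P.V_L) < 3.0)
        assert np.max(np.abs(y[:10] - y[0])) < 1.0
        # with every voltage-gated conductance removed, rest is exactly V_L
        p0 = P.replace(g_A=0.0, g_K=0.0, g_Na=0.0)
        y0 = resting_state_cable(p0, self.CABLE)
        np.testing.assert_allclose(y0[:10], -70.0, atol=1e-6)

    def test_invalid_site_indices_raise(self):
        with pytest.raises(InvalidParameterError):
            CableParams(cpt_in=0)
        with pytest.raises(InvalidParameterError):
            CableParams(cpt_inhib=10)

    def test_distal_inputs_attenuate_and_delay_somatic_response(self):
        exc = EventTrain(times=np.array([20.0]), kind="excitatory",
                         rate=1.0, duration=120.0, mode="periodic")
        # subthreshold drive: somatic EPSP attenuates and peaks later as the
        # input site moves distally
        p_weak = NeuronParams(g_A=0.0, g_syn_E=0.3, g_syn_I=0.0)
        peaks, epsp_lat = [], []
        for site in (1, 5, 9):
            res = simulate(p_weak, exc, None, 120.0, record_stride=2,
                           cable=CableParams(cpt_in=site))
            soma = res.V[:, 0]
            peaks.append(soma.max())
            epsp_lat.append(res.t[np.argmax(soma)])
        assert peaks[0] > peaks[1] > peaks[2]
        assert epsp_lat[0] < epsp_lat[1] < epsp_lat[2]
        # suprathreshold drive: spikes initiate with millisecond-scale extra
        # delay for distal inputs
        p_strong = NeuronParams(g_A=0.0, g_syn_E=3.0, g_syn_I=0.0)
        spike_lat = []
        for site in (1, 5, 9):
            res = simulate(p_strong, exc, None, 120.0, record_stride=0,
                           cable=CableParams(cpt_in=site))
            assert res.spike_times.size >= 1
            spike_lat.append(res.spike_times[0] - 20.0)
        assert spike_lat[0] < spike_lat[1] < spike_lat[2]
        assert spike_lat[2] - spike_lat[0] > 1.0

    def test_dendritic_inhibition_also_suppresses_firing(self):
        # inhibition targeting the dendrite instead of the soma still
        # reduces the somatic output on matched input trains
        p = NeuronParams(g_A=20.0, g_syn_E=2.0, g_syn_I=2.0)
        exc = EventTrain(times=np.arange(10.0, 4000.0, 25.0),
                         kind="excitatory", rate=40.0, duration=4000.0,
                         mode="periodic")
        inh = EventTrain(times=np.arange(0.0, 4000.0, 20.0),
                         kind="inhibitory", rate=50.0, duration=4000.0,
                         mode="periodic")
        counts = {}
        for g_syn_I, label in ((0.0, "off"), (2.0, "dendritic")):
            cable = CableParams(cpt_in=4, cpt_inhib=4)
            res = simulate(p.replace(g_syn_I=g_syn_I), exc, inh, 4000.0,
                           record_stride=0, cable=cable)
            counts[label] = len(res.spike_times)
        assert counts["dendritic"] < counts["off"]

    def test_strong_axial_coupling_approaches_isopotential(self):
        # subthreshold drive keeps the comparison free of action potentials,
        # whose dendritic attenuation would dominate the voltage spread
        p = NeuronParams(g_A=0.0, g_syn_E=0.3, g_syn_I=0.0)
        exc = EventTrain(times=np.array([20.0]), kind="excitatory",
                         rate=1.0, duration=60.0, mode="periodic")
        spreads = []
        for g_ax in (5.0, 20.0, 80.0):
            cable = CableParams(g_ax=g_ax, cpt_in=5)
            # explicit step limit scales with the axial coupling stiffness
            res = simulate(p, exc, None, 60.0, dt=min(0.005, 0.5 / g_ax),
                           record_stride=2, cable=cable)
            spreads.append(np.max(np.abs(res.V - res.V[:, [0]])))
        assert spreads[0] > spreads[1] > spreads[2]
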