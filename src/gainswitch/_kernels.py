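"""Compiled fixed-step integrators for the neuron models.

Synaptic gate resets are discontinuities, so integration proceeds span by
span between consecutive event times (every event is a mesh point) with the
gates evaluated in closed form ``s(t) = s0 exp(-beta (t - t0))`` at the
Runge-Kutta stage times.  Within a span a classical fourth-order explicit
step with a small fixed step size is used; the fastest membrane time scale
(C over the peak total conductance) is a few hundredths of a millisecond, so
the default step of 0.005 ms resolves it comfortably and halving the step
leaves spike counts unchanged on fixed trains.

Spikes are detected inside the integrator as upward crossings of a voltage
threshold with a lockout interval, with the crossing time interpolated
linearly within the step.
"""

import numpy as np
from numba import njit

# parameter-vector layout (float64)
#  0 C      1 g_L    2 g_K    3 g_Na   4 g_A    5 V_L    6 V_K    7 V_Na
#  8 phi_n  9 tau_a 10 tau_b 11 phi_a 12 phi_b
# 13 g_synE 14 g_synI 15 V_E 16 V_I  17 beta_E 18 beta_I
# 19 instantaneous_a (0/1)
# 20 theta_n 21 sigma_n 22 theta_a 23 sigma_a 24 theta_b 25 sigma_b
N_PARAMS = 26


def pack_params(p) -> np.ndarray:
    """Flatten a NeuronParams record into the kernel parameter vector."""
    return np.array([
        p.C, p.g_L, p.g_K, p.g_Na, p.g_A, p.V_L, p.V_K, p.V_Na,
        p.phi_n, p.tau_a, p.tau_b, p.phi_a, p.phi_b,
        p.g_syn_E, p.g_syn_I, p.V_E, p.V_I, p.beta_E, p.beta_I,
        1.0 if p.instantaneous_a else 0.0,
        p.theta_n, p.sigma_n, p.theta_a, p.sigma_a, p.theta_b, p.sigma_b,
    ], dtype=np.float64)


@njit(cache=True, inline="always")
def _point_deriv(V, n, a, b, sE, sI, p):
    minf = 1.0 / (1.0 + np.exp(-(V + 30.0) / 15.0))
    ninf = 1.0 / (1.0 + np.exp(-(V - p[20]) / p[21]))
    ainf = 1.0 / (1.0 + np.exp(-(V - p[22]) / p[23]))
    binf = 1.0 / (1.0 + np.exp((V - p[24]) / p[25]))
    taun = 1.0 + 100.0 / (1.0 + np.exp((V + 80.0) / 26.0))
    aval = ainf if p[19] != 0.0 else a
    I = (p[1] * (V - p[5])
         + p[2] * n ** 4 * (V - p[6])
         + p[4] * aval ** 3 * b * (V - p[6])
         + p[3] * minf ** 3 * (1.0 - n) * (V - p[7])
         + p[13] * sE * (V - p[15])
         + p[14] * sI * (V - p[16]))
    dV = -I / p[0]
    dn = p[8] * (ninf - n) / taun
    da = 0.0 if p[19] != 0.0 else p[11] * (ainf - a) / p[9]
    db = p[12] * (binf - b) / p[10]
    return dV, dn, da, db


@njit(cache=True)
def integrate_point(y0, duration, dt, tE, tI, p,
                    thresh, lockout, transient, stride):
    """Integrate the point neuron over [0, duration].

    Returns (spike_times, spike_sI, b_mean, t_rec, rec, y_final) where
    ``spike_sI`` holds, for each spike, the inhibitory gate value at the most
    recent excitatory event, ``b_mean`` is the time average of b over
    [transient, duration], and ``rec`` is the (V, n, a, b, sE, sI) trace
    sampled every ``stride`` substeps (empty when stride == 0).
    """
    V, n, a, b = y0[0], y0[1], y0[2], y0[3]
    sE = 0.0
    sI = 0.0
    betaE, betaI = p[17], p[18]

    max_spk = int(duration / max(lockout, 0.1)) + 4
    spikes = np.empty(max_spk)
    spike_sI = np.empty(max_spk)
    nspk = 0
    last_spike = -1e18
    sI_at_E = 0.0

    nE, nI = len(tE), len(tI)
    iE = 0
    iI = 0

    nrec = 0
    if stride > 0:
        cap = int(duration / dt) + nE + nI + 16
        cap = cap // stride + 4
        t_rec = np.empty(cap)
        rec = np.empty((cap, 6))
        t_rec[0] = 0.0
        rec[0, 0] = V
        rec[0, 1] = n
        rec[0, 2] = a
        rec[0, 3] = b
        rec[0, 4] = sE
        rec[0, 5] = sI
        nrec = 1
    else:
        t_rec = np.empty(0)
        rec = np.empty((0, 6))

    b_int = 0.0
    b_time = 0.0
    t = 0.0
    step_count = 0

    while t < duration - 1e-12:
        t_next = duration
        if iE < nE and tE[iE] < t_next:
            t_next = tE[iE]
        if iI < nI and tI[iI] < t_next:
            t_next = tI[iI]
        span = t_next - t
        if span > 1e-12:
            nsub = int(np.ceil(span / dt))
            h = span / nsub
            fE = np.exp(-betaE * 0.5 * h)
            fI = np.exp(-betaI * 0.5 * h)
            for _ in range(nsub):
                sE1 = sE * fE
                sI1 = sI * fI
                sE2 = sE1 * fE
                sI2 = sI1 * fI
                k1V, k1n, k1a, k1b = _point_deriv(V, n, a, b, sE, sI, p)
                k2V, k2n, k2a, k2b = _point_deriv(V + 0.5 * h * k1V,
                                                  n + 0.5 * h * k1n,
                                                  a + 0.5 * h * k1a,
                                                  b + 0.5 * h * k1b,
                                                  sE1, sI1, p)
                k3V, k3n, k3a, k3b = _point_deriv(V + 0.5 * h * k2V,
                                                  n + 0.5 * h * k2n,
                                                  a + 0.5 * h * k2a,
                                                  b + 0.5 * h * k2b,
                                                  sE1, sI1, p)
                k4V, k4n, k4a, k4b = _point_deriv(V + h * k3V,
                                                  n + h * k3n,
                                                  a + h * k3a,
                                                  b + h * k3b,
                                                  sE2, sI2, p)
                Vn = V + h / 6.0 * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
                nn = n + h / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
                an = a + h / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
                bn = b + h / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
                if V < thresh and Vn >= thresh and t + h - last_spike >= lockout:
                    frac = (thresh - V) / (Vn - V)
                    last_spike = t + frac * h
                    if nspk < max_spk:
                        spikes[nspk] = last_spike
                        spike_sI[nspk] = sI_at_E
                        nspk += 1
                if t >= transient:
                    b_int += 0.5 * (b + bn) * h
                    b_time += h
                V, n, a, b = Vn, nn, an, bn
                sE = sE2
                sI = sI2
                t += h
                step_count += 1
                if stride > 0 and step_count % stride == 0 and nrec < len(t_rec):
                    t_rec[nrec] = t
                    rec[nrec, 0] = V
                    rec[nrec, 1] = n
                    rec[nrec, 2] = a
                    rec[nrec, 3] = b
                    rec[nrec, 4] = sE
                    rec[nrec, 5] = sI
                    nrec += 1
        t = t_next
        while iE < nE and tE[iE] <= t + 1e-12:
            sE = 1.0
            sI_at_E = sI
            iE += 1
        while iI < nI and tI[iI] <= t + 1e-12:
            sI = 1.0
            iI += 1

    b_mean = b_int / b_time if b_time > 0 else b
    y_final = np.array([V, n, a, b])
    return (spikes[:nspk], spike_sI[:nspk], b_mean,
            t_rec[:nrec], rec[:nrec], y_final)


@njit(cache=True)
def _cable_deriv(y, sE, sI, p, g_ax, g_L_dend, j_exc, j_inh, out):
    V0 = y[0]
    n = y[10]
    a = y[11]
    b = y[12]
    minf = 1.0 / (1.0 + np.exp(-(V0 + 30.0) / 15.0))
    ninf = 1.0 / (1.0 + np.exp(-(V0 - p[20]) / p[21]))
    ainf = 1.0 / (1.0 + np.exp(-(V0 - p[22]) / p[23]))
    binf = 1.0 / (1.0 + np.exp((V0 - p[24]) / p[25]))
    taun = 1.0 + 100.0 / (1.0 + np.exp((V0 + 80.0) / 26.0))
    aval = ainf if p[19] != 0.0 else a
    I_soma = (p[1] * (V0 - p[5])
              + p[2] * n ** 4 * (V0 - p[6])
              + p[4] * aval ** 3 * b * (V0 - p[6])
              + p[3] * minf ** 3 * (1.0 - n) * (V0 - p[7]))
    # axial stencil
    out[0] = -(I_soma + g_ax * (y[0] - y[1])) / p[0]
    for j in range(1, 9):
        I_ax = g_ax * (-y[j - 1] + 2.0 * y[j] - y[j + 1])
        out[j] = -(g_L_dend * (y[j] - p[5]) + I_ax) / p[0]
    out[9] = -(g_L_dend * (y[9] - p[5]) + g_ax * (y[9] - y[8])) / p[0]
    out[j_exc] -= p[13] * sE * (y[j_exc] - p[15]) / p[0]
    out[j_inh] -= p[14] * sI * (y[j_inh] - p[16]) / p[0]
    out[10] = p[8] * (ninf - n) / taun
    out[11] = 0.0 if p[19] != 0.0 else p[11] * (ainf - a) / p[9]
    out[12] = p[12] * (binf - b) / p[10]


@njit(cache=True)
def integrate_cable(y0, duration, dt, tE, tI, p, g_ax, g_L_dend,
                    j_exc, j_inh, thresh, lockout, transient, stride):
    """Cable analogue of :func:`integrate_point`; spikes are detected on the
    somatic voltage.  Trace rows are (V_1..V_10, n, a, b, sE, sI)."""
    m = 13
    y = y0.copy()
    sE = 0.0
    sI = 0.0
    betaE, betaI = p[17], p[18]

    max_spk = int(duration / max(lockout, 0.1)) + 4
    spikes = np.empty(max_spk)
    spike_sI = np.empty(max_spk)
    nspk = 0
    last_spike = -1e18
    sI_at_E = 0.0

    nE, nI = len(tE), len(tI)
    iE = 0
    iI = 0

    k1 = np.empty(m)
    k2 = np.empty(m)
    k3 = np.empty(m)
    k4 = np.empty(m)
    ytmp = np.empty(m)
    ynew = np.empty(m)

    nrec = 0
    if stride > 0:
        cap = int(duration / dt) + nE + nI + 16
        cap = cap // stride + 4
        t_rec = np.empty(cap)
        rec = np.empty((cap, m + 2))
        t_rec[0] = 0.0
        for i in range(m):
            rec[0, i] = y[i]
        rec[0, m] = sE
        rec[0, m + 1] = sI
        nrec = 1
    else:
        t_rec = np.empty(0)
        rec = np.empty((0, m + 2))

    b_int = 0.0
    b_time = 0.0
    t = 0.0
    step_count = 0

    while t < duration - 1e-12:
        t_next = duration
        if iE < nE and tE[iE] < t_next:
            t_next = tE[iE]
        if iI < nI and tI[iI] < t_next:
            t_next = tI[iI]
        span = t_next - t
        if span > 1e-12:
            nsub = int(np.ceil(span / dt))
            h = span / nsub
            fE = np.exp(-betaE * 0.5 * h)
            fI = np.exp(-betaI * 0.5 * h)
            for _ in range(nsub):
                sE1 = sE * fE
                sI1 = sI * fI
                sE2 = sE1 * fE
                sI2 = sI1 * fI
                _cable_deriv(y, sE, sI, p, g_ax, g_L_dend, j_exc, j_inh, k1)
                for i in range(m):
                    ytmp[i] = y[i] + 0.5 * h * k1[i]
                _cable_deriv(ytmp, sE1, sI1, p, g_ax, g_L_dend, j_exc, j_inh, k2)
                for i in range(m):
                    ytmp[i] = y[i] + 0.5 * h * k2[i]
                _cable_deriv(ytmp, sE1, sI1, p, g_ax, g_L_dend, j_exc, j_inh, k3)
                for i in range(m):
                    ytmp[i] = y[i] + h * k3[i]
                _cable_deriv(ytmp, sE2, sI2, p, g_ax, g_L_dend, j_exc, j_inh, k4)
                for i in range(m):
                    ynew[i] = y[i] + h / 6.0 * (k1[i] + 2.0 * k2[i]
                                                + 2.0 * k3[i] + k4[i])
                V, Vn = y[0], ynew[0]
                if V < thresh and Vn >= thresh and t + h - last_spike >= lockout:
                    frac = (thresh - V) / (Vn - V)
                    last_spike = t + frac * h
                    if nspk < max_spk:
                        spikes[nspk] = last_spike
                        spike_sI[nspk] = sI_at_E
                        nspk += 1
                if t >= transient:
                    b_int += 0.5 * (y[12] + ynew[12]) * h
                    b_time += h
                for i in range(m):
                    y[i] = ynew[i]
                sE = sE2
                sI = sI2
                t += h
                step_count += 1
                if stride > 0 and step_count % stride == 0 and nrec < len(t_rec):
                    t_rec[nrec] = t
                    for i in range(m):
                        rec[nrec, i] = y[i]
                    rec[nrec, m] = sE
                    rec[nrec, m + 1] = sI
                    nrec += 1
        t = t_next
        while iE < nE and tE[iE] <= t + 1e-12:
            sE = 1.0
            sI_at_E = sI
            iE += 1
        while iI < nI and tI[iI] <= t + 1e-12:
            sI = 1.0
            iI += 1

    b_mean = b_int / b_time if b_time > 0 else y[12]
    return (spikes[:nspk], spike_sI[:nspk], b_mean,
            t_rec[:nrec], rec[:nrec], y.copy())


@njit(cache=True)
def integrate_b_quasi(b0, duration, dt, events, beta, g_syn, V_rev,
                      g_L, V_L, tau_b, phi_b, theta_b, sigma_b, transient):
    """Scalar inactivation equation b' = phi_b (b_inf(V(t)) - b) / tau_b
    driven by the quasi-steady voltage of a leak + one-synapse membrane,
    V(s) = (g_L V_L + g_syn s V_rev) / (g_L + g_syn s), with the gate s
    following the reset-and-decay rule on the given event train.

    Returns the time average of b over [transient, duration].
    """
    b = b0
    s = 0.0
    ne = len(events)
    ie = 0
    t = 0.0
    b_int = 0.0
    b_time = 0.0
    while t < duration - 1e-12:
        t_next = duration
        if ie < ne and events[ie] < t_next:
            t_next = events[ie]
        span = t_next - t
        if span > 1e-12:
            nsub = int(np.ceil(span / dt))
            h = span / nsub
            f = np.exp(-beta * 0.5 * h)
            for _ in range(nsub):
                s1 = s * f
                s2 = s1 * f
                V0 = (g_L * V_L + g_syn * s * V_rev) / (g_L + g_syn * s)
                V1 = (g_L * V_L + g_syn * s1 * V_rev) / (g_L + g_syn * s1)
                V2 = (g_L * V_L + g_syn * s2 * V_rev) / (g_L + g_syn * s2)
                bi0 = 1.0 / (1.0 + np.exp((V0 - theta_b) / sigma_b))
                bi1 = 1.0 / (1.0 + np.exp((V1 - theta_b) / sigma_b))
                bi2 = 1.0 / (1.0 + np.exp((V2 - theta_b) / sigma_b))
                k1 = phi_b * (bi0 - b) / tau_b
                k2 = phi_b * (bi1 - (b + 0.5 * h * k1)) / tau_b
                k3 = phi_b * (bi1 - (b + 0.5 * h * k2)) / tau_b
                k4 = phi_b * (bi2 - (b + h * k3)) / tau_b
                bn = b + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                if t >= transient:
                    b_int += 0.5 * (b + bn) * h
                    b_time += h
                b = bn
                s = s2
                t += h
        t = t_next
        while ie < ne and events[ie] <= t + 1e-12:
            s = 1.0
            ie += 1
    return b_int / b_time if b_time > 0 else b
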