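"""Reduced-model analysis: fast-slow dissection, nullcline knees, the
critical A-conductance, and the dead-time-modified Poisson rate theory.

The reduced model slaves A-current activation to voltage (``a = a_inf(V)``)
and treats ``V`` as fast against the slow gates ``n`` and ``b``.  Whether an
excitatory event can evoke a spike is decided by the *left knee* of the
V-nullcline of the ``s_E = 1`` phase plane: a spike requires the state to
sit below the knee, so if the knee lies below ``n = 0`` the neuron cannot
respond at all.  Writing ``N_lk(s_I, r_E, g_A)`` for the knee's n-value
(with the slow inactivation gate replaced by its input-rate-dependent
average ``b*_av(r_E)``), the theory yields

* the critical conductance ``g_A^0`` where ``N_lk(sigma*, 0, g_A)`` crosses
  zero -- the divisive/subtractive transition point;
* the minimum responsive input rate ``Gamma(g_A)`` for ``g_A > g_A^0``;
* a firing threshold ``theta`` on the inhibitory gate, computed as the fixed
  point of two maps between ``theta`` and the mean recovery level ``n_av``,
  which plugs into a dead-time-modified Poisson rate formula
  ``r_out = r_E rho / (1 + r_E R / 1000)``.

Periodic inhibition with period ``P_I`` keeps its gate above the floor
``sigma* = exp(-beta_I P_I)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import optimize

from . import _kernels
from .inputs import generate_periodic_train, generate_poisson_train
from .model import gate_steady_state, m_inf, tau_n
from .params import InvalidParameterError, NeuronParams, reduced_params
from .simulate import simulate
from .inputs import input_pair


class KneeNotFoundError(RuntimeError):
    """The V-nullcline has no fold on the requested side."""


class NoTransitionError(RuntimeError):
    """The knee does not change sign over the search interval."""


# --------------------------------------------------------------------------
# elementary pieces
# --------------------------------------------------------------------------

def sigma_star(beta_I: float, r_I: float) -> float:
    """Floor of the periodic inhibitory gate, exp(-beta_I * P_I)."""
    if r_I <= 0:
        raise InvalidParameterError("r_I must be > 0")
    return float(np.exp(-beta_I * 1000.0 / r_I))


def quasi_steady_V(s_E: float, s_I: float, params: NeuronParams) -> float:
    """Quasi-steady voltage of the passive (leak + synapses) membrane:
    the conductance-weighted average of the three reversal potentials."""
    num = (params.g_L * params.V_L + params.g_syn_E * s_E * params.V_E
           + params.g_syn_I * s_I * params.V_I)
    den = params.g_L + params.g_syn_E * s_E + params.g_syn_I * s_I
    return num / den


def quasi_steady_V_E(s_E: float, params: NeuronParams) -> float:
    return quasi_steady_V(s_E, 0.0, params)


def quasi_steady_V_I(s_I: float, params: NeuronParams) -> float:
    return quasi_steady_V(0.0, s_I, params)


def rho_fraction(theta: float, P_I: float, beta_I: float) -> float:
    """Fraction of the inhibitory period during which s_I < theta,
    1 + ln(theta) / (P_I beta_I), clipped to [0, 1]."""
    if theta <= 0:
        raise InvalidParameterError("theta must be > 0")
    return float(np.clip(1.0 + np.log(theta) / (P_I * beta_I), 0.0, 1.0))


def deadtime_rate(r_E: float, R: float, rho: float = 1.0) -> float:
    """Dead-time-modified Poisson output rate, r_E rho / (1 + r_E R / 1000)
    (rates in events/s, dead time R in ms)."""
    return r_E * rho / (1.0 + r_E * R / 1000.0)


def fit_refractory_R(r_E, r_out) -> float:
    """Least-squares dead time R (ms) from a no-inhibition rate curve."""
    r_E = np.asarray(r_E, float)
    r_out = np.asarray(r_out, float)
    popt, _ = optimize.curve_fit(
        lambda x, R: deadtime_rate(x, R), r_E, r_out, p0=[10.0], maxfev=10000)
    return float(popt[0])


# --------------------------------------------------------------------------
# b averages
# --------------------------------------------------------------------------

def b_average(r_E: float, method: Literal["full", "passive", "reduced"],
              params: NeuronParams,
              r_I: float = 50.0,
              duration: float = 100_000.0,
              seed: int = 0,
              dt: float = 0.02) -> float:
    """Average of the slow inactivation gate b along solutions.

    ``full``     time-average of b from a simulation of the given model.
    ``passive``  b_hat_av(r_E) = b_hat_I + b_hat_E(r_E) - b_hat_E(0) from
                 simulations with g_A = g_K = g_Na = 0 driven separately by
                 only-inhibitory and only-excitatory trains.
    ``reduced``  b*_av(r_E) = b*_I + b*_E(r_E) - b*_E(0) from the scalar
                 b-equation driven by the quasi-steady one-synapse voltages.
    """
    if r_E < 0:
        raise InvalidParameterError("r_E must be >= 0")
    if method == "full":
        exc, inh = input_pair(r_E, r_I, duration, seed)
        res = simulate(params, exc, inh, duration, dt=dt,
                       transient=min(1500.0, duration / 4), record_stride=0)
        return res.b_mean
    if method == "passive":
        passive = params.replace(g_A=0.0, g_K=0.0, g_Na=0.0)
        bI = _b_passive_component(passive, r_I=r_I, r_E=None,
                                  duration=duration, seed=seed, dt=dt)
        bE = _b_passive_component(passive, r_I=None, r_E=r_E,
                                  duration=duration, seed=seed, dt=dt)
        bE0 = _b_passive_component(passive, r_I=None, r_E=0.0,
                                   duration=duration, seed=seed, dt=dt)
        return bI + bE - bE0
    if method == "reduced":
        return (b_star_I(params, r_I=r_I, dt=dt)
                + b_star_E(r_E, params, duration=duration, seed=seed, dt=dt)
                - b_star_E(0.0, params, duration=duration, seed=seed, dt=dt))
    raise InvalidParameterError(f"unknown b-average method {method!r}")


def _b_passive_component(passive: NeuronParams, r_I, r_E,
                         duration, seed, dt) -> float:
    if r_I is not None:
        exc, inh = None, generate_periodic_train(r_I, duration)
    else:
        exc = generate_poisson_train(r_E, duration, seed=seed) if r_E else None
        inh = None
    res = simulate(passive, exc, inh, duration, dt=dt,
                   transient=min(1500.0, duration / 4), record_stride=0)
    return res.b_mean


def b_star_I(params: NeuronParams, r_I: float = 50.0, dt: float = 0.02) -> float:
    """Average of b over the periodic limit cycle of the scalar b-equation
    driven by V_I(s_I(t)); deterministic (one period after a 10 tau_b
    transient)."""
    P_I = 1000.0 / r_I
    transient = 10.0 * params.tau_b
    n_per = int(np.ceil(transient / P_I)) + 1
    duration = (n_per + 1) * P_I
    events = np.arange(0.0, duration + 0.5 * P_I, P_I)
    b0 = gate_steady_state("b", params.V_L, params)
    return float(_kernels.integrate_b_quasi(
        b0, duration, dt, events, params.beta_I, params.g_syn_I, params.V_I,
        params.g_L, params.V_L, params.tau_b, params.phi_b,
        params.theta_b, params.sigma_b, n_per * P_I))


def b_star_E(r_E: float, params: NeuronParams,
             duration: float = 100_000.0, seed: int = 0,
             dt: float = 0.02) -> float:
    """Average of b under Poisson excitation through the quasi-steady
    voltage V_E(s_E(t)), from a long seeded scalar simulation."""
    b0 = gate_steady_state("b", params.V_L, params)
    if r_E == 0:
        return float(b0)  # V stays at V_L = theta_b, so b rests at 1/2
    train = generate_poisson_train(r_E, duration, seed=seed)
    return float(_kernels.integrate_b_quasi(
        b0, duration, dt, train.times, params.beta_E, params.g_syn_E,
        params.V_E, params.g_L, params.V_L, params.tau_b, params.phi_b,
        params.theta_b, params.sigma_b, min(1500.0, duration / 4)))


# --------------------------------------------------------------------------
# V-nullcline and knees
# --------------------------------------------------------------------------

def _quartic_coeffs(V, b, s_E, s_I, g_A, params: NeuronParams):
    """The V-nullcline equation of the reduced model is quartic in n:
    A n^4 + B n + C = 0 (no quadratic or cubic term)."""
    V = np.asarray(V, float)
    A = params.g_K * (V - params.V_K)
    mi3 = m_inf(V) ** 3
    ai3 = gate_steady_state("a", V, params) ** 3
    B = -params.g_Na * mi3 * (V - params.V_Na)
    C = (params.g_L * (V - params.V_L)
         + g_A * ai3 * b * (V - params.V_K)
         + params.g_Na * mi3 * (V - params.V_Na)
         + params.g_syn_E * s_E * (V - params.V_E)
         + params.g_syn_I * s_I * (V - params.V_I))
    return A, B, C


def nullcline_n(V: float, b: float, s_E: float, s_I: float, g_A: float,
                params: NeuronParams) -> np.ndarray:
    """All real n-roots of the V-nullcline at the given voltage (possibly
    empty; n < 0 is allowed by analytic continuation)."""
    A, B, C = _quartic_coeffs(float(V), b, s_E, s_I, g_A, params)
    roots = np.roots([A, 0.0, 0.0, B, C])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    return real


def nullcline_branch(V, b, s_E, s_I, g_A, params: NeuronParams) -> np.ndarray:
    """Upper (physical) branch n(V) of the nullcline, vectorized over V.

    For V > V_K the quartic A n^4 + B n + C has A, B > 0, hence at most two
    real roots; the branch of interest is the larger one.  NaN marks voltages
    where the branch does not exist (the nullcline has receded).
    """
    V = np.atleast_1d(np.asarray(V, float))
    A, B, C = _quartic_coeffs(V, b, s_E, s_I, g_A, params)
    # Newton iteration from above; for n greater than the largest root the
    # quartic and its derivative are positive, so the iteration descends
    # monotonically onto the upper root when it exists.
    n = np.full(V.shape, 3.0)
    for _ in range(100):
        f = A * n ** 4 + B * n + C
        fp = 4.0 * A * n ** 3 + B
        step = f / fp
        n = n - step
        if np.all(np.abs(step) < 1e-12):
            break
    res = A * n ** 4 + B * n + C
    scale = np.abs(A) + np.abs(B) + np.abs(C)
    n = np.where(np.abs(res) < 1e-8 * scale, n, np.nan)
    return n


@dataclass(frozen=True)
class KneePoint:
    """A fold of the V-nullcline: ``smooth`` folds are local extrema of the
    branch n(V) (horizontal tangent); ``pinch`` folds are points where the
    branch terminates because the upper and lower roots coalesce."""
    V: float
    n: float
    side: str          # "left" | "right"
    fold: str          # "smooth" | "pinch"


_V_LO = -79.5
_V_HI = 54.0
_GRID_STEP = 0.05
#: side-specific scan windows: the left fold lives well below the spike
#: peak; the right fold can sit at depolarized voltages
_WINDOWS = {"left": (_V_LO, -20.0), "right": (-75.0, _V_HI)}


def find_knee(b: float, s_E: float, s_I: float, g_A: float,
              params: NeuronParams, side: str = "left",
              v_window: Optional[tuple[float, float]] = None) -> KneePoint:
    """Locate a knee (fold) of the V-nullcline of the reduced model.

    The left knee is the minimum of n over the stable low-V branch: either a
    smooth local minimum of n(V), or -- when the nullcline pinches into
    disconnected pieces -- the fold at which the low-V piece terminates.
    The right knee is the corresponding maximum on the high-V piece.
    """
    if v_window is None:
        v_window = _WINDOWS.get(side, (_V_LO, _V_HI))
    Vg = np.arange(v_window[0], v_window[1], _GRID_STEP)
    ng = nullcline_branch(Vg, b, s_E, s_I, g_A, params)
    finite = np.isfinite(ng)
    if not finite.any():
        raise KneeNotFoundError("nullcline branch absent in the search window")
    # contiguous pieces of the branch
    edges = np.nonzero(np.diff(finite.astype(int)))[0]
    starts = [0] if finite[0] else []
    starts += [e + 1 for e in edges if finite[e + 1]]
    ends = [e for e in edges if finite[e]]
    if finite[-1]:
        ends += [len(Vg) - 1]
    pieces = list(zip(starts, ends))

    def refine_smooth(i0, i1, i, sign):
        f = lambda v: sign * float(
            nullcline_branch(np.array([v]), b, s_E, s_I, g_A, params)[0])
        lo = Vg[max(i - 2, i0)]
        hi = Vg[min(i + 2, i1)]
        r = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                     options={"xatol": 1e-11})
        return KneePoint(V=float(r.x), n=sign * float(r.fun),
                         side=side, fold="smooth")

    def refine_pinch(v_in, v_out):
        # bisect the existence boundary of the branch
        for _ in range(80):
            v_mid = 0.5 * (v_in + v_out)
            if np.isfinite(nullcline_branch(np.array([v_mid]), b, s_E, s_I,
                                            g_A, params)[0]):
                v_in = v_mid
            else:
                v_out = v_mid
        nv = float(nullcline_branch(np.array([v_in]), b, s_E, s_I,
                                    g_A, params)[0])
        return KneePoint(V=float(v_in), n=nv, side=side, fold="pinch")

    if side == "left":
        i0, i1 = pieces[0]
        seg = ng[i0:i1 + 1]
        # first interior local minimum walking up in V
        interior = np.nonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:]))[0]
        if interior.size:
            i = i0 + 1 + interior[0]
            return refine_smooth(i0, i1, i, +1.0)
        if i1 < len(Vg) - 1:   # piece terminates inside the window: pinch fold
            return refine_pinch(Vg[i1], Vg[i1 + 1])
        raise KneeNotFoundError("no left fold in the search window")
    elif side == "right":
        i0, i1 = pieces[-1]
        seg = ng[i0:i1 + 1]
        interior = np.nonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]))[0]
        if interior.size:
            i = i0 + 1 + interior[-1]
            return refine_smooth(i0, i1, i, -1.0)
        if i1 < len(Vg) - 1:
            return refine_pinch(Vg[i1], Vg[i1 + 1])
        raise KneeNotFoundError("no right fold in the search window")
    raise InvalidParameterError(f"side must be 'left' or 'right', got {side!r}")


# --------------------------------------------------------------------------
# reduced-theory context and derived quantities
# --------------------------------------------------------------------------

@dataclass
class ReducedContext:
    """Precomputed ingredients of the reduced-model rate theory."""

    params: NeuronParams
    r_I: float
    sigma_star: float
    P_I: float
    b_grid: np.ndarray          # r_E grid of the b*_av table
    b_values: np.ndarray        # b*_av(r_E)
    tau_0: float                # silent-phase n time constant (ms)
    R: float                    # refractory dead time (ms)
    _N_rk_cache: dict = field(default_factory=dict)

    def b_av(self, r_E: float) -> float:
        return float(np.interp(r_E, self.b_grid, self.b_values))

    def N_rk(self, g_A: float) -> float:
        """Right-knee n-level, treated as a constant per g_A (its dependence
        on s_I and b is weak); evaluated at s_E = 1, s_I = sigma*,
        b = b*_av(0)."""
        key = round(float(g_A), 9)
        if key not in self._N_rk_cache:
            knee = find_knee(self.b_av(0.0), 1.0, self.sigma_star, g_A,
                             self.params, side="right")
            self._N_rk_cache[key] = knee.n
        return self._N_rk_cache[key]


def build_context(params: Optional[NeuronParams] = None,
                  r_I: float = 50.0,
                  r_E_grid=None,
                  R: float = 10.0,
                  tau_0: Optional[float] = None,
                  seed: int = 0,
                  b_duration: float = 100_000.0) -> ReducedContext:
    """Assemble a :class:`ReducedContext` at the reduced-model defaults.

    ``tau_0`` defaults to tau_n at the leak reversal (the n time constant in
    the silent phase, ~41.5 ms).  ``R`` defaults to the 10 ms dead time the
    no-inhibition fit yields; pass a freshly fitted value for self-contained
    pipelines.
    """
    params = params if params is not None else reduced_params()
    if r_E_grid is None:
        r_E_grid = np.arange(0.0, 201.0, 10.0)
    r_E_grid = np.asarray(r_E_grid, float)
    bI = b_star_I(params, r_I=r_I)
    bE0 = b_star_E(0.0, params)
    b_values = np.array([bI + b_star_E(r, params, duration=b_duration,
                                       seed=seed) - bE0
                         for r in r_E_grid])
    return ReducedContext(
        params=params, r_I=r_I,
        sigma_star=sigma_star(params.beta_I, r_I),
        P_I=1000.0 / r_I,
        b_grid=r_E_grid, b_values=b_values,
        tau_0=float(tau_n(params.V_L)) if tau_0 is None else float(tau_0),
        R=float(R))


def N_lk(s_I: float, r_E: float, g_A: float, ctx: ReducedContext) -> float:
    """Left-knee n-level of the s_E = 1 nullcline with b = b*_av(r_E)."""
    return find_knee(ctx.b_av(r_E), 1.0, s_I, g_A, ctx.params, side="left").n


def critical_gA(ctx: ReducedContext,
                bracket: tuple[float, float] = (1.0, 80.0)) -> float:
    """g_A^0: the root of g_A -> N_lk(sigma*, 0, g_A), located by bisection.

    Above g_A^0 the left knee at the inhibitory-gate floor sits below n = 0
    and the neuron cannot respond to arbitrarily low input rates.
    """
    f = lambda g: N_lk(ctx.sigma_star, 0.0, g, ctx)
    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise NoTransitionError("N_lk(sigma*, 0, g_A) does not change sign "
                                f"on [{lo}, {hi}]")
    return float(optimize.brentq(f, lo, hi, xtol=1e-3))


def gamma_curve(g_A: float, ctx: ReducedContext,
                r_E_max: float = 200.0) -> float:
    """Minimum responsive input rate Gamma(g_A) (events/s): the root in r_E
    of N_lk(sigma*, r_E, g_A).  Returns 0 for g_A <= g_A^0 (the neuron is
    responsive at all rates)."""
    f = lambda r: N_lk(ctx.sigma_star, r, g_A, ctx)
    if f(0.0) >= 0.0:
        return 0.0
    if f(r_E_max) < 0.0:
        raise NoTransitionError(f"knee still below zero at r_E = {r_E_max}")
    return float(optimize.brentq(f, 0.0, r_E_max, xtol=1e-6))


def theta_map(n_av: float, r_E: float, g_A: float,
              ctx: ReducedContext) -> tuple[float, bool]:
    """Theta(n_av): the s_I level whose left knee equals n_av.

    N_lk decreases in s_I.  If even s_I = 1 leaves the knee above n_av the
    threshold clamps to 1 (inhibition never blocks); if no s_I > 0 brings
    the knee up to n_av it clamps to the floor.  Returns (theta, clamped).
    """
    s_lo = 1e-9
    f = lambda s: N_lk(s, r_E, g_A, ctx) - n_av
    f_hi = f(1.0)
    if f_hi >= 0.0:
        return 1.0, True
    f_lo = f(s_lo)
    if f_lo <= 0.0:
        return s_lo, True
    return float(optimize.brentq(f, s_lo, 1.0, xtol=1e-8)), False


def n_map(theta: float, r_E: float, g_A: float, ctx: ReducedContext) -> float:
    """N(theta): mean n at spike-evoking events, N_rk exp(-1000 phi_n /
    (tau_0 r_out)), with r_out the dead-time rate thinned by rho(theta)."""
    rho = rho_fraction(theta, ctx.P_I, ctx.params.beta_I)
    r_out = deadtime_rate(r_E, ctx.R, rho)
    if r_out <= 0.0:
        return 0.0
    n_av = ctx.N_rk(g_A) * float(
        np.exp(-1000.0 * ctx.params.phi_n / (ctx.tau_0 * r_out)))
    # deep in the subtractive regime the reference right knee can sit below
    # n = 0; clip so the composed map remains a self-map of [0, 1]
    return max(n_av, 0.0)


_S_GRID = np.geomspace(1e-6, 1.0, 48)


def _theta_interp(r_E: float, g_A: float, ctx: ReducedContext):
    """Cached monotone inverse of s_I -> N_lk(s_I, r_E, g_A), tabulated on a
    log-spaced s_I grid.  Used inside the fixed-point iteration where the
    knee map is evaluated many times."""
    key = ("theta", round(float(r_E), 9), round(float(g_A), 9))
    cache = ctx._N_rk_cache
    if key not in cache:
        nk = np.array([N_lk(s, r_E, g_A, ctx) for s in _S_GRID])
        cache[key] = nk
    nk = cache[key]

    def theta(n_av: float) -> float:
        if n_av <= nk[-1]:       # even s_I = 1 leaves the knee above n_av
            return 1.0
        if n_av >= nk[0]:        # no s_I brings the knee up to n_av
            return float(_S_GRID[0])
        # nk decreases along _S_GRID; interpolate log(s) against the knee
        return float(np.exp(np.interp(-n_av, -nk, np.log(_S_GRID))))

    return theta


def firing_threshold(r_E: float, g_A: float,
                     ctx: ReducedContext) -> tuple[float, float]:
    """Fixed point (theta*, n_av*) of n -> N(Theta(n)) on [0, 1], by
    bisection.  The composed map is a continuous self-map of [0, 1], so a
    fixed point always exists."""
    theta_of = _theta_interp(r_E, g_A, ctx)
    g = lambda n: n - n_map(theta_of(n), r_E, g_A, ctx)
    lo, hi = 0.0, 1.0
    g_lo = g(lo)
    if g_lo >= 0.0:      # n = 0 already a fixed point (non-responsive regime)
        n_star = 0.0
    else:
        for _ in range(52):
            mid = 0.5 * (lo + hi)
            if g(mid) < 0.0:
                lo = mid
            else:
                hi = mid
        n_star = 0.5 * (lo + hi)
    return theta_of(n_star), n_star


def onset_slope(g_A: float, ctx: ReducedContext) -> float:
    """Slope of the inhibited rate curve at firing onset (r_E = 0):
    1 + ln(theta_0) / (P_I beta_I) with theta_0 = Theta(0), clipped at 0."""
    theta_0, _ = theta_map(0.0, 0.0, g_A, ctx)
    return rho_fraction(theta_0, ctx.P_I, ctx.params.beta_I)


def theory_rate_curve(r_E_grid, g_A: float, ctx: ReducedContext) -> np.ndarray:
    """Approximated inhibited output rates over the grid: the dead-time
    Poisson rate thinned by the fixed-point firing threshold."""
    out = np.empty(len(r_E_grid))
    for i, r_E in enumerate(np.asarray(r_E_grid, float)):
        theta, _ = firing_threshold(r_E, g_A, ctx)
        rho = rho_fraction(theta, ctx.P_I, ctx.params.beta_I)
        out[i] = deadtime_rate(r_E, ctx.R, rho)
    return out
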