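# Methods

## Model

The point neuron is a Hodgkin–Huxley-type membrane (units mV, ms, mS/cm²,
µA/cm², µF/cm²) with four currents: leak, delayed-rectifier potassium
(activation n, fourth power), A-type potassium (fast activation a, cubed;
slow inactivation b), and sodium (instantaneous activation m = m_∞(V),
inactivation slaved to potassium activation, h = 1 − n). Steady-state
gating curves are logistic sigmoids; we store the slope *magnitude* and the
physiological direction explicitly — n and a are activation gates
(increasing in V, half-points −32 and −50 mV, slopes 8 and 20 mV), b is an
inactivation gate (decreasing, half-point −70 mV, slope 6 mV). This
explicit convention avoids the sign ambiguity that arises when a single
signed slope carries the direction, and it is corroborated quantitatively:
the reduced theory built on it yields a critical conductance g_A⁰ = 29.0
mS/cm², and the full model's dead zone and switch location come out where
the theory predicts.

Constants: C = 1 µF/cm², g_L = 1, g_K = 45, g_Na = 37 mS/cm²,
V_L = −70, V_K = −80, V_Na = 55 mV, φ_n = 0.75,
τ_n(V) = 1 + 100/(1 + e^{(V+80)/26}) ms, τ_a = 2 ms (sweepable as τ_A),
τ_b = 150 ms. Synapses: reversal potentials 0 / −85 mV, decay rates
β_E = 0.2, β_I = 0.18 ms⁻¹; conductance gates reset to 1 at each event and
decay exponentially. The g_A conductance is the principal swept parameter.

The cable variant attaches nine passive compartments (leak 0.1 mS/cm²,
axial coupling g_Ax = 10 mS/cm², same capacitance) to the soma, which keeps
all voltage-gated currents and (by default) the inhibitory synapse;
excitation targets dendritic compartment `cpt_in` ∈ 1..9 (proximal to
distal).

Two model variants share one parameter record: the *full* model integrates
a dynamically; the *reduced* model used by the analysis slaves it to
voltage (a = a_∞(V)). The reduced model needs much stronger excitation
(g_synE ≈ 3 rather than ≈ 0.5) to fire, because instantaneous A-current
activation otherwise vetoes spike initiation.

## Synthetic inputs

The generator reproduces the study's input statistics exactly: excitatory
event times are a homogeneous Poisson process of rate r_E; inhibitory
events are periodic with rate r_I (period P_I = 1000/r_I ms), with Poisson
inhibition available as a control. The phase of the periodic train is not
constrained by the model definition; the first inhibitory event defaults to
t = 0 and is exposed as a parameter. One top-level seed spawns independent
sub-streams per train, so switching inhibition on/off or changing its mode
never perturbs the excitatory realization. What the generator does *not*
emulate: rate modulation in time, synaptic depression/facilitation,
conductance rise times, correlations between inputs. Conclusions drawn from
passing tests therefore concern stationary, uncorrelated drive only.

## Numerics

Gate resets are discontinuities, so gates are never part of the ODE state:
integration proceeds span-by-span between consecutive event times (every
event is a mesh point) with gates evaluated in closed form at the
Runge–Kutta stage times. Within spans a compiled classical RK4 with fixed
step dt = 0.005 ms is used. The fastest membrane time scale — capacitance
over peak total conductance — is ≈ 0.02 ms, an order of magnitude above the
step; halving dt changes spike counts on fixed trains by zero, and the
fixed-step integrator agrees spike-for-spike with an adaptive implicit
Radau reference (`method="radau"`, tolerances 1e-8) on fixed trains. Spikes
are upward crossings of −20 mV with a 2 ms lockout, the crossing time
interpolated linearly; any threshold well inside (−30, 0) gives identical
counts because action potentials overshoot toward V_Na.

Initial conditions are the input-free resting equilibrium, found by
bracketing the lowest-voltage zero of the total membrane current (the model
also has threshold and depolarized equilibria). Output rates count spikes
over [transient, duration] with a 500 ms transient; the default 20 s
window puts ≈ 100 spikes behind a 5 spikes/s estimate (≈ 10% sampling
error). Tests and sweeps scale this window (6–15 s) where many parameter
combinations are scanned; the acceptance script uses the full 20 s.

## Rate-curve analysis

Rate curves pair, per r_E grid point (default 5–100 events/s in steps
of 5), an uninhibited (g_synI = 0) and an inhibited run on the same
excitatory realization. The threshold-linear summary y = [m(x − x0)]₊ of
inhibited (y) against uninhibited (x) rates is fitted by Nelder–Mead
simplex on the summed squared residuals, restricted to points with
y < 5 spikes/s. When fewer than three points fall below the cap (strongly
divisive responses cross it within the first grid steps), the three
lowest-rate points are used instead, keeping the fit anchored to the
low-rate portion. Inhibition is labelled *subtractive* when the x-intercept
exceeds the (≈ 0) uninhibited reference by more than 2 spikes/s, and
*divisive* otherwise; since right-shifted responses frequently also show
slope reduction ("mixed" responses), the slope is always reported next to
the label. Boundary maps scan g_A ascending (step 1 by default, step 2 in
the sweep tests) and report the first subtractive value per g_synE.

## Reduced theory

Fast–slow structure: V is fast; n and b are slow. For the left-knee
criterion, b is replaced by an input-rate-dependent constant constructed in
three stages of increasing reduction, each validated against the previous
one (agreement within 0.05 across r_E ∈ [0, 100]): the full-model time
average; the passive average (all voltage-gated conductances removed,
excitation and inhibition applied separately,
b̂_av(r_E) = b̂_I + b̂_E(r_E) − b̂_E(0)); and the quasi-steady average
b*_av(r_E), where the scalar b-equation is driven by the conductance-
weighted voltages V_E(s_E(t)) and V_I(s_I(t)). b*_I averages one period of
the periodic limit cycle after a 10 τ_b transient (deterministic);
b*_E(r_E) averages a long seeded scalar simulation (100 s by default) —
because b is linear with constant time constant, its long-run average
equals the stationary mean of b_∞ along the drive, which for Poisson input
has a closed renewal form used as an independent check in the tests.

The V-nullcline of the reduced model is quartic in n with no quadratic or
cubic term; for V > V_K its leading and linear coefficients are positive,
so it has at most two real roots and the physical branch is the larger one
(computed by a vectorized, residual-checked Newton iteration; `nullcline_n`
returns all real roots via the companion matrix for verification). The
*left knee* is the minimum of n over the stable low-V branch. Two fold
geometries occur: a smooth local minimum of n(V) (horizontal tangent,
located by bounded scalar minimization after a 0.05 mV grid scan), and — at
strong A-current — a *pinch*, where the branch terminates because upper and
lower roots coalesce; there the knee is the existence boundary, located by
bisection to ~1e-12 in V. Knee values below n = 0 are meaningful
(analytic continuation) and signal loss of excitability. g_A⁰ is the root
of N_lk(σ*, 0, g_A) by Brent bisection (tolerance 1e-3); Γ(g_A) the root in
r_E, with b*_av interpolated linearly on its table (finer tables near the
onset sharpen Γ by a few percent).

The rate approximation treats output spiking as a Poisson process thinned
by a dead time R and by the fraction ρ(θ) = 1 + ln θ/(P_I β_I) of the
inhibitory cycle below the firing threshold θ (natural logarithm — forced
by the derivation from the exponential gate decay). R is fitted to
reduced-model no-inhibition curves (R ≈ 9.5 ms, weakly g_A-dependent); the
theory context defaults to R = 10 ms. θ is the fixed point of
θ = Θ(n_av) (the s_I level whose left knee equals n_av; monotone, inverted
from a cached 48-point log-spaced table inside the fixed-point loop) and
n_av = N(θ) = N_rk e^{−1000 φ_n/(τ_0 r_out)}. Here N_rk is the right-knee
level, treated as a constant per g_A (its dependence on s_I and b is weak)
and computed at s_E = 1, s_I = σ*, b = b*_av(0); τ_0 is the silent-phase n
time constant, never fixed by the model definition, and defaults to
τ_n(V_L) ≈ 41.5 ms (exposed as a parameter and recorded in outputs). The
fixed point is found by 52 bisection steps on [0, 1]; it exists because the
composed map is a continuous self-map of the interval. In the deep
subtractive regime N_rk can itself fall below zero at the reference
conditions; the fixed point then sits at n_av = 0 and the threshold
reduces to θ = Θ(0), which reproduces the dead-zone edge Γ.

## Design choices that were genuinely open

* **Gate value before the first event** is 0 (the model starts from rest
  with no synaptic history).
* **Simultaneous events** of both kinds are both applied; they reset
  independent gates, so order is irrelevant.
* **Θ's domain**: the inverse knee map is solved on s_I ∈ (0, 1] and
  clamped (with a flag) when no inhibitory level attains the requested knee
  height, rather than restricted a priori to [σ*, 1].
* **Dead time for the rate theory** is fitted on the *reduced* model at its
  own drive (g_synE = 3): that is the model the approximation describes.
  The full model at g_synE = 0.5 recovers excitability much more slowly
  (effective dead times of tens of ms), which is visible in its saturating
  rate curves.
* **R fit conditions**: g_A = 25 (mid-range); the fit varies by < 1 ms
  across g_A ∈ {15, 25, 35}.

## Known limitations

* The threshold-linear classification is sampling-noise-limited near the
  boundary; labels are stable across seeds only a few mS/cm² away from it.
* The theory's rate curves systematically overestimate simulated inhibited
  rates (the thinning argument ignores partial recovery within the
  inhibitory cycle); they are quantitative for onset location and slope,
  qualitative for absolute rates.
* The cable model is a nine-compartment caricature of a dendrite: no
  tapering, no active dendritic conductances, a single lumped axial
  conductance.
* Fixed-step integration is tuned for the standard parameter ranges; for
  τ_A well below 0.1 ms the step is reduced proportionally by the caller
  (the τ_A sweep tests do this).
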