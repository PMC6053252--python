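"""Input/output rate curves, threshold-linear fits, and the classification
of inhibition as divisive or subtractive.

The classifier follows the convention that a response is *subtractive*
whenever the threshold-linear relation between inhibited and uninhibited
output rates is right-shifted by more than 2 spikes/s, and *divisive*
otherwise.  Because right-shifted responses often also show slope reduction
("mixed" responses), the fit's slope is always reported alongside the shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .params import CableParams, InvalidParameterError, NeuronParams
from .simulate import output_rate

#: Only points whose inhibited rate is below this (spikes/s) enter the fit.
FIT_WINDOW_CAP = 5.0
#: Right-shift (spikes/s) beyond which inhibition counts as subtractive.
SUBTRACTIVE_SHIFT = 2.0


class InsufficientDataError(ValueError):
    """Fewer than three points fall inside the fitting window."""


@dataclass
class RateCurve:
    """Paired output rates over a grid of excitatory input rates."""

    r_E: np.ndarray
    r_out_noinh: np.ndarray
    r_out_inh: np.ndarray
    params: NeuronParams
    seed: int
    r_I: float = 50.0
    duration: float = 20000.0
    inhib_mode: str = "periodic"

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"r_E": self.r_E,
                      "r_out_noinh": self.r_out_noinh,
                      "r_out_inh": self.r_out_inh}).to_csv(path, index=False)


@dataclass
class ThresholdLinearFit:
    """Least-squares fit of y = [m (x - x0)]_+ inside the fitting window."""

    m: float
    x0: float
    residual: float
    n_points: int
    degenerate: bool = False
    fit_window_cap: float = FIT_WINDOW_CAP


@dataclass
class InhibitionClass:
    label: str                     # "divisive" | "subtractive"
    x0_shift: float                # spikes/s
    m: float                       # slope of the inhibited fit
    degenerate: bool = False
    criterion_threshold: float = SUBTRACTIVE_SHIFT

    def to_json(self, path: str | Path, extra: Optional[dict] = None) -> None:
        rec = {"label": self.label, "x0_shift": self.x0_shift, "m": self.m,
               "degenerate": self.degenerate,
               "criterion_threshold": self.criterion_threshold}
        if extra:
            rec.update(extra)
        Path(path).write_text(json.dumps(rec, indent=2) + "\n")


def compute_rate_curve(params: NeuronParams, r_E_grid,
                       r_I: float = 50.0,
                       duration: float = 20000.0,
                       transient: float = 500.0,
                       seed: int = 0,
                       inhib_mode: str = "periodic",
                       cable: Optional[CableParams] = None) -> RateCurve:
    """Output rates with inhibition off (g_synI = 0) and on at every grid
    point, using the same excitatory realization for both branches."""
    r_E_grid = np.asarray(r_E_grid, float)
    if r_E_grid.size == 0:
        raise InvalidParameterError("r_E grid must be nonempty")
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(len(r_E_grid))]
    noinh = np.empty_like(r_E_grid)
    inh = np.empty_like(r_E_grid)
    for i, (rE, s) in enumerate(zip(r_E_grid, seeds)):
        noinh[i] = output_rate(params, rE, with_inhibition=False, r_I=r_I,
                               duration=duration, transient=transient,
                               seed=s, inhib_mode=inhib_mode, cable=cable)
        inh[i] = output_rate(params, rE, with_inhibition=True, r_I=r_I,
                             duration=duration, transient=transient,
                             seed=s, inhib_mode=inhib_mode, cable=cable)
    return RateCurve(r_E=r_E_grid, r_out_noinh=noinh, r_out_inh=inh,
                     params=params, seed=seed, r_I=r_I, duration=duration,
                     inhib_mode=inhib_mode)


def _relu_line(x, m, x0):
    return np.maximum(m * (x - x0), 0.0)


def fit_threshold_linear(x, y, cap: float = FIT_WINDOW_CAP) -> ThresholdLinearFit:
    """Fit y = [m (x - x0)]_+ to the points with y < cap by derivative-free
    simplex minimization (Nelder-Mead) of the sum of squared residuals.

    Raises :class:`InsufficientDataError` with fewer than 3 in-window points;
    returns a degenerate (flagged) fit when every in-window response is zero,
    in which case x0 is unbounded above the data range.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 points, got {x.size}")
    mask = y < cap
    if mask.sum() < 3:
        # strongly divisive responses can cross the cap within the first few
        # grid points; fall back to the three lowest-rate points so the
        # low-rate portion is still what gets fitted
        mask = np.zeros_like(mask)
        mask[np.argsort(y, kind="stable")[:3]] = True
    xs, ys = x[mask], y[mask]
    if np.all(ys == 0.0):
        return ThresholdLinearFit(m=0.0, x0=float(xs.max()), residual=0.0,
                                  n_points=int(xs.size), degenerate=True)

    def sse(p):
        m, x0 = p
        return float(np.sum((ys - _relu_line(xs, m, x0)) ** 2))

    # initial guess from a plain line through the firing points
    pos = ys > 0
    if pos.sum() >= 2:
        m0, c0 = np.polyfit(xs[pos], ys[pos], 1)
        m0 = max(m0, 1e-3)
        x0_0 = -c0 / m0
    else:
        m0, x0_0 = 1.0, 0.0
    best = None
    for guess in ([m0, x0_0], [1.0, 0.0], [0.5, float(xs.min())]):
        res = optimize.minimize(sse, guess, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    m, x0 = best.x
    if m < 0:  # negative slopes are unphysical here; refit clamped
        m = 0.0
    return ThresholdLinearFit(m=float(m), x0=float(x0),
                              residual=float(best.fun), n_points=int(xs.size))


def classify_inhibition(fit: ThresholdLinearFit,
                        reference_x0: float = 0.0,
                        threshold: float = SUBTRACTIVE_SHIFT) -> InhibitionClass:
    """Subtractive iff the x-intercept shift strictly exceeds ``threshold``.

    A degenerate fit (no firing anywhere in the window under inhibition) is
    classified subtractive and flagged.
    """
    if fit.degenerate:
        return InhibitionClass(label="subtractive", x0_shift=float("inf"),
                               m=fit.m, degenerate=True, criterion_threshold=threshold)
    shift = fit.x0 - reference_x0
    label = "subtractive" if shift > threshold else "divisive"
    return InhibitionClass(label=label, x0_shift=float(shift), m=fit.m,
                           criterion_threshold=threshold)


def classify_curve(curve: RateCurve) -> InhibitionClass:
    """Fit inhibited vs. uninhibited rates and classify in one step."""
    fit = fit_threshold_linear(curve.r_out_noinh, curve.r_out_inh)
    return classify_inhibition(fit)


def classify_parameter_set(params: NeuronParams, r_E_grid=None,
                           **curve_kwargs) -> tuple[InhibitionClass, RateCurve]:
    if r_E_grid is None:
        r_E_grid = default_r_E_grid()
    curve = compute_rate_curve(params, r_E_grid, **curve_kwargs)
    return classify_curve(curve), curve


def default_r_E_grid() -> np.ndarray:
    """Excitatory rate grid, 5-100 events/s in steps of 5."""
    return np.arange(5.0, 101.0, 5.0)


def map_boundary(g_syn_E_values, g_A_values, params: NeuronParams,
                 r_E_grid=None,
                 r_I: float = 50.0,
                 duration: float = 20000.0,
                 seed: int = 0,
                 inhib_mode: str = "periodic",
                 cable_factory=None) -> pd.DataFrame:
    """For each excitatory strength, scan g_A ascending and return the first
    (smallest) value at which inhibition is subtractive.

    ``cable_factory``: optional callable ``g_syn_E -> CableParams`` selecting
    the cable configuration (e.g. the excitatory input site) per column; None
    runs the point model.  Scanning stops at the first subtractive g_A.
    """
    g_syn_E_values = np.asarray(g_syn_E_values, float)
    g_A_values = np.sort(np.asarray(g_A_values, float))
    if r_E_grid is None:
        r_E_grid = default_r_E_grid()
    rows = []
    for gse in g_syn_E_values:
        boundary = np.nan
        for gA in g_A_values:
            p = params.replace(g_syn_E=float(gse), g_A=float(gA))
            cable = cable_factory(gse) if cable_factory is not None else None
            cls, _ = classify_parameter_set(
                p, r_E_grid, r_I=r_I, duration=duration, seed=seed,
                inhib_mode=inhib_mode, cable=cable)
            if cls.label == "subtractive":
                boundary = gA
                break
        rows.append({"g_syn_E": float(gse), "g_A_boundary": boundary})
    return pd.DataFrame(rows)
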