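"""Experiment orchestration: named, configurable computations that
reproduce the package's headline analyses and write CSV/JSON results.

Every experiment is deterministic given its seed; every output record embeds
the fully resolved parameter set so results are auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, rates, theory
from .params import CableParams, NeuronParams, reduced_params
from .simulate import output_rate

log = logging.getLogger("gainswitch")

EXPERIMENTS = ("io_curve", "classify", "boundary", "tau_sweep", "cable",
               "theory_gA0", "theory_gamma", "theory_threshold",
               "theory_slope", "fit_R")

#: Recognized configuration keys (beyond neuron-parameter overrides under
#: the "params." namespace).
_CONFIG_KEYS = {
    "experiment", "seed", "duration", "out", "scale",
    "r_I", "r_E_grid", "g_A", "g_A_grid", "g_syn_E_grid", "tau_A_values",
    "cpt_in", "cpt_inhib", "inhib_mode", "R",
}


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass
class ExperimentConfig:
    experiment: str
    seed: int = 0
    duration: float = 20000.0
    out: str = "results"
    scale: float = 1.0          # fractional duration multiplier
    options: dict = field(default_factory=dict)
    param_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        exp = d.pop("experiment", None)
        if exp not in EXPERIMENTS:
            raise ConfigError(f"experiment must be one of {EXPERIMENTS}, got {exp!r}")
        overrides = {}
        options = {}
        bad = []
        known_params = {f.name for f in dataclasses.fields(NeuronParams)}
        core = {}
        for k, v in d.items():
            if k.startswith("params."):
                name = k[len("params."):]
                if name not in known_params:
                    bad.append(k)
                else:
                    overrides[name] = v
            elif k in ("seed", "duration", "out", "scale"):
                core[k] = v
            elif k in _CONFIG_KEYS:
                options[k] = v
            else:
                bad.append(k)
        if bad:
            raise ConfigError(f"unknown configuration keys: {sorted(bad)}")
        return cls(experiment=exp, options=options,
                   param_overrides=overrides, **core)


def _base_params(cfg: ExperimentConfig) -> NeuronParams:
    if cfg.experiment.startswith("theory") or cfg.experiment == "fit_R":
        base = reduced_params()
    else:
        base = NeuronParams()
    return base.replace(**cfg.param_overrides)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute one experiment; returns the summary record (also written,
    with CSV side files, under ``cfg.out``)."""
    t_start = time.time()
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _base_params(cfg)
    duration = cfg.duration * cfg.scale
    opts = cfg.options
    r_I = float(opts.get("r_I", 50.0))
    seed = cfg.seed
    summary: dict[str, Any] = {
        "experiment": cfg.experiment, "seed": seed, "duration_ms": duration,
        "r_I": r_I, "params": params.to_dict(), "version": __version__,
    }

    if cfg.experiment == "io_curve":
        grid = np.asarray(opts.get("r_E_grid", rates.default_r_E_grid()), float)
        curve = rates.compute_rate_curve(params, grid, r_I=r_I,
                                         duration=duration, seed=seed,
                                         inhib_mode=opts.get("inhib_mode", "periodic"))
        curve.to_csv(outdir / "io_curve.csv")
        summary["r_out_noinh_max"] = float(curve.r_out_noinh.max())
        summary["r_out_inh_max"] = float(curve.r_out_inh.max())

    elif cfg.experiment == "classify":
        grid = np.asarray(opts.get("r_E_grid", rates.default_r_E_grid()), float)
        cls, curve = rates.classify_parameter_set(
            params, grid, r_I=r_I, duration=duration, seed=seed,
            inhib_mode=opts.get("inhib_mode", "periodic"))
        curve.to_csv(outdir / "classify_curve.csv")
        summary.update(label=cls.label, x0_shift=cls.x0_shift, m=cls.m)

    elif cfg.experiment in ("boundary", "tau_sweep", "cable"):
        gse = np.asarray(opts.get("g_syn_E_grid", [0.4, 0.5, 0.7]), float)
        gAs = np.asarray(opts.get("g_A_grid", np.arange(0.0, 61.0, 1.0)), float)
        frames = []
        if cfg.experiment == "tau_sweep":
            sweep_vals = opts.get("tau_A_values", [0.5, 1.0, 2.0])
            for tau in sweep_vals:
                df = rates.map_boundary(gse, gAs, params.replace(tau_a=float(tau)),
                                        r_I=r_I, duration=duration, seed=seed)
                df["tau_A"] = tau
                frames.append(df)
        elif cfg.experiment == "cable":
            sites = opts.get("cpt_in", [2, 4, 6])
            cpt_inhib = int(opts.get("cpt_inhib", 0))
            for site in np.atleast_1d(sites):
                cable = CableParams(cpt_in=int(site), cpt_inhib=cpt_inhib)
                df = rates.map_boundary(gse, gAs, params, r_I=r_I,
                                        duration=duration, seed=seed,
                                        cable_factory=lambda _g, c=cable: c)
                df["cpt_in"] = int(site)
                frames.append(df)
        else:
            frames.append(rates.map_boundary(gse, gAs, params, r_I=r_I,
                                             duration=duration, seed=seed))
        out = pd.concat(frames, ignore_index=True)
        out.to_csv(outdir / f"{cfg.experiment}_boundary.csv", index=False)
        summary["boundary"] = out.to_dict(orient="records")

    elif cfg.experiment == "theory_gA0":
        ctx = theory.build_context(params, r_I=r_I, seed=seed)
        gA0 = theory.critical_gA(ctx)
        summary.update(g_A0=gA0, sigma_star=ctx.sigma_star,
                       b_av0=ctx.b_av(0.0), tau_0=ctx.tau_0)

    elif cfg.experiment == "theory_gamma":
        ctx = theory.build_context(params, r_I=r_I, seed=seed)
        gA0 = theory.critical_gA(ctx)
        gAs = np.asarray(opts.get("g_A_grid", np.arange(29.0, 46.0, 1.0)), float)
        recs = [{"g_A": g, "Gamma": theory.gamma_curve(g, ctx)}
                for g in gAs if g > gA0]
        pd.DataFrame(recs).to_csv(outdir / "gamma.csv", index=False)
        summary.update(g_A0=gA0, gamma=recs)

    elif cfg.experiment == "theory_threshold":
        g_A = float(opts.get("g_A", 25.0))
        ctx = theory.build_context(params, r_I=r_I, seed=seed,
                                   R=float(opts.get("R", 10.0)))
        grid = np.asarray(opts.get("r_E_grid", np.arange(10.0, 151.0, 10.0)), float)
        rows = []
        for rE in grid:
            th, nav = theory.firing_threshold(rE, g_A, ctx)
            rho = theory.rho_fraction(th, ctx.P_I, params.beta_I)
            rows.append({"r_E": rE, "theta": th, "n_av": nav,
                         "r_out_theory": theory.deadtime_rate(rE, ctx.R, rho)})
        pd.DataFrame(rows).to_csv(outdir / "threshold.csv", index=False)
        summary.update(g_A=g_A, threshold=rows)

    elif cfg.experiment == "theory_slope":
        ctx = theory.build_context(params, r_I=r_I, seed=seed)
        gAs = np.asarray(opts.get("g_A_grid", np.arange(0.0, 31.0, 2.5)), float)
        rows = [{"g_A": g, "onset_slope": theory.onset_slope(g, ctx)}
                for g in gAs]
        pd.DataFrame(rows).to_csv(outdir / "onset_slope.csv", index=False)
        summary["onset_slope"] = rows

    elif cfg.experiment == "fit_R":
        grid = np.asarray(opts.get("r_E_grid", np.arange(10.0, 151.0, 10.0)), float)
        noinh = [output_rate(params, rE, with_inhibition=False, r_I=r_I,
                             duration=duration, seed=seed + i)
                 for i, rE in enumerate(grid)]
        R = theory.fit_refractory_R(grid, noinh)
        pd.DataFrame({"r_E": grid, "r_out": noinh}).to_csv(
            outdir / "fit_R_curve.csv", index=False)
        summary["R_ms"] = R

    summary["wall_time_s"] = round(time.time() - t_start, 2)
    (outdir / f"{cfg.experiment}_summary.json").write_text(
        json.dumps(summary, indent=2, default=_jsonable) + "\n")
    log.info("%s finished in %.1f s", cfg.experiment, summary["wall_time_s"])
    return summary


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
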