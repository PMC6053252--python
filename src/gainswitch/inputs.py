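"""Synaptic event trains and reset-and-decay conductance gating.

Excitatory events arrive as a homogeneous Poisson process with rate ``r_E``;
inhibitory events are periodic with rate ``r_I`` (Poisson inhibition is also
available as a control).  Each event resets its gating variable to 1, after
which the gate decays exponentially, ``s' = -beta s``, until the next event.
Because the reset is a discontinuity, gates are represented by the explicit
event list and evaluated in closed form between events rather than being
carried in the ODE state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .params import InvalidParameterError

Kind = Literal["excitatory", "inhibitory"]
Mode = Literal["poisson", "periodic"]


@dataclass(frozen=True)
class EventTrain:
    """A sorted train of synaptic event times (ms) on [0, duration]."""

    times: np.ndarray
    kind: Kind
    rate: float          # nominal rate, events/s
    duration: float      # ms
    mode: Mode
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise InvalidParameterError("event times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise InvalidParameterError("event times must lie in [0, duration]")

    def __len__(self) -> int:
        return len(self.times)

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ms": self.times, "kind": self.kind}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, rate: float = float("nan"),
                 mode: Mode = "poisson") -> "EventTrain":
        df = pd.read_csv(path)
        kinds = df["kind"].unique()
        if len(kinds) > 1:
            raise InvalidParameterError("CSV mixes event kinds; one train per file")
        times = df["time_ms"].to_numpy(dtype=float)
        duration = float(times[-1]) if times.size else 0.0
        kind = str(kinds[0]) if len(kinds) else "excitatory"
        return cls(times=times, kind=kind, rate=rate, duration=duration, mode=mode)


def generate_poisson_train(rate: float, duration: float,
                           seed: int | np.random.Generator = 0,
                           kind: Kind = "excitatory") -> EventTrain:
    """Homogeneous Poisson event train; inter-event intervals are exponential
    with mean ``1000 / rate`` ms.  Reproducible for a given seed."""
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate == 0:
        times = np.empty(0)
    else:
        mean_isi = 1000.0 / rate
        # draw in blocks until past the horizon
        n_guess = max(16, int(duration / mean_isi * 1.5) + 10)
        isis = rng.exponential(mean_isi, size=n_guess)
        t = np.cumsum(isis)
        while t.size == 0 or t[-1] < duration:
            more = rng.exponential(mean_isi, size=n_guess)
            t = np.concatenate([t, t[-1] + np.cumsum(more)]) if t.size else np.cumsum(more)
        times = t[t <= duration]
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    return EventTrain(times=times, kind=kind, rate=rate, duration=duration,
                      mode="poisson", seed=seed_val)


def generate_periodic_train(rate: float, duration: float, first_event: float = 0.0,
                            kind: Kind = "inhibitory") -> EventTrain:
    """Periodic events at ``first_event + k * 1000/rate`` for k = 0, 1, ...

    The phase of the train relative to simulation start is a free choice of
    the experiment; the default puts the first event at t = 0.
    """
    if rate <= 0:
        raise InvalidParameterError("rate must be > 0 for a periodic train")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    period = 1000.0 / rate
    if first_event > duration:
        times = np.empty(0)
    else:
        n = int(np.floor((duration - first_event) / period + 1e-12)) + 1
        times = first_event + period * np.arange(n)
        times = times[times <= duration]
    return EventTrain(times=times, kind=kind, rate=rate, duration=duration,
                      mode="periodic")


def gate_value(train: EventTrain, beta: float, t):
    """Closed-form gate ``exp(-beta (t - t_last))`` with ``t_last`` the most
    recent event at or before ``t``; 0 before any event has occurred.

    Accepts scalar or array ``t``.
    """
    if beta <= 0:
        raise InvalidParameterError("beta must be > 0")
    t_arr = np.asarray(t, dtype=float)
    idx = np.searchsorted(train.times, t_arr, side="right") - 1
    out = np.zeros_like(t_arr)
    has = idx >= 0
    if train.times.size:
        out[has] = np.exp(-beta * (t_arr[has] - train.times[idx[has]]))
    return out if t_arr.ndim else float(out)


def input_pair(r_E: float, r_I: float, duration: float, seed: int,
               inhib_mode: Mode = "periodic",
               first_inhib: float = 0.0) -> tuple[EventTrain, EventTrain]:
    """Matched excitatory/inhibitory trains from independent sub-streams of a
    single top-level seed, so that turning inhibition on or off, or switching
    its mode, never perturbs the excitatory realization."""
    ss = np.random.SeedSequence(seed)
    child_e, child_i = ss.spawn(2)
    exc = generate_poisson_train(r_E, duration,
                                 seed=np.random.default_rng(child_e))
    if inhib_mode == "periodic":
        inh = generate_periodic_train(r_I, duration, first_event=first_inhib)
    else:
        inh = generate_poisson_train(r_I, duration,
                                     seed=np.random.default_rng(child_i),
                                     kind="inhibitory")
    return exc, inh
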