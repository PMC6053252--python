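"""Parameter records for the point-neuron and soma-dendrite cable models.

Units follow the usual membrane-patch convention throughout the package:
mV, ms, mS/cm^2, uA/cm^2 and uF/cm^2.  Synaptic event rates are exposed in
events/s and converted internally (a periodic train of rate ``r`` has period
``1000 / r`` ms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


class InvalidParameterError(ValueError):
    """Raised when a parameter record violates its physical constraints."""


@dataclass(frozen=True)
class NeuronParams:
    """Membrane, channel-gating and synaptic constants of the point neuron.

    The same record covers the full model (dynamic A-current activation with
    time constant ``tau_a``) and the reduced model in which activation is
    instantaneous, ``a = a_inf(V)`` (set ``instantaneous_a=True``).

    Steady-state gating curves are logistic sigmoids
    ``x_inf(V) = 1 / (1 + exp(-dir * (V - theta_x) / sigma_x))`` where
    ``sigma_x`` is the slope *magnitude* and ``dir`` is +1 for the activation
    gates ``n`` and ``a`` and -1 for the inactivation gate ``b`` (which is
    de-inactivated, i.e. increased, by hyperpolarization).  Sodium activation
    is instantaneous, ``m = m_inf(V)``, and sodium inactivation is slaved to
    potassium activation, ``h = 1 - n``.
    """

    # membrane
    C: float = 1.0          # uF/cm^2
    g_L: float = 1.0        # mS/cm^2
    g_K: float = 45.0
    g_Na: float = 37.0
    g_A: float = 20.0       # A-channel maximal conductance; swept in studies
    V_L: float = -70.0      # mV
    V_K: float = -80.0
    V_Na: float = 55.0

    # gating kinetics
    phi_n: float = 0.75
    phi_a: float = 1.0
    phi_b: float = 1.0
    theta_n: float = -32.0  # mV, half-activation
    theta_a: float = -50.0
    theta_b: float = -70.0
    sigma_n: float = 8.0    # mV, slope magnitude
    sigma_a: float = 20.0
    sigma_b: float = 6.0
    tau_a: float = 2.0      # ms (the sweepable tau_A)
    tau_b: float = 150.0    # ms
    instantaneous_a: bool = False

    # synapses
    g_syn_E: float = 0.5    # mS/cm^2
    g_syn_I: float = 1.0
    V_E: float = 0.0        # mV
    V_I: float = -85.0
    beta_E: float = 0.2     # 1/ms, conductance decay rate
    beta_I: float = 0.18

    def __post_init__(self) -> None:
        for name in ("g_L", "g_K", "g_Na", "g_A", "g_syn_E", "g_syn_I"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("C", "tau_a", "tau_b", "beta_E", "beta_I",
                     "sigma_n", "sigma_a", "sigma_b"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def replace(self, **changes) -> "NeuronParams":
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "NeuronParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Excitation/inhibition strengths used for the reduced-model analysis, where
#: excitation must be much stronger than in the full model to evoke spikes.
REDUCED_DRIVE = dict(g_syn_E=3.0, g_syn_I=5.0, instantaneous_a=True)


def reduced_params(**changes) -> NeuronParams:
    """Default parameter set for the reduced (instantaneous-a) model."""
    merged = {**REDUCED_DRIVE, **changes}
    return NeuronParams(**merged)


@dataclass(frozen=True)
class CableParams:
    """Soma-dendrite cable: soma (compartment 1) carries all voltage-gated
    currents; nine passive dendritic compartments are chained to it.

    ``cpt_in`` indexes the dendritic compartment receiving excitation,
    1 (proximal) through 9 (distal).  ``cpt_inhib`` places inhibition at the
    soma (0) or a dendritic compartment (1-9).
    """

    n_compartments: int = 10
    g_L_dend: float = 0.1   # mS/cm^2, one tenth of the somatic leak
    g_ax: float = 10.0      # mS/cm^2, axial coupling
    cpt_in: int = 1
    cpt_inhib: int = 0

    def __post_init__(self) -> None:
        if self.n_compartments != 10:
            raise InvalidParameterError("cable model is defined for 10 compartments")
        if not 1 <= self.cpt_in <= 9:
            raise InvalidParameterError("cpt_in must be in 1..9")
        if not 0 <= self.cpt_inhib <= 9:
            raise InvalidParameterError("cpt_inhib must be in 0..9")
        if self.g_ax < 0 or self.g_L_dend < 0:
            raise InvalidParameterError("conductances must be >= 0")

    def replace(self, **changes) -> "CableParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
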