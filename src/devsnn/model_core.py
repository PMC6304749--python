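"""Neuron and synapse dynamics.

Single-neuron conductance-based leaky integrate-and-fire dynamics with two
exponentially decaying conductance channels (AMPA-like excitation, GABA_A-like
inhibition).  The developmental state of the network enters only through the
GABA_A reversal potential: depolarizing (-40 mV) in the immature state,
hyperpolarizing (-70 mV) in the mature state.

Subthreshold dynamics::

    dV/dt = (E_leak - V)/tau_m + [g_e*(E_exc - V) + g_i*(E_gaba - V)]/c_m
    dg_e/dt = -g_e/tau_exc
    dg_i/dt = -g_i/tau_inh

with g in nS, V in mV, c_m in pF and time in ms, so every term is mV/ms.
When V crosses ``V_threshold`` the neuron emits a spike, V is clamped to
``V_reset`` and held there for ``tau_ref``.

The membrane is advanced with forward Euler; conductances use the exact
exponential update.  The vectorized network engine in :mod:`devsnn.simulator`
reproduces exactly the per-step arithmetic defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum


class Maturation(str, Enum):
    IMMATURE = "immature"
    MATURE = "mature"


#: GABA_A reversal potential (mV) per developmental state.
E_GABA_BY_STATE = {Maturation.IMMATURE: -40.0, Maturation.MATURE: -70.0}


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire membrane parameters (ms, pF, mV)."""

    tau_m: float = 20.0
    c_m: float = 281.0
    E_leak: float = -70.6
    V_threshold: float = -50.4
    V_reset: float = -74.0
    tau_ref: float = 5.0

    def __post_init__(self) -> None:
        if not self.V_reset < self.V_threshold:
            raise ValueError("V_reset must be below V_threshold")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.c_m <= 0:
            raise ValueError("c_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")


@dataclass(frozen=True)
class SynapseParams:
    """Conductance channel parameters: decay constants (ms), per-spike
    increments (nS) and the AMPA reversal potential (mV)."""

    tau_exc: float = 5.0
    tau_inh: float = 10.0
    g_exc: float = 4.0
    g_inh: float = 64.0
    g_ext: float = 200.0
    E_exc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_exc", "tau_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_exc", "g_inh", "g_ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MaturationState:
    """Developmental GABA_A state: the label and its reversal potential are
    locked together (immature <-> -40 mV, mature <-> -70 mV)."""

    label: Maturation
    E_gaba: float

    def __post_init__(self) -> None:
        label = Maturation(self.label)
        object.__setattr__(self, "label", label)
        expected = E_GABA_BY_STATE[label]
        if self.E_gaba != expected:
            raise ValueError(
                f"{label.value} state requires E_gaba = {expected} mV, got {self.E_gaba}"
            )

    @classmethod
    def immature(cls) -> "MaturationState":
        return cls(Maturation.IMMATURE, E_GABA_BY_STATE[Maturation.IMMATURE])

    @classmethod
    def mature(cls) -> "MaturationState":
        return cls(Maturation.MATURE, E_GABA_BY_STATE[Maturation.MATURE])

    @classmethod
    def from_label(cls, label: str) -> "MaturationState":
        m = Maturation(label)
        return cls(m, E_GABA_BY_STATE[m])


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous state of one neuron (mV, nS, ms)."""

    V: float
    g_e: float = 0.0
    g_i: float = 0.0
    refractory_remaining: float = 0.0
    last_spike: float | None = None

    def __post_init__(self) -> None:
        if self.g_e < 0 or self.g_i < 0:
            raise ValueError("conductances must be non-negative")
        if self.refractory_remaining < 0:
            raise ValueError("refractory_remaining must be non-negative")


def _require_finite(state: NeuronState) -> None:
    for name in ("V", "g_e", "g_i", "refractory_remaining"):
        v = getattr(state, name)
        if not math.isfinite(v):
            raise FloatingPointError(f"non-finite neuron state: {name}={v!r}")


def conductance_decay(g: float, tau: float, dt: float) -> float:
    """Exact exponential conductance decay over one step: ``g * exp(-dt/tau)``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if g < 0:
        raise ValueError("g must be non-negative")
    return g * math.exp(-dt / tau)


def membrane_drive(
    V: float,
    g_e: float,
    g_i: float,
    np_: NeuronParams,
    sp: SynapseParams,
    E_gaba: float,
):
    """dV/dt (mV/ms) of the subthreshold membrane equation.

    Kept as a free function so the network engine and single-neuron stepping
    share one expression (bit-identical arithmetic).
    """
    return (np_.E_leak - V) / np_.tau_m + (
        g_e * (sp.E_exc - V) + g_i * (E_gaba - V)
    ) / np_.c_m


def membrane_step(
    state: NeuronState,
    np_: NeuronParams,
    sp: SynapseParams,
    ms: MaturationState,
    dt: float,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by ``dt`` ms.

    Refractory neurons stay clamped at ``V_reset`` and only the timer counts
    down; active neurons take one forward-Euler step and spike-reset on
    threshold crossing.  Conductances decay exponentially in either case.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _require_finite(state)

    g_e_next = conductance_decay(state.g_e, sp.tau_exc, dt)
    g_i_next = conductance_decay(state.g_i, sp.tau_inh, dt)

    if state.refractory_remaining > 0:
        return (
            replace(
                state,
                V=np_.V_reset,
                g_e=g_e_next,
                g_i=g_i_next,
                refractory_remaining=max(state.refractory_remaining - dt, 0.0),
            ),
            False,
        )

    dV = membrane_drive(state.V, state.g_e, state.g_i, np_, sp, ms.E_gaba)
    V_new = state.V + dt * dV
    if not math.isfinite(V_new):
        raise FloatingPointError(f"membrane potential diverged: V={V_new!r}")

    if V_new >= np_.V_threshold:
        return (
            replace(
                state,
                V=np_.V_reset,
                g_e=g_e_next,
                g_i=g_i_next,
                refractory_remaining=np_.tau_ref,
            ),
            True,
        )
    return replace(state, V=V_new, g_e=g_e_next, g_i=g_i_next), False


def on_presynaptic_spike(
    state: NeuronState, weight: float, is_inhibitory: bool
) -> NeuronState:
    """Instantaneous conductance jump on arrival of a presynaptic spike."""
    if weight < 0:
        raise ValueError("synaptic weight must be non-negative")
    if is_inhibitory:
        return replace(state, g_i=state.g_i + weight)
    return replace(state, g_e=state.g_e + weight)
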