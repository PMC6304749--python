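"""Short-term synaptic plasticity (utilization/resource recursion).

Each synapse carries a running utilization ``u`` (facilitation) and an
available-resource fraction ``x`` (depression).  On a presynaptic spike at
interval ``dt`` after the previous one::

    u-  = u * exp(-dt / tau_fac)
    u'  = u- + U * (1 - u-)
    x-  = 1 - (1 - x) * exp(-dt / tau_dep)     # x is the post-release value
    eff = u' * x-
    x'  = x- * (1 - u')

The transmitted weight is ``nominal_weight * eff / U`` so that the first
spike from rest transmits exactly the nominal weight.  Facilitation is
applied before release and the release uses the updated utilization; this
ordering is stated explicitly because conventions differ across
implementations.

Four named variants differ only in their (tau_dep, tau_fac) pairs:
STD1 = (100, 1), STD2 = (100, 10), STF1 = (1, 100), STF2 = (10, 100) ms.
The baseline utilization U is configuration (0.5 by default), shared by all
variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "STPParams",
    "STPState",
    "VARIANT_TIME_CONSTANTS",
    "stp_variant",
    "stp_on_spike",
    "steady_state",
    "steady_state_efficacy",
]

#: (tau_dep, tau_fac) in ms for each named variant.
VARIANT_TIME_CONSTANTS: dict[str, tuple[float, float]] = {
    "STD1": (100.0, 1.0),
    "STD2": (100.0, 10.0),
    "STF1": (1.0, 100.0),
    "STF2": (10.0, 100.0),
}

DEFAULT_U = 0.5


@dataclass(frozen=True)
class STPParams:
    U: float = DEFAULT_U
    tau_dep: float = 100.0
    tau_fac: float = 1.0
    variant: str = "none"

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("U must lie in (0, 1]")
        if self.tau_dep <= 0 or self.tau_fac <= 0:
            raise ValueError("time constants must be positive")

    @property
    def is_static(self) -> bool:
        return self.variant == "none"


@dataclass(frozen=True)
class STPState:
    """Per-synapse dynamic variables; ``x`` stores the post-release resource."""

    u: float = 0.0
    x: float = 1.0
    t_last: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.u <= 1 and 0 <= self.x <= 1):
            raise ValueError("u and x must lie in [0, 1]")


def stp_variant(name: str, U: float = DEFAULT_U) -> STPParams:
    """Parameters for one of std1|std2|stf1|stf2|none (case-insensitive)."""
    key = name.strip().upper()
    if key in ("NONE", "CONTROL"):
        return STPParams(U=U, variant="none")
    if key not in VARIANT_TIME_CONSTANTS:
        raise ValueError(
            f"unknown STP variant {name!r}; expected one of "
            "std1, std2, stf1, stf2, none"
        )
    tau_dep, tau_fac = VARIANT_TIME_CONSTANTS[key]
    return STPParams(U=U, tau_dep=tau_dep, tau_fac=tau_fac, variant=key)


def stp_on_spike(
    state: STPState, p: STPParams, delta_t: float | None
) -> tuple[STPState, float]:
    """Apply one presynaptic spike; returns the new state and the efficacy.

    ``delta_t`` is the interval since the previous spike in ms (None for the
    first spike, treated as full recovery).  The applied weight factor is
    ``efficacy / U``.
    """
    if p.is_static:
        return state, p.U  # applied factor efficacy/U == 1
    if delta_t is None:
        u_minus, x_minus = state.u * 0.0, 1.0
    else:
        if delta_t <= 0:
            raise ValueError("delta_t must be positive")
        u_minus = state.u * math.exp(-delta_t / p.tau_fac)
        x_minus = 1.0 - (1.0 - state.x) * math.exp(-delta_t / p.tau_dep)
    u_new = u_minus + p.U * (1.0 - u_minus)
    efficacy = u_new * x_minus
    x_after = x_minus * (1.0 - u_new)
    if not (0.0 <= u_new <= 1.0 and 0.0 <= x_after <= 1.0):
        raise FloatingPointError(
            f"STP invariant violated: u={u_new}, x={x_after}"
        )
    return replace(state, u=u_new, x=x_after), efficacy


def steady_state(p: STPParams, rate: float) -> tuple[float, float]:
    """Fixed point (u*, x-*) of the recursion under a periodic train.

    ``x-*`` is the pre-release resource at the moment of each spike, so the
    steady-state efficacy is ``u* * x-*``.  Closed form::

        u*  = U / (1 - (1 - U) * exp(-T/tau_fac))
        x-* = (1 - e_d) / (1 - (1 - u*) * e_d),   e_d = exp(-T/tau_dep)
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    T = 1000.0 / rate  # ms
    e_f = math.exp(-T / p.tau_fac)
    e_d = math.exp(-T / p.tau_dep)
    u_star = p.U / (1.0 - (1.0 - p.U) * e_f)
    x_star = (1.0 - e_d) / (1.0 - (1.0 - u_star) * e_d)
    return u_star, x_star


def steady_state_efficacy(p: STPParams, rate: float) -> float:
    """Steady-state efficacy under a regular train at ``rate`` Hz."""
    if p.is_static:
        return p.U
    u_star, x_star = steady_state(p, rate)
    return u_star * x_star
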