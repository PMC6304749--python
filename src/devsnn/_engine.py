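"""Numba inner loop of the clock-driven engine.

The kernel advances a block of steps and mutates the state arrays in place;
all randomness (external Poisson counts) is drawn outside and passed in, so
runs stay bit-reproducible and the kernel is pure.  The per-neuron update
order mirrors :func:`devsnn.model_core.membrane_step` exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["step_block"]


@njit(cache=True)
def step_block(
    # mutable state
    V, g_e, g_i, refr, u, x, last_spike_step,
    buf_e, buf_i,  # (D, n) ring buffers
    # block inputs
    step0, n_block, ext_counts,  # ext_counts: (n_block, n) int64
    # constants
    dt, decay_e, decay_i,
    E_leak, tau_m, c_m, E_exc, E_gaba, V_threshold, V_reset, tau_ref,
    g_ext,
    # synapses (CSR by source)
    indptr, tgt, weight, delay_steps, inh,
    # STP
    stp_active, U, tau_fac, tau_dep,
    # spike output
    out_steps, out_ids,
):
    n = V.shape[0]
    D = buf_e.shape[0]
    m = 0
    for k in range(n_block):
        step = step0 + k
        slot = step % D
        for i in range(n):
            g_e[i] += buf_e[slot, i]
            g_i[i] += buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0
            c = ext_counts[k, i]
            if c > 0:
                g_e[i] += c * g_ext

        for i in range(n):
            if refr[i] > 0.0:
                V[i] = V_reset
                r = refr[i] - dt
                refr[i] = r if r > 0.0 else 0.0
                g_e[i] *= decay_e
                g_i[i] *= decay_i
                continue
            dV = (E_leak - V[i]) / tau_m + (
                g_e[i] * (E_exc - V[i]) + g_i[i] * (E_gaba - V[i])
            ) / c_m
            v_new = V[i] + dt * dV
            g_e[i] *= decay_e
            g_i[i] *= decay_i
            if v_new >= V_threshold:
                V[i] = V_reset
                refr[i] = tau_ref
                out_steps[m] = step
                out_ids[m] = i
                m += 1
                # transmitted factor (efficacy / U); static synapses pass 1
                factor = 1.0
                if stp_active[i]:
                    if last_spike_step[i] < 0:
                        u_minus = 0.0
                        x_minus = 1.0
                    else:
                        delta_t = (step - last_spike_step[i]) * dt
                        u_minus = u[i] * np.exp(-delta_t / tau_fac)
                        x_minus = 1.0 - (1.0 - x[i]) * np.exp(-delta_t / tau_dep)
                    u_new = u_minus + U * (1.0 - u_minus)
                    factor = u_new * x_minus / U
                    u[i] = u_new
                    x[i] = x_minus * (1.0 - u_new)
                last_spike_step[i] = step
                for s in range(indptr[i], indptr[i + 1]):
                    dslot = (step + delay_steps[s]) % D
                    if inh[s]:
                        buf_i[dslot, tgt[s]] += weight[s] * factor
                    else:
                        buf_e[dslot, tgt[s]] += weight[s] * factor
            else:
                V[i] = v_new

        if step % 2000 == 0:
            for i in range(n):
                if not np.isfinite(V[i]):
                    return m, step  # caller raises with diagnostics
    return m, -1
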