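"""Local EPSP dynamics of one high-impedance postsynaptic compartment.

Each synapse occupies a ~2 um^2 membrane domain of 50 GOhm input
resistance carrying a 20 pS leak.  Open synaptic conductances pull the
potential toward the 0 mV glutamatergic reversal while shortening the
effective membrane time constant; the update is the per-step exponential
relaxation of the conductance-based RC circuit toward its instantaneous
steady state.  NMDA receptors are gated by the compartment's own voltage
of the previous step, so a depolarizing AMPA transient can regeneratively
recruit NMDA conductance — the compartment supports NMDA plateau-like
behavior.  A hard ceiling keeps the potential strictly below 0 mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MembraneParams, MgBlockParams, ParameterError, SynapticInput
from .receptor_kinetics import (
    ampa_conductance,
    mg_unblock_fraction,
    nmda_conductance,
    receptor_current,
)

__all__ = [
    "V_CEILING",
    "dynamic_time_constant",
    "step_membrane_potential",
    "SynapseState",
    "EpspResult",
    "simulate_synaptic_event",
]

#: Numerical ceiling just below the glutamatergic reversal potential; the
#: compartment voltage is clamped to stay strictly negative.
V_CEILING = -1e-9


def dynamic_time_constant(g_syn: float, membrane: MembraneParams) -> float:
    """Effective membrane time constant with ``g_syn`` pS of open conductance.

    ``tau(g) = tau_m / (1 + r_m * g_syn)`` — the resting constant when no
    synaptic conductance is open, shrinking monotonically as channels
    open.  ``r_m`` in GOhm times ``g_syn`` in pS gives the dimensionless
    ratio ``g_syn / g_leak``.
    """
    if g_syn < 0:
        raise ParameterError("g_syn must be >= 0")
    return membrane.tau_m / (1.0 + membrane.r_m * g_syn * 1e-3)


def step_membrane_potential(
    v: float,
    g_ampa: float,
    g_nmda_eff: float,
    dt: float,
    membrane: MembraneParams,
    leak_target: float | None = None,
) -> float:
    """One explicit step of the compartment RC update.

    The potential relaxes toward the conductance-weighted steady state
    ``V_inf = (g_leak * E_L + g_syn * V_eq) / (g_leak + g_syn)`` with rate
    ``1 / tau(g_syn)`` from :func:`dynamic_time_constant`.  ``leak_target``
    replaces ``E_L`` when the compartment rides on a dendritic baseline
    set by other active sources.  The result is clamped strictly below
    0 mV.
    """
    if g_ampa < 0 or g_nmda_eff < 0:
        raise ParameterError("conductances must be >= 0")
    e_l = membrane.e_leak if leak_target is None else leak_target
    g_syn = g_ampa + g_nmda_eff
    g_tot = membrane.g_leak + g_syn
    v_inf = (membrane.g_leak * e_l + g_syn * membrane.v_eq_syn) / g_tot
    tau = dynamic_time_constant(g_syn, membrane)
    v_next = v_inf + (v - v_inf) * np.exp(-dt / tau)
    return min(v_next, V_CEILING)


@dataclass
class EpspResult:
    """Trajectory of one synaptic event.

    ``i_syn`` equals ``i_ampa + i_nmda`` pointwise (pA, positive
    depolarizing); ``v_local`` is strictly below 0 mV throughout.
    """

    times: np.ndarray
    v_local: np.ndarray
    i_syn: np.ndarray
    i_ampa: np.ndarray
    i_nmda: np.ndarray
    g_ampa: np.ndarray
    g_nmda_eff: np.ndarray


class SynapseState:
    """Stepwise integrator for one synaptic compartment.

    Used both standalone (fixed baseline) and inside the coupled engine
    loop, where the baseline at each step is the dendritic field produced
    by every other source at this synapse's position.
    """

    def __init__(self, inp: SynapticInput, membrane: MembraneParams,
                 mg: MgBlockParams, dt: float):
        self.inp = inp
        self.membrane = membrane
        self.mg = mg
        self.dt = dt
        self.v = membrane.v_rest

    def step(self, t: float, baseline: float) -> tuple[float, float, float]:
        """Advance to time ``t``; returns (v, g_ampa, g_nmda_eff).

        Before onset the compartment tracks the baseline passively; after
        onset it integrates the RC update, with the NMDA Mg gate driven by
        the compartment's own previous-step voltage.
        """
        ts = t - self.inp.onset
        if ts <= 0:
            self.v = min(baseline, V_CEILING)
            return self.v, 0.0, 0.0
        g_a = ampa_conductance(ts, self.inp.ampa)
        g_n = nmda_conductance(ts, self.v, self.inp.nmda, self.mg)
        self.v = step_membrane_potential(
            self.v, g_a, g_n, self.dt, self.membrane, leak_target=baseline,
        )
        return self.v, g_a, g_n


def simulate_synaptic_event(
    inp: SynapticInput,
    baseline: np.ndarray | float | None,
    membrane: MembraneParams,
    dt: float,
    duration: float = 40.0,
) -> EpspResult:
    """Integrate one synaptic event against a prescribed baseline.

    ``baseline`` is the propagated potential at this synapse's position
    from all other sources (resting potential if ``None`` or scalar); the
    local trajectory starts from the baseline value holding at onset.
    """
    n = int(round(duration / dt))
    times = np.arange(n) * dt
    if inp.onset >= duration:
        raise ParameterError(
            f"onset {inp.onset} ms outside the {duration} ms window"
        )
    if baseline is None:
        base = np.full(n, membrane.v_rest)
    elif np.ndim(baseline) == 0:
        base = np.full(n, float(baseline))
    else:
        base = np.asarray(baseline, dtype=float)
        if base.size != n:
            raise ValueError("baseline length does not match the time grid")

    state = SynapseState(inp, membrane, mg=MgBlockParams(), dt=dt)
    v = np.empty(n)
    g_a = np.empty(n)
    g_n = np.empty(n)
    v[0] = min(base[0], V_CEILING)
    g_a[0] = g_n[0] = 0.0
    for k in range(1, n):
        v[k], g_a[k], g_n[k] = state.step(times[k], base[k])

    i_a = receptor_current(g_a, v, membrane.v_eq_syn)
    i_n = receptor_current(g_n, v, membrane.v_eq_syn)
    return EpspResult(
        times=times, v_local=v, i_syn=i_a + i_n, i_ampa=i_a, i_nmda=i_n,
        g_ampa=g_a, g_nmda_eff=g_n,
    )
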