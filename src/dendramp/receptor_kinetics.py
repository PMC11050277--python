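"""Receptor conductance waveforms and the NMDA magnesium unblock factor.

Pure functions of time and voltage; every stateful coupling (which voltage
gates which conductance at which step) lives in the compartment and engine
modules.
"""

from __future__ import annotations

import numpy as np

from .params import MgBlockParams, ParameterError, ReceptorParams

__all__ = [
    "dual_exponential_waveform",
    "dual_exponential_peak_time",
    "mg_unblock_fraction",
    "ampa_conductance",
    "nmda_conductance",
    "receptor_current",
]


def dual_exponential_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form argmax of ``exp(-t/tau_decay) - exp(-t/tau_rise)``."""
    if not tau_decay > tau_rise > 0:
        raise ParameterError("require tau_decay > tau_rise > 0")
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) * np.log(tau_decay / tau_rise)


def dual_exponential_waveform(
    t_since_onset,
    tau_rise: float,
    tau_decay: float,
    normalize_peak: bool = False,
):
    """Difference-of-exponentials gating factor, zero for t <= 0.

    With ``normalize_peak`` the waveform is rescaled so its maximum over
    time equals exactly 1; otherwise the raw difference is returned, whose
    maximum is ``exp(-t*/tau_decay) - exp(-t*/tau_rise)`` at the closed-form
    peak time ``t*``.
    """
    if not tau_decay > tau_rise > 0:
        raise ParameterError(
            f"require tau_decay > tau_rise > 0, got {tau_rise}, {tau_decay}"
        )
    t = np.asarray(t_since_onset, dtype=float)
    w = np.where(t > 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    if normalize_peak:
        ts = dual_exponential_peak_time(tau_rise, tau_decay)
        w = w / (np.exp(-ts / tau_decay) - np.exp(-ts / tau_rise))
    if np.ndim(t_since_onset) == 0:
        return float(w)
    return w


def mg_unblock_fraction(v, params: MgBlockParams = MgBlockParams()):
    """Fraction of NMDA receptors free of Mg2+ occlusion at potential ``v``.

    Jahr-Stevens form: ``k_eq / (k_eq + mg_ex * exp(-v_factor * v))``.
    Strictly increasing in ``v`` and bounded in (0, 1); equals
    ``k_eq / (k_eq + mg_ex)`` at 0 mV.
    """
    v = np.asarray(v, dtype=float)
    # exp argument clipped only to avoid overflow warnings at absurd inputs
    expo = np.clip(-params.v_factor * v, -700.0, 700.0)
    out = params.k_eq / (params.k_eq + params.mg_ex * np.exp(expo))
    if out.ndim == 0:
        return float(out)
    return out


def ampa_conductance(t_since_onset, params: ReceptorParams):
    """AMPA conductance (pS) at ``t_since_onset`` ms after glutamate release."""
    w = dual_exponential_waveform(
        t_since_onset, params.tau_rise, params.tau_decay,
        normalize_peak=params.normalize_peak,
    )
    return params.g_max_total * w


def nmda_conductance(
    t_since_onset,
    v,
    params: ReceptorParams,
    mg: MgBlockParams = MgBlockParams(),
):
    """Effective NMDA conductance (pS): ligand gate times Mg unblock at ``v``."""
    w = dual_exponential_waveform(
        t_since_onset, params.tau_rise, params.tau_decay,
        normalize_peak=params.normalize_peak,
    )
    return params.g_max_total * w * mg_unblock_fraction(v, mg)


def receptor_current(g, v, v_eq: float = 0.0):
    """Ohmic receptor current in pA, positive when depolarizing.

    ``g`` in pS and voltages in mV give fA; dividing by 1000 yields pA.
    The sign convention reports current injected into the membrane as a
    positive magnitude when it drives the potential toward ``v_eq``.
    """
    return np.multiply(g, np.subtract(v_eq, v)) / 1000.0
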