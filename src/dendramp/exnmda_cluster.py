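"""Extrasynaptic NMDA cluster: a ligand-gated point conductance on the shaft.

Roughly 80 NMDA receptors collapsed to a single locus carry about seven
times the synaptic NMDA conductance with a much slower decay (NR2B-like,
tens of ms).  Ligand availability is modeled by the same dual-exponential
gate as at the synapse; the Mg block is relieved by the dendritic
depolarization that synaptic currents deliver to the cluster's position.
The cluster's own current does not feed back into its gating voltage —
shaft potential at the cluster is shifted only by waves of synaptic
origin, which is what makes the cluster an amplifier of incoming signals
rather than a self-igniting source.
"""

from __future__ import annotations

from .params import ClusterSpec, MgBlockParams
from .receptor_kinetics import (
    dual_exponential_waveform,
    mg_unblock_fraction,
    receptor_current,
)

__all__ = ["cluster_conductance", "cluster_current", "ClusterState"]


def cluster_conductance(
    t_since_onset,
    v_local,
    spec: ClusterSpec,
    mg: MgBlockParams = MgBlockParams(),
):
    """Effective cluster conductance (pS), zero before ligand delivery.

    ``v_local`` is the shaft potential at the cluster position produced by
    synaptic sources at the previous step.  The ligand gate uses the raw
    difference of exponentials, matching the synaptic NMDA convention.
    """
    w = dual_exponential_waveform(
        t_since_onset, spec.tau_rise, spec.tau_decay, normalize_peak=False,
    )
    return spec.g_max_total * w * mg_unblock_fraction(v_local, mg)


def cluster_current(g_eff, v_local, v_eq: float = 0.0):
    """Ohmic current (pA, positive depolarizing) injected at the cluster."""
    return receptor_current(g_eff, v_local, v_eq)


class ClusterState:
    """Stepwise evaluator used by the engine loop.

    Every step depends only on previous-step quantities: the gating
    voltage handed in is the synaptic-origin field at the cluster position
    evaluated one step earlier, so setting ``g_max_total = 0`` reproduces
    the passive simulation bit-exactly.
    """

    def __init__(self, spec: ClusterSpec, mg: MgBlockParams, v_eq: float = 0.0):
        self.spec = spec
        self.mg = mg
        self.v_eq = v_eq

    def step(self, t: float, v_gate: float) -> tuple[float, float]:
        """Return (g_eff pS, injected current pA) at time ``t``."""
        ts = t - self.spec.onset
        if ts <= 0 or self.spec.g_max_total == 0.0:
            return 0.0, 0.0
        g = cluster_conductance(ts, v_gate, self.spec, self.mg)
        return g, cluster_current(g, v_gate, self.v_eq)
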