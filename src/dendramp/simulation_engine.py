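"""Coupled step-by-step simulation and the experiment protocol presets.

The engine advances every source explicitly at the native 10 us step:

1. each synaptic compartment is updated from its baseline — the dendritic
   field that every *other* source produced at its position one step
   earlier;
2. the synaptic currents are injected into the cable;
3. the cluster conductance is evaluated from the previous-step field of
   synaptic origin at its position, and its current is injected too;
4. all contributions are superposed into the voltage field.

Everything is deterministic; two runs of the same protocol produce
bit-identical fields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cable_propagation import VoltageField, discrete_kernel, propagate_current, superpose
from .exnmda_cluster import ClusterState
from .params import (
    ClusterSpec,
    ModelParams,
    ProtocolError,
    ProtocolSpec,
    SynapticInput,
    three_input_train,
)
from .synaptic_compartment import SynapseState
from .receptor_kinetics import receptor_current

__all__ = [
    "TraceSummary",
    "run_protocol",
    "soma_trace",
    "peak_metrics",
    "amplification_gain",
    "scan_latency",
    "scan_interval",
    "scan_spacing",
    "scan_cluster_position",
    "scan_decay_constant",
    "PRESETS",
    "get_preset",
]

log = logging.getLogger("dendramp")


@dataclass(frozen=True)
class TraceSummary:
    """Peak deviation of a voltage trace relative to rest."""

    peak_amplitude: float   # mV above rest
    peak_time: float        # ms, earliest maximum
    location: float         # um


def _simulate_currents(spec: ProtocolSpec):
    """Run the coupled loop; returns (times, currents S x n, diagnostics)."""
    p = spec.params
    dt = p.cable.dt
    n = int(round(spec.duration / dt))
    times = np.arange(n) * dt

    syn_states = [SynapseState(s, p.membrane, p.mg, dt) for s in spec.inputs]
    n_syn = len(syn_states)
    if n_syn > 4:
        warnings.warn(
            f"{n_syn} synaptic inputs: the model is characterized for up to "
            "four", stacklevel=3,
        )
    positions = [s.position for s in spec.inputs]
    has_cluster = spec.cluster is not None
    if has_cluster:
        cluster = ClusterState(spec.cluster, p.mg, p.membrane.v_eq_syn)
        positions = positions + [spec.cluster.position]
    n_src = len(positions)

    # pairwise discrete kernels, target <- source
    kern: Dict[tuple, np.ndarray] = {}
    for i in range(n_src):
        for j in range(n_src):
            if i == j:
                continue
            d = abs(positions[i] - positions[j])
            if ("d", d) not in kern:
                kern[("d", d)] = discrete_kernel(d, n, p.cable)
            kern[(i, j)] = kern[("d", d)]

    I = np.zeros((n_src, n))                  # injected currents, pA
    v_loc = np.full((n_syn, n), p.membrane.v_rest)
    g_ampa = np.zeros((n_syn, n))
    g_nmda = np.zeros((n_syn, n))
    g_clu = np.zeros(n)
    dt_c = dt

    for k in range(1, n):
        # previous-step field of every other source at each target position
        def field_from(js: Iterable[int], target: int) -> float:
            tot = 0.0
            for j in js:
                tot += float(np.dot(I[j, :k], kern[(target, j)][k:0:-1]))
            return tot * dt_c

        t = times[k]
        for i, st in enumerate(syn_states):
            others = [j for j in range(n_src) if j != i]
            base = p.membrane.v_rest + field_from(others, i)
            v, ga, gn = st.step(t, base)
            v_loc[i, k] = v
            g_ampa[i, k] = ga
            g_nmda[i, k] = gn
            I[i, k] = receptor_current(ga + gn, v, p.membrane.v_eq_syn)
        if has_cluster:
            ci = n_src - 1
            v_gate = p.membrane.v_rest + field_from(range(n_syn), ci)
            g, ic = cluster.step(t, v_gate)
            g_clu[k] = g
            I[ci, k] = ic

    diag = dict(
        source_positions=np.array(positions),
        v_local=v_loc, g_ampa=g_ampa, g_nmda=g_nmda, g_cluster=g_clu,
        i_sources=I, times_full=times,
    )
    return times, I, diag


def run_protocol(
    spec: ProtocolSpec,
    positions: Optional[Sequence[float]] = None,
) -> VoltageField:
    """Execute a protocol and return the voltage field on the output grid.

    ``positions`` overrides the export grid (default: 0 to cable length at
    ``dx_out``).  The field's ``meta`` carries the full-resolution source
    currents, compartment traces, and the far-edge trace at the native
    time step.
    """
    p = spec.params
    times, I, diag = _simulate_currents(spec)
    n = times.size
    cable = p.cable

    if positions is None:
        positions = np.arange(0.0, cable.length + 0.5 * cable.dx_out, cable.dx_out)
    positions = np.asarray(positions, dtype=float)

    contribs = [
        propagate_current(pos, I[j], cable, positions=positions)
        for j, pos in enumerate(diag["source_positions"])
    ]
    field_full = superpose(contribs, v_rest=p.membrane.v_rest,
                           grid=(positions, times))

    # far-edge trace at native resolution for precise peak metrics
    if cable.length in positions:
        soma_full = field_full.values[int(np.argmin(np.abs(positions - cable.length)))]
    else:
        edge = superpose(
            [propagate_current(pos, I[j], cable, positions=[cable.length])
             for j, pos in enumerate(diag["source_positions"])],
            v_rest=p.membrane.v_rest, grid=([cable.length], times),
        )
        soma_full = edge.values[0]

    stride = max(1, int(round(cable.dt_out / cable.dt)))
    field = VoltageField(
        positions=positions,
        times=times[::stride],
        values=field_full.values[:, ::stride],
        v_rest=p.membrane.v_rest,
        meta={**diag, "protocol": spec.name, "soma_trace_full": soma_full},
    )
    log.info(
        "protocol %s: %d sources, grid %d x %d, far-edge peak %+.3f mV",
        spec.name, I.shape[0], field.positions.size, field.times.size,
        float(soma_full.max()),
    )
    return field


def soma_trace(field: VoltageField) -> np.ndarray:
    """Voltage time series at the far ("somatic") edge of the field grid."""
    return field.values[int(np.argmax(field.positions))]


def peak_metrics(
    trace: np.ndarray,
    times: Optional[np.ndarray] = None,
    rest: float = -65.0,
    location: float = float("nan"),
) -> TraceSummary:
    """Amplitude above rest and time of the earliest maximum of a trace."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("peak_metrics requires a non-empty trace")
    if times is None:
        times = np.arange(trace.size, dtype=float)
    idx = int(np.argmax(trace))          # argmax returns the earliest tie
    return TraceSummary(
        peak_amplitude=float(trace[idx] - rest),
        peak_time=float(times[idx]),
        location=float(location),
    )


def amplification_gain(with_cluster: VoltageField,
                       without_cluster: VoltageField) -> float:
    """Ratio of far-edge peak amplitudes, with / without the cluster."""
    rest = without_cluster.v_rest
    a_with = float(np.max(with_cluster.meta.get(
        "soma_trace_full", soma_trace(with_cluster))) - rest)
    a_passive = float(np.max(without_cluster.meta.get(
        "soma_trace_full", soma_trace(without_cluster))) - rest)
    if a_passive == 0.0:
        warnings.warn("passive far-edge amplitude is zero; gain is infinite")
        return float("inf")
    return a_with / a_passive


def _far_edge_summary(spec: ProtocolSpec) -> TraceSummary:
    length = spec.params.cable.length
    field = run_protocol(spec, positions=[length])
    return peak_metrics(
        field.meta["soma_trace_full"], field.meta["times_full"],
        rest=spec.params.membrane.v_rest, location=length,
    )


def _rows_to_frame(rows: List[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def scan_latency(
    base: ProtocolSpec,
    offsets: Sequence[float],
    order: str = "cluster_first",
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Shift one input class later by each offset and summarize the far edge.

    ``cluster_first`` delays every synaptic onset by the offset (ligand
    reaches the cluster first); ``epsp_first`` delays the cluster.  With
    ``include_baseline`` a final ``offset = inf`` row reports the protocol
    with the delayed class absent altogether.
    """
    if order not in ("cluster_first", "epsp_first"):
        raise ValueError("order must be 'cluster_first' or 'epsp_first'")
    if any(o < 0 for o in offsets):
        raise ValueError("offsets must be >= 0")
    if base.cluster is None:
        raise ProtocolError("latency scan requires a cluster in the base protocol")
    rows = []
    for off in offsets:
        if order == "cluster_first":
            inputs = tuple(replace(s, onset=s.onset + off) for s in base.inputs)
            spec = base.with_(name=f"{base.name}+lat{off}", inputs=inputs)
        else:
            cl = replace(base.cluster, onset=base.cluster.onset + off)
            spec = base.with_(name=f"{base.name}+lat{off}", cluster=cl)
        s = _far_edge_summary(spec)
        rows.append(dict(offset=off, order=order,
                         peak_amplitude=s.peak_amplitude,
                         peak_time=s.peak_time, location=s.location))
    if include_baseline:
        if order == "cluster_first":
            spec = base.with_(name=f"{base.name}+noinput", inputs=())
        else:
            spec = base.with_(name=f"{base.name}+nocluster", cluster=None)
        s = _far_edge_summary(spec)
        rows.append(dict(offset=float("inf"), order=order,
                         peak_amplitude=s.peak_amplitude,
                         peak_time=s.peak_time, location=s.location))
    return _rows_to_frame(rows)


def scan_interval(base: ProtocolSpec, intervals: Sequence[float],
                  spacing: float = 1.0) -> pd.DataFrame:
    """Vary the inter-stimulus interval of a three-input train."""
    rows = []
    for iv in intervals:
        if iv < 0:
            raise ValueError("intervals must be >= 0")
        inputs = three_input_train(iv, spacing=spacing)
        spec = base.with_(name=f"{base.name}+iv{iv}", inputs=inputs)
        s = _far_edge_summary(spec)
        rows.append(dict(interval=iv, spacing=spacing,
                         peak_amplitude=s.peak_amplitude,
                         peak_time=s.peak_time, location=s.location))
    return _rows_to_frame(rows)


def scan_spacing(base: ProtocolSpec, intervals: Sequence[float],
                 spacing: float) -> pd.DataFrame:
    """Three inputs spread ``spacing`` um apart, one row per interval."""
    if spacing < 0:
        raise ValueError("spacing must be >= 0")
    return scan_interval(base, intervals, spacing=spacing)


def scan_cluster_position(base: ProtocolSpec,
                          positions: Sequence[float]) -> pd.DataFrame:
    """Move the cluster along the shaft; far-edge summary per position."""
    if base.cluster is None:
        raise ProtocolError("position scan requires a cluster in the base protocol")
    rows = []
    for pos in positions:
        spec = base.with_(name=f"{base.name}+pos{pos}",
                          cluster=replace(base.cluster, position=pos))
        s = _far_edge_summary(spec)
        rows.append(dict(position=pos, peak_amplitude=s.peak_amplitude,
                         peak_time=s.peak_time, location=s.location))
    return _rows_to_frame(rows)


def scan_decay_constant(base: ProtocolSpec,
                        taus: Sequence[float]) -> pd.DataFrame:
    """Vary the cluster conductance decay constant (subunit composition)."""
    if base.cluster is None:
        raise ProtocolError("decay scan requires a cluster in the base protocol")
    rows = []
    for tau in taus:
        spec = base.with_(name=f"{base.name}+tau{tau}",
                          cluster=replace(base.cluster, tau_decay=tau))
        s = _far_edge_summary(spec)
        rows.append(dict(tau_decay=tau, peak_amplitude=s.peak_amplitude,
                         peak_time=s.peak_time, location=s.location))
    return _rows_to_frame(rows)


# --------------------------------------------------------------------------
# protocol presets
# --------------------------------------------------------------------------

def _single_input() -> tuple:
    return (SynapticInput(position=0.0, onset=0.5),)


def _preset_fig1a() -> ProtocolSpec:
    """Single synaptic input at the origin; purely passive propagation."""
    return ProtocolSpec(name="fig1a", inputs=_single_input())


def _preset_fig1b() -> ProtocolSpec:
    """Cluster alone at 400 um, ligand at 0.5 ms; no synaptic input."""
    return ProtocolSpec(name="fig1b", cluster=ClusterSpec())


def _preset_fig1c() -> ProtocolSpec:
    """Single input and cluster, ligand delivered to both at 0.5 ms."""
    return ProtocolSpec(name="fig1c", inputs=_single_input(),
                        cluster=ClusterSpec())


def _preset_fig2a() -> ProtocolSpec:
    """Three inputs 1.3 ms apart at neighboring loci; no cluster."""
    return ProtocolSpec(name="fig2a", inputs=three_input_train(1.3))


def _preset_fig2b() -> ProtocolSpec:
    """Three inputs 1.3 ms apart co-activated with the cluster."""
    return ProtocolSpec(name="fig2b", inputs=three_input_train(1.3),
                        cluster=ClusterSpec())


def _preset_fig3() -> ProtocolSpec:
    """Cluster leads: synaptic train delayed 5 ms after ligand delivery."""
    return ProtocolSpec(name="fig3",
                        inputs=three_input_train(1.3, first_onset=5.5),
                        cluster=ClusterSpec())


def _preset_fig4() -> ProtocolSpec:
    """High-frequency train (0.3 ms intervals) with the cluster."""
    return ProtocolSpec(name="fig4", inputs=three_input_train(0.3),
                        cluster=ClusterSpec())


def _preset_fig5() -> ProtocolSpec:
    """Inputs spread 100 um apart (1.3 ms intervals) with the cluster."""
    return ProtocolSpec(name="fig5",
                        inputs=three_input_train(1.3, spacing=100.0),
                        cluster=ClusterSpec())


def _preset_fig6() -> ProtocolSpec:
    """Dense train (0.3 ms) with the cluster; base for the position scan."""
    return ProtocolSpec(name="fig6", inputs=three_input_train(0.3),
                        cluster=ClusterSpec())


def _preset_fig7() -> ProtocolSpec:
    """Slowest-decay cluster (100 ms) with the standard 1.3 ms train."""
    return ProtocolSpec(name="fig7", inputs=three_input_train(1.3),
                        cluster=ClusterSpec(tau_decay=100.0))


PRESETS: Dict[str, Callable[[], ProtocolSpec]] = {
    "fig1a": _preset_fig1a, "fig1b": _preset_fig1b, "fig1c": _preset_fig1c,
    "fig2a": _preset_fig2a, "fig2b": _preset_fig2b, "fig3": _preset_fig3,
    "fig4": _preset_fig4, "fig5": _preset_fig5, "fig6": _preset_fig6,
    "fig7": _preset_fig7,
}


def get_preset(name: str) -> ProtocolSpec:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ProtocolError(
            f"unknown protocol '{name}'; available: {', '.join(sorted(PRESETS))}"
        ) from None
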