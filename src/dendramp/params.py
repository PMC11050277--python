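"""Domain types and default biophysical constants.

All quantities use the unit system conventional for single-neuron
biophysics at this scale: conductances in pS, voltages in mV, currents in
pA, times in ms, distances in um, resistances in GOhm.  The identity
pS * mV = fA keeps Ohm's law closed within the system: i[pA] =
g[pS] * v[mV] / 1000.

Defaults describe a 1 mm passive dendrite receiving glutamatergic input at
one end, with an optional extrasynaptic NMDA (exNMDA) receptor cluster on
the shaft acting as a ligand- and voltage-gated amplifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple


class ParameterError(ValueError):
    """A parameter violates one of its declared invariants."""


class ProtocolError(ValueError):
    """A protocol definition is internally inconsistent."""


@dataclass(frozen=True)
class ReceptorParams:
    """Kinetic and conductance description of one ionotropic receptor pool.

    ``g_max_total`` is the conductance scale of the dual-exponential gate.
    If ``normalize_peak`` is true the gate is scaled to unit maximum so
    that ``g_max_total`` is the attained peak conductance (AMPA
    convention); otherwise the raw difference of exponentials is used and
    the attained peak is ``g_max_total`` times the waveform maximum
    (NMDA convention, where the Mg block keeps the realized conductance
    well below the nominal total).
    """

    g_max_total: float          # pS
    tau_rise: float             # ms
    tau_decay: float            # ms
    n_receptors: int = 0
    g_single: float = 0.0       # pS
    open_probability: float = 1.0
    normalize_peak: bool = True

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ParameterError(
                f"require tau_decay > tau_rise > 0, got "
                f"tau_rise={self.tau_rise}, tau_decay={self.tau_decay}"
            )
        if self.g_max_total < 0:
            raise ParameterError("g_max_total must be >= 0")
        if not 0.0 <= self.open_probability <= 1.0:
            raise ParameterError("open_probability must lie in [0, 1]")


@dataclass(frozen=True)
class MgBlockParams:
    """Voltage-dependent magnesium block of the NMDA receptor pore.

    The unblocked fraction follows the Jahr-Stevens form
    ``delta(V) = k_eq / (k_eq + mg_ex * exp(-v_factor * V))`` so that
    depolarization relieves the block.
    """

    k_eq: float = 3.6           # mM
    v_factor: float = 0.062     # 1/mV
    mg_ex: float = 1.2          # mM

    def __post_init__(self) -> None:
        if min(self.k_eq, self.v_factor, self.mg_ex) <= 0:
            raise ParameterError("Mg-block parameters must be strictly positive")


@dataclass(frozen=True)
class MembraneParams:
    """Passive properties of the ~2 um^2 postsynaptic membrane domain."""

    v_rest: float = -65.0       # mV
    e_leak: float = -65.0       # mV
    v_eq_syn: float = 0.0       # mV, glutamatergic reversal
    r_m: float = 50.0           # GOhm, input resistance of the domain
    g_leak: float = 20.0        # pS
    tau_m: float = 15.0         # ms

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ParameterError("tau_m must be positive")
        if self.g_leak <= 0 or self.r_m <= 0:
            raise ParameterError("leak conductance and r_m must be positive")
        # r_m [GOhm] and g_leak [pS]: product is dimensionless.
        if abs(self.r_m * self.g_leak * 1e-3 - 1.0) > 0.01:
            raise ParameterError(
                f"r_m must equal 1/g_leak within 1% "
                f"(r_m*g_leak = {self.r_m * self.g_leak * 1e-3:.4f})"
            )


@dataclass(frozen=True)
class CableParams:
    """Passive infinite-cable description of the dendritic shaft."""

    radius: float = 0.6             # um
    axial_resistivity: float = 100.0  # Ohm*cm
    lambda_m: float = 400.0         # um, space constant
    r_lambda: float = 1.85          # GOhm, input resistance scale
    length: float = 1000.0          # um
    dx_out: float = 1.0             # um, export grid spacing
    dt: float = 0.01                # ms, simulation step (10 us)
    dt_out: float = 0.05            # ms, export grid step (50 us)
    tau_m: float = 15.0             # ms, static membrane time constant

    def __post_init__(self) -> None:
        if self.lambda_m <= 0 or self.length <= 0:
            raise ParameterError("lambda_m and length must be positive")
        if self.dt <= 0 or self.dt_out <= 0:
            raise ParameterError("time steps must be positive")
        if self.dx_out < 0.1:
            raise ParameterError("dx_out below the 0.1 um native resolution")


@dataclass(frozen=True)
class SynapticInput:
    """One synaptic contact: where, when, and with which receptor pools."""

    position: float             # um from the synaptic end of the cable
    onset: float                # ms
    ampa: ReceptorParams = field(default_factory=lambda: AMPA_DEFAULT)
    nmda: ReceptorParams = field(default_factory=lambda: NMDA_DEFAULT)

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ParameterError("onset must be >= 0")
        if self.position < 0:
            raise ParameterError("position must be >= 0")


@dataclass(frozen=True)
class ClusterSpec:
    """Extrasynaptic NMDA receptor cluster collapsed to a point locus.

    The cluster shares the receptor kinetics of its synaptic counterpart
    but carries roughly seven times the conductance (about 80 receptors)
    and a much slower conductance decay, as expected for NR2B-rich
    extrasynaptic pools.
    """

    position: float = 400.0     # um
    onset: float = 0.5          # ms, ligand delivery time
    g_max_total: float = 4200.0  # pS
    tau_rise: float = 3.0       # ms
    tau_decay: float = 50.0     # ms
    n_receptors: int = 80

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ParameterError("require tau_decay > tau_rise > 0 for cluster")
        if self.g_max_total < 0:
            raise ParameterError("cluster g_max_total must be >= 0")
        # 80 receptors at ~50 pS each; total conductance must stay within
        # 10% of the per-receptor accounting unless explicitly zeroed.
        if self.g_max_total and self.n_receptors:
            per = 52.5  # pS per receptor implied by the 7x-synaptic total
            nominal = self.n_receptors * per
            if abs(self.g_max_total - nominal) > 0.10 * nominal:
                raise ParameterError(
                    f"cluster g_max_total {self.g_max_total} pS deviates more "
                    f"than 10% from n_receptors x single-channel conductance"
                )


#: Synaptic AMPA pool: ~20 receptors, opening probability 0.8; the 250 pS
#: figure is the attained peak total conductance (peak-normalized gate).
AMPA_DEFAULT = ReceptorParams(
    g_max_total=250.0, tau_rise=0.07, tau_decay=0.7,
    n_receptors=20, g_single=30.0, open_probability=0.8,
    normalize_peak=True,
)

#: Synaptic NMDA pool: ~12 channels of ~50 pS; 600 pS is the nominal scale
#: of the un-normalized gate, so the attained conductance stays well below
#: it even at full Mg unblock.
NMDA_DEFAULT = ReceptorParams(
    g_max_total=600.0, tau_rise=3.0, tau_decay=20.0,
    n_receptors=12, g_single=50.0, open_probability=1.0,
    normalize_peak=False,
)


@dataclass(frozen=True)
class ModelParams:
    """Bundle of every constant the simulator needs."""

    membrane: MembraneParams = field(default_factory=MembraneParams)
    cable: CableParams = field(default_factory=CableParams)
    mg: MgBlockParams = field(default_factory=MgBlockParams)
    ampa: ReceptorParams = field(default_factory=lambda: AMPA_DEFAULT)
    nmda: ReceptorParams = field(default_factory=lambda: NMDA_DEFAULT)


@dataclass(frozen=True)
class ProtocolSpec:
    """A named experiment: inputs, optional cluster, duration, constants."""

    name: str
    inputs: Tuple[SynapticInput, ...] = ()
    cluster: Optional[ClusterSpec] = None
    duration: float = 40.0      # ms
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        onsets = [s.onset for s in self.inputs]
        if self.cluster is not None:
            onsets.append(self.cluster.onset)
        if onsets and self.duration <= max(onsets) + 10.0:
            raise ProtocolError(
                f"duration {self.duration} ms must exceed the latest onset "
                f"({max(onsets)} ms) by more than 10 ms"
            )
        length = self.params.cable.length
        for s in self.inputs:
            if not 0 <= s.position <= length:
                raise ProtocolError(
                    f"input position {s.position} um outside cable [0, {length}]"
                )
        if self.cluster is not None and not 0 <= self.cluster.position <= length:
            raise ProtocolError(
                f"cluster position {self.cluster.position} um outside cable"
            )

    def with_(self, **kw) -> "ProtocolSpec":
        return replace(self, **kw)


def three_input_train(
    interval: float,
    spacing: float = 1.0,
    first_onset: float = 0.5,
    ampa: ReceptorParams = AMPA_DEFAULT,
    nmda: ReceptorParams = NMDA_DEFAULT,
) -> Tuple[SynapticInput, ...]:
    """Three sequential inputs at neighboring loci, a fixed time apart."""
    return tuple(
        SynapticInput(position=i * spacing, onset=first_onset + i * interval,
                      ampa=ampa, nmda=nmda)
        for i in range(3)
    )
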