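"""Passive propagation along an infinite cable via the analytic kernel.

The dendrite is treated as an infinite passive cable: a point current
injected at one locus spreads as a leaky Gaussian,

    K(x, t) = A * sqrt(tau_m / t) * exp(-x^2 tau_m / (4 lambda^2 t))
                * exp(-t / tau_m),

the voltage response per unit injected charge (mV per pA*ms).  The
amplitude ``A = r_lambda / (tau_m * sqrt(pi))`` is calibrated so that a
sustained current ``i`` produces the steady-state profile
``i * r_lambda * exp(-|x| / lambda)``: ``r_lambda`` plays the role of the
cable's input resistance, and the familiar exponential space-constant
attenuation is recovered as the time integral of the kernel.

Discrete convolution uses bin-averaged kernel weights obtained from the
closed-form time integral of K (an erf/erfcx expression), which integrates
the 1/sqrt(t) onset exactly for piecewise-constant currents and gives
clean convergence when the time step is refined.  No boundaries are
modeled: charge spreads symmetrically and no sealed-end reflections occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from scipy.special import erf, erfcx

from .params import CableParams, ProtocolError

__all__ = [
    "cable_kernel",
    "cable_kernel_integral",
    "discrete_kernel",
    "propagate_current",
    "superpose",
    "VoltageField",
]


def cable_kernel(x_offset: float, t_elapsed, cable: CableParams):
    """Impulse response of the infinite cable, mV per pA*ms of charge.

    Even in ``x_offset``; singular like 1/sqrt(t) at the origin, hence
    defined for ``t_elapsed > 0`` only.
    """
    t = np.asarray(t_elapsed, dtype=float)
    if np.any(t <= 0):
        raise ValueError("cable_kernel requires t_elapsed > 0")
    tau = cable.tau_m
    lam = cable.lambda_m
    amp = cable.r_lambda / (tau * np.sqrt(np.pi))
    out = (
        amp
        * np.sqrt(tau / t)
        * np.exp(-(x_offset * x_offset * tau) / (4.0 * lam * lam * t))
        * np.exp(-t / tau)
    )
    if out.ndim == 0:
        return float(out)
    return out


def cable_kernel_integral(x_offset: float, t_elapsed, cable: CableParams):
    """Closed form of ``int_0^t K(x, s) ds`` (mV per pA of sustained current).

    With ``a = |x| / (2 lambda)`` and ``u = sqrt(t / tau)``:

        F = (r/2) * [ e^{-2a} (1 + erf(u - a/u))
                      - erfcx(u + a/u) e^{-(u^2 + a^2/u^2)} ]

    which tends to ``r * exp(-|x|/lambda)`` as t -> inf, the steady-state
    cable attenuation.
    """
    t = np.asarray(t_elapsed, dtype=float)
    tau = cable.tau_m
    a = abs(x_offset) / (2.0 * cable.lambda_m)
    r = cable.r_lambda
    out = np.zeros_like(t)
    pos = t > 0
    u = np.sqrt(t[pos] / tau)
    if a == 0.0:
        out[pos] = r * erf(u)
    else:
        out[pos] = 0.5 * r * (
            np.exp(-2.0 * a) * (1.0 + erf(u - a / u))
            - erfcx(u + a / u) * np.exp(-(u * u + (a * a) / (u * u)))
        )
    if out.ndim == 0:
        return float(out)
    return out


def discrete_kernel(x_offset: float, n_steps: int, cable: CableParams) -> np.ndarray:
    """Bin-averaged kernel weights for discrete causal convolution.

    ``k[m] = (F(m dt) - F((m-1) dt)) / dt`` for m >= 1 and ``k[0] = 0``,
    so that ``sum_m i[t-m] k[m] dt`` integrates the response to a
    piecewise-constant current exactly; the lag-0 weight is zero, keeping
    every coupling strictly causal (previous-step currents only).
    """
    dt = cable.dt
    edges = cable_kernel_integral(x_offset, np.arange(n_steps + 1) * dt, cable)
    k = np.zeros(n_steps)
    k[1:] = np.diff(edges)[1:] / dt
    return k


@dataclass
class VoltageField:
    """Membrane potential on a positions x times grid.

    ``values[i, j]`` is the potential (mV) at ``positions[i]`` um and
    ``times[j]`` ms; x = 0 is the synaptic end and x = length the far
    ("somatic") edge.  ``meta`` carries engine diagnostics such as
    compartment traces.
    """

    positions: np.ndarray       # um
    times: np.ndarray           # ms
    values: np.ndarray          # mV, shape (n_positions, n_times)
    v_rest: float = -65.0
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.positions.size, self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.positions.size}, {self.times.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voltage field contains non-finite values")

    def trace_at(self, position: float) -> np.ndarray:
        """Voltage time series at the grid position nearest ``position``."""
        idx = int(np.argmin(np.abs(self.positions - position)))
        return self.values[idx]

    def deviation(self) -> np.ndarray:
        return self.values - self.v_rest


def propagate_current(
    source_position: float,
    i_a: np.ndarray,
    cable: CableParams,
    positions: np.ndarray | None = None,
) -> VoltageField:
    """Voltage deviation field produced by one injected point current.

    ``i_a`` is the axial current time series (pA, positive depolarizing)
    on the simulation clock.  The current spreads symmetrically — half of
    the injected charge travels toward each side of the injection locus —
    which the even, charge-calibrated kernel already encodes; the
    contribution at every position is the causal convolution of ``i_a``
    with the discrete kernel at the corresponding offset.  Returned values
    are deviations from rest (mV), zero before the first nonzero sample.
    """
    if not 0.0 <= source_position <= cable.length:
        raise ProtocolError(
            f"source position {source_position} um outside cable "
            f"[0, {cable.length}]"
        )
    i_a = np.asarray(i_a, dtype=float)
    n = i_a.size
    if positions is None:
        positions = np.arange(0.0, cable.length + 0.5 * cable.dx_out, cable.dx_out)
    positions = np.asarray(positions, dtype=float)
    spec = np.fft.rfft(i_a, 2 * n)
    nz = np.nonzero(i_a)[0]
    first = int(nz[0]) if nz.size else n - 1
    dev = np.empty((positions.size, n))
    for i, x in enumerate(positions):
        k = discrete_kernel(abs(x - source_position), n, cable)
        dev[i] = np.fft.irfft(spec * np.fft.rfft(k, 2 * n), 2 * n)[:n] * cable.dt
        dev[i, :first + 1] = 0.0            # exact causality despite FFT roundoff
    times = np.arange(n) * cable.dt
    return VoltageField(positions=positions, times=times, values=dev, v_rest=0.0)


def superpose(contributions: Sequence[VoltageField], v_rest: float = -65.0,
              grid: tuple | None = None) -> VoltageField:
    """Pointwise sum of deviation fields plus the resting potential.

    All contributions must share one grid; an empty list yields a uniform
    resting field on ``grid = (positions, times)``.
    """
    if not contributions:
        if grid is None:
            raise ValueError("superpose of empty list needs an explicit grid")
        positions, times = grid
        values = np.full((len(positions), len(times)), v_rest, dtype=float)
        return VoltageField(positions=positions, times=times, values=values,
                            v_rest=v_rest)
    first = contributions[0]
    total = np.zeros_like(first.values)
    for c in contributions:
        if (c.values.shape != first.values.shape
                or not np.array_equal(c.positions, first.positions)
                or not np.array_equal(c.times, first.times)):
            raise ValueError("superpose requires identical grids")
        total += c.values
    return VoltageField(
        positions=first.positions.copy(), times=first.times.copy(),
        values=total + v_rest, v_rest=v_rest,
    )
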