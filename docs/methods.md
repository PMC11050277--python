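# Methods

## Scope and intent

`dendramp` is a minimal, fully deterministic model of how a cluster of
extrasynaptic NMDA receptors (exNMDA) on a dendritic shaft can amplify
synaptic signals traveling toward the soma.  It couples three elements:
conductance-based synaptic compartments, an analytic passive cable, and a
point-cluster of slow NMDA receptors.  It deliberately excludes active
dendritic Na⁺/Ca²⁺/K⁺ conductances, action-potential generation, receptor
desensitization, glutamate diffusion, Ca²⁺ signaling and plasticity, and
dendritic tapering or branching: the question it addresses is purely
whether, where, and when a ligand-and-voltage-gated point conductance can
boost a passively propagating depolarization.

## Units

Conductance pS, voltage mV, current pA, time ms, distance µm, resistance
GΩ.  These close under Ohm's law (pS × mV / 1000 = pA) and make
`r_m · g` dimensionless (GΩ × pS × 10⁻³).

## Receptor kinetics

Ligand gating of every receptor pool follows the difference of
exponentials `w(t) = e^(−t/τ_d) − e^(−t/τ_r)` for `t > 0`, zero at or
before ligand delivery.  Its maximum sits at
`t* = (τ_r τ_d / (τ_d − τ_r)) · ln(τ_d/τ_r)`.

Two scaling conventions coexist deliberately:

* **AMPA** is peak-normalized: the quoted 250 pS *is* the attained
  maximum total conductance (≈20 receptors × 15–20 pS × opening
  probability 0.8).  This makes the peak AMPA current from rest
  250 pS × 65 mV ≈ 16 pA.
* **NMDA** (synaptic and extrasynaptic) is *not* normalized: 600 pS (and
  7 × 600 = 4200 pS for the cluster) is the nominal scale of the gate,
  so even at full Mg unblock the attained conductance stays well below
  it (the raw waveform maximum for 3/20 ms kinetics is ≈ 0.61).  This
  matches the physiological reading of a "total maximum conductance" as
  the all-channels-open bound that gating never quite reaches.

The Mg²⁺ block uses the Jahr–Stevens equilibrium form
`δ(V) = K_eq / (K_eq + [Mg]ₑₓ · e^(−c·V))` with `K_eq = 3.6 mM`,
`[Mg]ₑₓ = 1.2 mM`, `c = 0.062 /mV`: δ(0) = 0.75, δ(−65) ≈ 0.051,
strictly increasing and bounded in (0, 1).  The sign of the exponent is
fixed by the requirement that depolarization relieves the block.

## Synaptic compartment

Each synapse is a separate high-impedance domain: leak 20 pS to
E_L = −65 mV, r_m = 50 GΩ (= 1/g_leak), resting τ_m = 15 ms, synaptic
reversal 0 mV.  The explicit update at each 10 µs step relaxes the
voltage exponentially toward the conductance-weighted steady state

    V∞ = (g_leak·E_L + g_syn·V_eq) / (g_leak + g_syn)

with the dynamic time constant `τ(t) = τ_m / (1 + r_m·g_syn(t))`; open
synaptic conductance therefore both depolarizes and accelerates the
membrane.  A hard ceiling keeps the voltage strictly below 0 mV.

The NMDA gate is driven by the compartment's own previous-step voltage.
Consequently the AMPA transient regeneratively recruits NMDA
conductance, and a single event settles into an NMDA-sustained plateau
near the steady state of the leak/NMDA divider (≈ −5 mV) that decays
over tens of ms as the ligand gate closes.  This is the model's local
expression of the well-known NMDA plateau-potential mechanism, and it is
a direct consequence of the self-consistent RC dynamics: a sustained
potential of −5 mV requires ≈ 240 pS of open conductance, which only the
NMDA pool can supply once AMPA has decayed.

When several sources are active, each compartment "rides" on its
baseline: the cable-propagated potential produced at its position by all
*other* sources one step earlier replaces E_L as the relaxation floor,
so the pre-onset voltage tracks the baseline exactly and spatiotemporal
summation across neighboring inputs emerges naturally.

The current exported to the cable is the Ohmic driving-force current of
the compartment, `i_syn = (g_AMPA + g_NMDA_eff) · (V_eq − V)/1000`,
reported positive-depolarizing.

## Cable propagation

The shaft is an infinite passive cable with space constant λ = 400 µm,
static τ_m = 15 ms (the dynamic constant belongs to the synaptic domain
only) and input-resistance scale r_λ = 1.85 GΩ.  The impulse response to
a unit charge at offset x is

    K(x,t) = r_λ/(τ_m√π) · √(τ_m/t) · exp(−x²τ_m/(4λ²t)) · exp(−t/τ_m),

calibrated so that a sustained current i yields the steady profile
`i · r_λ · e^(−|x|/λ)` — r_λ is the cable's input resistance and the
classical space-constant attenuation is recovered exactly in the time
integral.  Injected charge spreads symmetrically to both sides; no
boundaries or reflections are modeled.

Discrete propagation convolves each current with *bin-averaged* kernel
weights `k_m = (F(m·Δt) − F((m−1)·Δt))/Δt`, where F is the closed-form
time integral of K (an erf/erfcx expression).  This integrates the
1/√t onset exactly for piecewise-constant currents: halving the time
step changes far-edge peaks by < 0.01%.  The lag-0 weight is zero, so
every field a source sees is built from strictly previous-step currents
and the explicit coupling has no implicit solves.  Contributions from
all sources superpose linearly; the resting potential is added last.

## exNMDA cluster

The cluster is 80 receptors collapsed to one locus (default 400 µm from
the synaptic end), with the synaptic NMDA kinetics except for a slower
decay (default 50 ms; scanned 10–100 ms) and total scale 4200 pS.
Ligand delivery at its onset opens the same dual-exponential gate; no
explicit glutamate concentration variable is modeled.

Its Mg-unblock voltage is the shaft potential at its position produced
by the *synaptic* sources (plus rest) at the previous step — the
cluster's own injected current does not feed back into its gate.  This
choice encodes the cluster's role as an amplifier of arriving signals:
with self-feedback included, a 4200 pS point conductance on a 1.85 GΩ
cable is supercritical and ignites regeneratively with no synaptic
input at all (far-edge responses an order of magnitude above the
cluster-only response reported here), which is not the phenomenon under
study.  Setting the cluster conductance to zero reproduces the passive
simulation bit-exactly.

## Protocols, scans, and metrics

Preset protocols cover: a single input (fig1a), cluster only (fig1b),
their co-activation (fig1c), a three-input train at 1.3 ms intervals
without/with the cluster (fig2a/fig2b), a cluster-leads latency variant
(fig3), a dense 0.3 ms train (fig4, fig6), 100 µm spatial spread (fig5),
and a slow-decay variant (fig7).  The first onset is at 0.5 ms; the
default window is 40 ms, which contains every protocol's far-edge peak
except the 100 ms-decay tail, and the native grid is 10 µs × 0.1 µm with
a default export grid of 50 µs × 1 µm.  Scan utilities vary latency
(3–9 ms, either ordering, with an `offset = ∞` baseline row), interval
(0.3/1.3/3 ms), spacing (1 vs 100 µm), cluster position (200–700 µm),
and cluster decay constant (10–100 ms), each row an independent run.
The far-edge summary reports the peak deviation from rest and the time
of the earliest maximum, measured on the native time grid.

## Behavior of the implementation

Within this charge-conserving model the single-event magnitudes are:
peak AMPA current ≈ 14.7 pA (the compartment has depolarized slightly by
the time the conductance peaks, so the 16.25 pA bound is not quite
attained), local plateau ≈ −5 mV, effective NMDA conductance up to
≈ 250 pS during the plateau, far-edge deviation ≈ 0.17 mV.  The
cluster-only protocol delivers ≈ 3.2 mV to the far edge, peaking late
(≈ 34 ms) because the cable integrates the slowly decaying cluster
current over its 15 ms memory; co-activation adds a supra-additive
≈ 0.1 mV.  Because a single EPSP is bounded to ≲ 0.2 mV at 1000 µm, its
wave at 400 µm is ≲ 0.8 mV and shifts the cluster's unblock fraction by
only a few percent: amplification in this regime is real but modest, the
far-edge response is dominated by the cluster's intrinsic drive, and the
response grows monotonically as the cluster moves toward the readout
edge.  Timing scans shift the far-edge peak by fractions of a ms.

## Known limitations

* The cable is linear and charge-conserving; strong distal seeding of
  the cluster by small synaptic events (factors of 2–4 at 400–600 µm)
  cannot arise, so the amplifier operates in a near-linear regime.
* One cluster only; the engine accepts the configuration but no
  multi-cluster interactions have been characterized.
* Constant dendritic diameter; no spine-neck resistance; one-way
  compartment → cable coupling (apart from the baseline feedback).
* The synaptic compartment's plateau assumes NMDA gating by its own
  local voltage; gating by the shaft potential instead would suppress
  the plateau and roughly halve the injected charge.
* Validated for up to four synaptic inputs (more produce a warning).
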