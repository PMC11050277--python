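"""A single glutamatergic synaptic event and its passive attenuation.

Builds one default synaptic input at the origin of the 1 mm dendrite,
integrates the local compartment, and measures how much of the signal
survives passive cable propagation to the far ("somatic") edge.
"""

import numpy as np

import dendramp as dd

event = dd.simulate_synaptic_event(
    dd.SynapticInput(position=0.0, onset=0.5), None,
    dd.MembraneParams(), dt=0.01, duration=40.0)

print(f"peak AMPA current:          {event.i_ampa.max():6.2f} pA")
print(f"peak total synaptic current:{event.i_syn.max():6.2f} pA")
print(f"peak NMDA conductance:      {event.g_nmda_eff.max():6.1f} pS")
print(f"local EPSP peak:            {event.v_local.max():6.2f} mV (from -65)")

field = dd.run_protocol(dd.get_preset("fig1a"), positions=[1000.0])
t = field.meta["times_full"]
dev = field.meta["soma_trace_full"] + 65.0
print(f"far-edge peak deviation:    {dev.max():6.3f} mV at {t[np.argmax(dev)]:.1f} ms")
print()
print("The fast AMPA conductance drives the tiny postsynaptic domain close")
print("to the glutamatergic reversal (the ~-5 mV plateau, sustained by")
print("regenerative NMDA recruitment), yet after 1000 um of passive cable")
print("the deviation reaching the far edge is only a fraction of a mV.")
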