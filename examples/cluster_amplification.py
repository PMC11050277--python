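"""Co-activating an extrasynaptic NMDA cluster amplifies the far-edge signal.

Compares three protocols: a single EPSP alone, the 80-receptor cluster at
400 um alone, and their co-activation, then reports the supra-additive
amplification gain at the far edge.
"""

import numpy as np

import dendramp as dd


def far_peak(name):
    field = dd.run_protocol(dd.get_preset(name), positions=[1000.0])
    t = field.meta["times_full"]
    dev = field.meta["soma_trace_full"] + 65.0
    return field, dev.max(), t[np.argmax(dev)]


f_epsp, a_epsp, t_epsp = far_peak("fig1a")
f_clu, a_clu, t_clu = far_peak("fig1b")
f_both, a_both, t_both = far_peak("fig1c")

print(f"EPSP only:      {a_epsp:5.3f} mV at {t_epsp:5.1f} ms")
print(f"cluster only:   {a_clu:5.3f} mV at {t_clu:5.1f} ms")
print(f"co-activated:   {a_both:5.3f} mV at {t_both:5.1f} ms")
print(f"gain (with/without cluster): {dd.amplification_gain(f_both, f_epsp):.1f}x")
extra = a_both - (a_epsp + a_clu)
print(f"supra-additivity: combined exceeds the sum of parts by {extra:.3f} mV")
print()
print("The synaptic wave depolarizes the shaft at the cluster, relieving a")
print("little more of its Mg block, so the combined response at the far")
print("edge is larger than the two protocols added together.")
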