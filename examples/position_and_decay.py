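"""Cluster placement and subunit kinetics as amplification parameters.

Moves the cluster along the shaft and varies its conductance decay
constant (the NR2B-like slow kinetics), reporting the far-edge peak for
each configuration.
"""

import dendramp as dd

print("cluster position scan (dense three-input train):")
pos = dd.scan_cluster_position(dd.get_preset("fig6"),
                               [200.0, 300.0, 400.0, 700.0])
print(pos.to_string(index=False))
print()

print("decay-constant scan (1.3 ms train, cluster at 400 um):")
dec = dd.scan_decay_constant(dd.get_preset("fig2b"),
                             [10.0, 20.0, 50.0, 100.0])
print(dec.to_string(index=False))
d = dict(zip(dec["tau_decay"], dec["peak_amplitude"]))
print(f"gain from 20 -> 50 ms:  {d[50.0]-d[20.0]:.2f} mV")
print(f"gain from 50 -> 100 ms: {d[100.0]-d[50.0]:.2f} mV")
print()
print("Slower conductance decay injects charge for longer and boosts the")
print("far-edge response, with diminishing returns beyond ~50 ms; within")
print("a charge-conserving cable, placements closer to the readout edge")
print("lose less to attenuation.")
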