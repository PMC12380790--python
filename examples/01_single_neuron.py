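"""Single Izhikevich neuron: subthreshold rest vs tonic spiking.

Builds one regular-spiking neuron, integrates it for 1 s at three bias
currents, and prints the spike count.  Below rheobase (~4 in model current
units) the neuron is silent — the network's populations are all biased in
this subthreshold regime and fire only when noise or synaptic input pushes
them over threshold.
"""

import numpy as np

import tcmsim as t
from tcmsim.neurons import NeuronState

arch = t.ARCHETYPES["RS"]
params, _ = t.make_population(1, arch, heterogeneity_scale=0.0,
                              excitatory=True, bias_current=0.0,
                              rng=np.random.default_rng(0))

for bias in (0.0, 3.5, 10.0):
    state = NeuronState(v=np.array([-65.0]), u=np.array([-13.0]))
    rng = np.random.default_rng(0)
    spikes = 0
    for step in range(12_000):                   # 1.2 s at dt = 0.1 ms
        mask, _ = t.step_neurons(state, np.array([bias]), params, 0.1, rng)
        if step >= 2_000:                        # drop the onset transient
            spikes += int(mask[0])
    regime = "subthreshold" if spikes == 0 else "tonic spiking"
    print(f"bias {bias:5.1f} -> {spikes:3d} spikes/s   ({regime})")
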