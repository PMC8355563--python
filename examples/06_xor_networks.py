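"""Non-linear classification with three multi-layer spiking networks.

Network 1: frozen random-projection layer (L1 distances to random
centroids) + trained supervised layer.  Network 2: a trainable coupled
hidden layer whose rectified mean potentials feed the supervised layer.
Network 3: the label is also injected into the hidden layer, letting
both layers exploit feature-label structure for extra sparsity.

Decision boundaries are majority votes over five differently seeded
runs, as the per-seed boundaries of the spiking networks vary.
"""

from gtnn import experiments as E

r = E.xor_multilayer(seed=0)
names = {1: "Network 1 (random projection)",
         2: "Network 2 (layer-wise training)",
         3: "Network 3 (label-informed layers)"}
for kind in (1, 2, 3):
    res = r[kind]
    print(f"{names[kind]:<34} vote accuracy {res['vote_accuracy']:.0%}, "
          f"rho_train = {res['rho_train_mean']:.3f}")
print("All three solve XOR; progressively more trainable structure buys "
      "progressively fewer spikes per decision.")
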