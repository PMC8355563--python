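"""Unsupervised domain description and anomaly detection.

Template-projection training drives Q t toward the training cloud, so the
network spikes least for points it has seen.  The firing-rate threshold
(a quantile of the training rates) turns that into a one-class decision
rule; raising the rejection fraction shrinks the accepted region.
"""

import numpy as np

from gtnn import DomainDescriptor
from gtnn.datasets import gen_cluster

cluster = gen_cluster([0.5, 0.6], spread=0.08, n=20, seed=7)
g = np.linspace(0, 1, 25)
grid = np.stack(np.meshgrid(g, g), -1).reshape(-1, 2)

for rf in (0.0, 0.25, 0.5):
    dd = DomainDescriptor(2, seed=3).fit(cluster.X, reject_frac=rf)
    labels, _ = dd.predict(cluster.X)
    glabels, _ = dd.predict(grid)
    print(f"reject {int(rf*100):>2}%: {np.mean(labels=='member'):.0%} of training "
          f"points accepted, member region covers {np.sum(glabels=='member')}"
          f"/625 grid cells (threshold {dd.threshold:.4f})")

dd0 = DomainDescriptor(2, seed=3).fit(cluster.X, reject_frac=0.0)
lab, r = dd0.predict(np.array([[0.05, 0.05]]))
print(f"far point (0.05,0.05): {lab[0]} (rho={r[0]:.3f} vs threshold "
      f"{dd0.threshold:.3f}) — unfamiliar inputs make the network fire more")
print("learned projection Qt =", np.round(dd0.centroid(), 3),
      "~ cluster median", np.round(np.median(cluster.X, 0), 3))
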