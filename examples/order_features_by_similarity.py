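"""Pre-order features with a precomputed similarity matrix.

The Markov state prior assumes functionally similar features sit next to
each other.  Given any symmetric feature-feature similarity (in practice a
GO semantic similarity computed upstream), greedy nearest-neighbour
seriation produces the column order the model consumes.  Here a two-block
similarity is shuffled and the seriation makes each block contiguous again.
"""

import numpy as np

from hmmbiclust import ExpressionMatrix, order_features

rng = np.random.default_rng(0)
p = 20
block = np.array([0] * 10 + [1] * 10)
perm = rng.permutation(p)
sim = 0.05 * rng.random((p, p))
sim = (sim + sim.T) / 2
sim += (block[perm][:, None] == block[perm][None, :]) * 1.0
np.fill_diagonal(sim, 2.0)

M = ExpressionMatrix(rng.normal(size=(5, p)))
ordered = order_features(M, sim)

labels = block[perm[ordered.feature_order]]
print("block labels in the shuffled input :", block[perm].tolist())
print("block labels after seriation       :", labels.tolist())
print("contiguous blocks:", (np.diff(labels) != 0).sum() == 1)
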