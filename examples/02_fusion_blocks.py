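"""The three fusion operators on small tensors, with their key identities.

AFF produces complementary per-position gates over a local and a global
feature map; HMU is a residual refinement block; HMUFF exchanges
information between two spatial scales through a stochastic
negative-similarity matrix.
"""

import numpy as np

from lgnet.fusion import (AFF, HMU, HMUFF, HMUConfig, difference_matrix,
                          flatten_spatial)
from lgnet.tensor import Tensor

rng = np.random.default_rng(0)

# --- AFF: gates sum to one, output is a pointwise convex combination
aff = AFF(channels=3, rng=np.random.default_rng(1), dtype=np.float64)
x_local = Tensor(rng.standard_normal((3, 4, 4)))
x_global = Tensor(rng.standard_normal((3, 4, 4)))
w = aff.weights(x_local.reshape(1, 3, 4, 4), x_global.reshape(1, 3, 4, 4))
print("AFF gate sums (every spatial position):",
      np.unique(np.round(w.data.sum(axis=1), 12)))

# --- difference matrix: stochastic along the normalised axis
fh1 = flatten_spatial(Tensor(rng.standard_normal((2, 2, 2))))
fh2 = flatten_spatial(Tensor(rng.standard_normal((2, 1, 3))))
md = difference_matrix(fh1, fh2, "rows")
print("difference matrix row sums:", np.round(md.values.data.sum(axis=-1), 12))

# --- HMU: zeroing the output projection reduces the block to its residual
hmu = HMU(channels=6, cfg=HMUConfig(groups=2),
          rng=np.random.default_rng(2), dtype=np.float64)
hmu.zero_output_branch()
x = Tensor(rng.standard_normal((1, 6, 3, 3)))
print("HMU with zeroed projection is the identity:",
      bool(np.allclose(hmu(x).data, x.data)))

# --- HMUFF: shapes preserved across unequal spatial scales
hm = HMUFF(channels=6, cfg=HMUConfig(groups=2),
           rng=np.random.default_rng(3), dtype=np.float64)
x1 = Tensor(rng.standard_normal((1, 6, 4, 4)))
x2 = Tensor(rng.standard_normal((1, 6, 2, 2)))
x12, x21 = hm(x1, x2)
print("HMUFF output shapes:", x12.shape, x21.shape,
      "(match the inputs, residually fused across scales)")
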