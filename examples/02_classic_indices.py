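"""Classic rank-difference baselines on the toy census.

The Holling index HI = ((M[k+1] - M[k-1]) / M[k])^gamma and the
Siemann-Brown index SB = log10(M[r+1] / M[r]) are the historical
difference indices; both are descriptive (no significance criterion).
SB is exactly the observed log10 rank gap the resampling test scores.
"""

from importlib.resources import files

import numpy as np

from ddetect import holling_index, read_census, siemann_brown_index

census = read_census(files("ddetect.data") / "toy_two_cluster.csv")
hi = holling_index(census, gamma=1.3)   # 1.3: conventional bird transform
sb = siemann_brown_index(census)

k = int(np.argmax(sb.values))
print(f"largest SB value {sb.values[k]:.3f} at rank {k + 1} "
      f"({census.labels[k]} -> {census.labels[k + 1]})")
print(f"largest HI value {hi.values.max():.3f} (gamma = {hi.gamma})")
# Both indices peak at the between-cluster jump; unlike the resampling
# test they give no probability scale for calling it a discontinuity.
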