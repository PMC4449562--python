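"""Encode a single peptide into anchoring-pair composition features.

Every ordered residue pair separated by i intervening positions (i = 0..I)
is a feature X.{i}Y weighted k/(l-i-1): occurrences over the number of
length-(i+2) windows.  The 7-mer below has 21 distinct pairs at I=5, and
each gap stratum sums to 1.
"""

import numpy as np

import apcpred as ap

config = ap.EncodingConfig(max_gap=5)
space = ap.enumerate_features(config)
vector = ap.encode("QAGTSLS", config)

print(f"feature space: {len(space)} descriptors (400 * (I+1) at I={config.max_gap})")
nonzero = np.flatnonzero(vector)
print(f"nonzero features of QAGTSLS: {len(nonzero)}")
for j in nonzero:
    print(f"  {space.pairs[j].name:8s} = {vector[j]:.4f}")
for i in range(config.max_gap + 1):
    print(f"gap-{i} stratum sum: {vector[i * 400:(i + 1) * 400].sum():.1f}")
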