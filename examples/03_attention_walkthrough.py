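"""Walk through the two attention operators on a toy feature map.

SE squeezes each channel to its spatial mean, passes the pooled vector
through a bottleneck MLP with a sigmoid, and rescales the channels; NAM
normalizes the map, derives per-element sigmoid weights from a 1x1
convolution of the normalized features, multiplies them into the input and
reconstructs.  The printed weights show SE suppressing the low-variance
channel and every NAM weight lying strictly inside (0, 1).
"""

import numpy as np

from mnvit.attention import (ExciteParams, FeatureMap, nam_attention,
                             se_excite, se_squeeze)

rng = np.random.default_rng(0)
x = FeatureMap(np.stack([rng.normal(2.0, 1.0, (4, 4)),   # informative channel
                         rng.normal(0.0, 0.05, (4, 4)),  # near-constant channel
                         rng.normal(-1.0, 0.5, (4, 4))]))

z = se_squeeze(x)
print("squeeze (per-channel means):", np.round(z.z, 3))
p = ExciteParams.random(channels=3, reduction=1, rng=rng, scale=0.8)
s = se_excite(z, p)
print("excitation weights:        ", np.round(s.s, 3))

out, state = nam_attention(
    x, norm_mean=z.z, norm_std=x.values.std(axis=(1, 2)),
    f_att_weight=rng.normal(0, 0.5, (3, 3)),
    f_recon_weight=np.eye(3))
print(f"NAM attention weights in ({state.a.min():.3f}, {state.a.max():.3f})")
print("reconstructed map shape:   ", out.values.shape)
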