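"""Inspect the channel and spatial attention gates of one block.

Feeds a random feature map through freshly initialized attention parameters
and prints the gates: per-channel weights in (0,1) from the shared-MLP
channel module, and the range of the 7x7-fused spatial map. Also checks the
zero-weight closed form (every gate exactly 0.5).
"""
import numpy as np

from sswan import (
    ChannelAttentionParams,
    SpatialAttentionParams,
    channel_descriptor,
    spatial_descriptor,
    ssab_block,
)
from sswan.attention import identity_conv_kernel

rng = np.random.default_rng(0)
feat = rng.normal(size=(16, 16, 8))

cp = ChannelAttentionParams.initialize(width=8, reduction=4, rng=rng)
sp = SpatialAttentionParams.initialize(rng)

ch_gate = channel_descriptor(feat, cp)
sp_gate = spatial_descriptor(feat, sp)
print("channel gate :", np.array2string(ch_gate, precision=3))
print(f"spatial gate : min {sp_gate.min():.3f}, max {sp_gate.max():.3f} "
      f"over {sp_gate.shape} positions")

zero_cp = ChannelAttentionParams(w1=np.zeros((8, 2)), b1=np.zeros(2),
                                 w2=np.zeros((2, 8)), b2=np.zeros(8))
zero_sp = SpatialAttentionParams(kernel=np.zeros((7, 7, 2, 1)))
out = ssab_block(feat, identity_conv_kernel(8), np.zeros(8), zero_cp, zero_sp)
print(f"zero-attention block output == 1.25 * input: "
      f"{np.allclose(out, 1.25 * feat)}")
# With all attention weights zero both sigmoids sit at 0.5, so the block
# body scales its conv output by 0.25 before the skip adds the input back.
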