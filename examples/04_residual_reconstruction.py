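"""Show global residual learning: baseline, residual target, reconstruction.

The network predicts the wavelet coefficients of (image - bicubic baseline);
adding the synthesized residual back onto the baseline recovers the image.
This script does the ideal-case arithmetic without a network, then shows how
far an untrained network is from that fixed point.
"""
import numpy as np

from sswan import (
    NetworkConfig,
    PhantomConfig,
    SSWAN,
    degraded_baseline,
    generate_phantom,
    psnr,
    reconstruct,
    residual_target,
)

sample = generate_phantom(PhantomConfig(size=(64, 64), seed=2))
image = sample.image
baseline = degraded_baseline(image, factor=2)

print(f"baseline PSNR (what bicubic alone achieves) : "
      f"{psnr(baseline, image, peak=np.ptp(image)):.2f} dB")

target = residual_target(image, baseline)
ideal = reconstruct(target, baseline)
print(f"ideal residual reconstruction error         : "
      f"{np.abs(ideal - image).max():.2e}")

model = SSWAN(NetworkConfig(num_blocks=2, width=8, seed=0))
out = model.forward(image)
rec = out["recon"].data
print(f"untrained network reconstruction PSNR       : "
      f"{psnr(rec, out['norm'], peak=np.ptp(out['norm'])):.2f} dB")
# The ideal case is exact because the wavelet transform is invertible; an
# untrained network starts near the baseline and training moves its
# predicted coefficients toward the residual target.
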