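# sswan

A wavelet-domain attention network for semantic segmentation of 2D
brain-tumor MRI slices, built as an importable Python library with a thin
command-line interface. It is aimed at researchers who want a small,
fully-inspectable implementation of attention-gated residual learning in the
wavelet coefficient domain — one that trains on a desktop CPU against
synthetic phantoms, with every numerical component covered by independent
brute-force oracles.

## The method

A slice `F` of shape `(r, c)` is z-scored and reduced to a bicubic
degrade-upsample baseline `F_bic` (Keys kernel, factor 2). One level of an
orthonormal 2D discrete wavelet transform splits the baseline into four
half-resolution channels (LL, LH, HL, HH). The network operates entirely at
this half resolution:

```
I_0     = LeakyReLU( W_5x5 * DWT(F_bic) )                    shallow extraction
I_{f+1} = spa( chn( W_3x3 * I_f ) ) + I_f,   f = 0..T-1      attention blocks
I_cat   = [I_1, ..., I_T]                                    dense concatenation
I_c     = W_3x3 * LeakyReLU( W_3x3 * I_cat )                 4-channel fusion
F_hat   = IDWT(I_c) + F_bic                                  global residual
```

`chn` is channel attention — global max- and average-pooled channel vectors
through one shared bottleneck MLP (hidden width `w/h`), summed, sigmoid —
and `spa` is spatial attention — channel-pooled max/avg maps fused by a 7x7
convolution and a sigmoid. Both are multiplicative gates in (0, 1). A 1x1
convolution head on the fused features, bilinearly upsampled and
softmax-normalized, yields per-pixel class probabilities.

Training minimizes a weighted soft Dice loss

```
K = 1 - sum_l w_l * 2 <n_l, i_l> / (||n_l||^2 + ||i_l||^2 + eps)
```

plus a self-supervised reconstruction term `MSE(F_hat, F)` whose target
needs no annotation, and optionally an L2 penalty. A lesion-weighted binary
Dice variant (ground-truth term weighted 3:1 in the denominator) penalizes
under-segmentation of the tumor more than over-segmentation. Evaluation
reports accuracy, precision, recall/sensitivity, specificity, per-class
Dice, MSE and PSNR.

Because annotated MRI cannot ship with a test suite, the package includes a
phantom generator: nested concentric ellipses (whole tumor ⊃ tumor core ⊃
enhancing tumor) on a low-frequency textured background with Gaussian
noise, deterministic per seed.

## Worked example

```python
import numpy as np
from sswan import (NetworkConfig, PhantomConfig, SSWAN, TrainConfig,
                   generate_dataset, train, evaluate_dice)

phantoms = generate_dataset(8, PhantomConfig(size=(64, 64), noise_sigma=0.05,
                                             seed=0), base_seed=0)
model = SSWAN(NetworkConfig(num_blocks=2, width=8, reduction=4, seed=0))
history = train(model, phantoms, TrainConfig(epochs=40))
print(history[-1])
print("train dice:", evaluate_dice(model, phantoms))
```

prints (exactly reproducible — everything is seeded):

```
{'epoch': 39, 'loss': 0.2144..., 'mean_foreground_dice': 0.9500...}
train dice: 0.9511...
```

meaning the 2-block, width-8 network fits the 8 phantoms to a mean
foreground Dice overlap of ~0.95 within 40 epochs on one CPU. See
`examples/` for narrative scripts covering the wavelet round trip, the
attention gates, training + held-out evaluation, and residual
reconstruction; each prints its numbers with a line on what they mean.

The same pipeline is available from the shell:

```sh
sswan simulate --n 16 --size 64 --seed 0 --out data/
sswan train --data data/ --epochs 100 --seed 0 --checkpoint run/model.npz
sswan predict --checkpoint run/model.npz --input data/phantom0000_image.png --out pred.png
sswan evaluate --pred pred.png --truth data/phantom0000_labels.png --out metrics.json
```

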