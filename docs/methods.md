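# Methods

## Model

The network performs semantic segmentation of a single 2D slice by learning
in the wavelet coefficient domain. The design couples two ideas:

1. **Global residual learning over a bicubic baseline.** The input slice is
   z-scored and degraded by a bicubic downsample-upsample round trip
   (factor 2 by default). The network never has to reproduce the
   low-frequency bulk of the image — the baseline is added back at the
   output — only the residual detail the round trip destroyed, expressed as
   the four coefficients of a one-level 2D DWT. Because the transform is
   orthonormal and exactly invertible, a perfect coefficient prediction
   reconstructs the slice exactly; this is verified as an identity test
   rather than assumed.
2. **Attention-gated trunk at half resolution.** All convolutional work
   happens on the half-resolution 4-channel coefficient stack: a 5x5
   shallow conv to width `w`, then `T` attention blocks, each a 3x3 conv
   followed by a channel gate and a spatial gate with a local additive
   skip. The outputs of *all* blocks are concatenated (width `w*T`) before
   fusion, so every block receives gradient directly from the loss rather
   than only through its successors. Fusion is a 3x3 conv back to width `w`
   (leaky ReLU) and a 3x3 conv to the 4 predicted coefficient channels.

Leaky ReLU (negative slope 0.2 by default) is used throughout because
wavelet coefficients are signed; a one-sided ReLU would silence half of
every detail channel. The slope value is a free choice — any moderate
nonzero slope preserves the signed information — and is configurable.

The channel gate follows the squeeze-and-excite-with-two-pools pattern:
global max-pool and average-pool over space give two width-`w` vectors,
both pass through one *shared* two-layer MLP with bottleneck `w/h`
(reduction `h`, default 4), are summed and squashed by a sigmoid. Sharing
the MLP makes the gate symmetric in the two pooled statistics, which is
tested explicitly. The spatial gate pools along channels (max and mean),
stacks the two maps, and fuses them with a same-padded 7x7 convolution and
a sigmoid, giving one multiplier per position.

### Segmentation head

The trunk is purely reconstructive; class scores come from a deliberately
minimal head: a 1x1 convolution from the fused width-`w` features to `L`
channels at coefficient resolution, bilinear 2x upsampling (half-pixel
centers) back to slice resolution, and a per-pixel softmax. Keeping the
head at one 1x1 layer isolates the segmentation capacity in the attention
trunk, which is the component under study. Labels are obtained by argmax;
there is no threshold parameter.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `num_blocks` T | 8 (tests: 1–2) | attention blocks in the trunk |
| `width` w | 64 (tests: 8–16) | channels per block |
| `reduction` h | 4 | channel-MLP bottleneck ratio; hidden width w/h |
| `leaky_slope` | 0.2 | negative slope of every leaky ReLU |
| `downsample_factor` | 2 | bicubic degradation of the baseline |
| `wavelet` | haar | analysis/synthesis filter pair (orthonormal) |
| `noise_sigma` | 0.05 | phantom pixel noise (intensity units) |
| `lr` | 1e-3 | Adam step size |

The full-scale defaults (T=8, w=64) reflect the regime where the
architecture is intended to operate; all shipped tests and protocols use
the desk-scale settings noted above, chosen so a complete training run
takes about a minute on one CPU core.

## Training objective

Per sample the loss is

    L = dice_weight * K_dice + recon_weight * MSE(F_hat, F_norm) + lam * sum ||W||^2

with defaults (1.0, 1.0, 0.0). The joint form was a genuine design choice:
the method could plausibly be trained in two phases (reconstruction pretext,
then supervised Dice) or jointly. Joint training is the default because
(a) the reconstruction term is the only gradient path into the final
coefficient-fusion convolution, so a Dice-only objective provably leaves
that layer untrained — the test suite checks that one joint step delivers a
nonzero gradient to every parameter group; and (b) both phases are still
available by zeroing one weight. The Dice term uses uniform class weights
`w_l = 1/L` by default (configurable), with smoothing epsilon 1e-6 in the
denominator only, so empty-vs-empty classes are not silently scored
perfect. The lesion-weighted binary variant multiplies the ground-truth
denominator term by 3 and rescales the numerator (2 → 4) so a perfect
prediction still scores exactly 0.

Optimization is Adam (lr 1e-3, betas 0.9/0.999), one step per sample, fixed
sample order, no shuffling — determinism given the model seed is part of
the contract and is tested bitwise. One epoch is one pass over the sample
list.

## Numerical choices

- **Wavelet boundary handling.** Analysis uses periodized convolution so
  coefficient arrays are exactly half-size and orthonormal filters conserve
  energy to rounding. Odd-sized inputs are symmetrically padded by one
  trailing row/column; the pad is recorded on the coefficient stack and
  cropped after synthesis. Channel order is (LL, LH, HL, HH) with the first
  letter naming the row-axis filter; LH therefore responds to vertical
  edges, HL to horizontal ones.
- **Bicubic resampling.** The Keys cubic-convolution kernel (a = -1/2) with
  half-pixel center alignment, border samples replicated, weights
  renormalized to sum to one per output position. This kernel is local, so
  constants are reproduced everywhere and linear ramps exactly in the
  interior — properties the tests rely on. Scale 1 returns the input
  unchanged by construction.
- **Differentiation.** All gradients come from a small reverse-mode
  autodiff module written for this package (`sswan.autodiff`): double
  precision, im2col + matmul convolutions, argmax-routed max-pool
  gradients (ties to the first index), and an inverse-DWT operation whose
  backward pass is the forward DWT (valid because the transform is
  orthonormal). Every operation is validated against central differences.
- **Degenerate inputs.** Non-finite images are rejected, never coerced.
  A zero-variance image z-scores with divisor 1. Metrics with zero
  denominators are reported as NaN, not 0, so pooled averages cannot be
  inflated. PSNR of identical images is +inf, and PSNR is +inf iff MSE is 0.
- **Bias terms** exist in every convolution and MLP layer and initialize to
  zero; weights are Kaiming-uniform from a seeded generator. Biases are
  excluded from the L2 penalty.
- **Metric conventions.** Default sensitivity/specificity follow the
  standard one-vs-rest definitions TP/(TP+FN) and TN/(TN+FP). An alternative
  printed convention that divides both by (TP+FP) circulates in parts of the
  segmentation literature; it is reproducible via `paper_exact=True` /
  `--paper-exact-metrics` for comparison, never by default.

## What the phantoms emulate — and what they do not

The generator draws concentric random ellipses (center, semi-axes 12–28% of
the short side, rotation) for up to three nested tumor sub-regions on a
background of three low-frequency cosine gratings plus i.i.d. Gaussian
noise. Concentric construction makes the nesting invariant
(ET ⊆ TC ⊆ WT) hold by geometry, which the tests verify over 200 seeds.
Per-class mean intensities default to (0.2, 0.6, 0.8, 1.0).

Phantoms deliberately do **not** simulate MRI physics: no bias fields, no
multi-modal contrast relationships, no partial-volume effects, no
anatomical background. Passing the overfit and held-out protocols therefore
shows that the architecture, gradients, losses and metrics are correct and
that the method can learn intensity-plus-shape segmentation end-to-end; it
does not certify clinical-grade performance on real BraTS volumes, which
requires full-scale training on the real dataset.

## Protocol sizes

The shipped protocols are sized for a single CPU core: 16 training and 8
held-out phantoms at 64x64, a 2-block trunk at widths 8 and 16, 200 epochs.
These sizes are the package's fixed study conditions — they are what the
acceptance script re-runs — and scale upward by changing the configs, not
the code.

## Known limitations

- One 2D plane per call; multi-modal inputs must be handled as separate
  calls or user-level channel stacking. No 3D convolutions.
- Single-level wavelet decomposition only; no multi-level pyramids.
- The pure-NumPy training loop is fast at desk scale but not competitive
  with GPU frameworks at BraTS scale.
- NIfTI affines are passed through untouched; no resampling, registration
  or skull-stripping.
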