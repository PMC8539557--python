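# Methods

## Problem and model

The package performs single-image super-resolution (SISR) of grayscale
medical CT slices: given a low-resolution (LR) image, reconstruct a
high-resolution (HR) one at an integer scale factor s ∈ {2, 3, 4}.  LR
inputs are modeled as antialiased bicubic downsamples of HR ground
truth, the standard benchmark degradation for SR networks.

The network (IDMAN — information distillation and multi-scale attention
network) is a deep residual CNN operating at LR resolution:

    I_SR = H_rec( H_up( H_dfes( H_sfe(I_LR) ) ) )

- **Shallow feature extraction** H_sfe: one 3×3 convolution from the
  input channel to C feature channels.
- **Deep feature extraction structure (DFES)** H_dfes: G groups
  (IDMAG), each of B blocks (IDMAB), with a trailing 3×3 convolution
  and skip connection at both the group and trunk level, so every
  residual branch learns a correction.
- **IDMAB**: the block body refines features by *information
  distillation* — three steps, each splitting its input channels into a
  retained slice of d channels (kept through a 1×1 convolution) and a
  coarse remainder (3×3 convolution + identity + ReLU, passed to the
  next step); a final 3×3 convolution extracts d more channels from the
  last coarse slice; the four retained slices (4d channels) are
  concatenated and fused back to C channels by a 1×1 convolution.  The
  fused features pass through the attention module and are added to the
  block input.
- **Multi-scale attention block (MAB)**: the channel descriptor
  z = avgpool(X) (global average pooling to C×1×1) feeds parallel
  branches with kernel sizes k ∈ {3, 5}; each branch computes
  conv_k → 1×1 reduction C→C/r → ReLU → 1×1 expansion C/r→C → conv_k,
  the branch outputs are summed, squashed by a sigmoid, and used to
  rescale the channels of X.  With no branches configured the module
  degenerates to plain squeeze-and-excitation channel attention
  (1×1–ReLU–1×1–sigmoid).
- **Upsampling**: sub-pixel convolution — a 3×3 convolution to C·s²
  channels followed by pixel shuffling; ×4 is two chained ×2 stages.
- **Reconstruction**: one 3×3 convolution C → 1.  An optional
  weight-shared feedback refinement (``n_refine`` > 0) reapplies the
  same convolution to the input features plus the broadcast previous
  estimate; it adds no parameters and is off by default.
- **Weight normalization (WN)**: every convolution in the DFES trunk is
  reparameterized as w = g·v/‖v‖ per output channel, so ‖w‖ = |g|
  exactly; head/tail convolutions (shallow, upsampler, reconstruction)
  are left plain so ablations share an identical head and tail.

Training minimizes the mean absolute error (L1) between I_SR and I_HR
with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), learning rate
lr(t) = lr₀ · 0.5^⌊t/T⌋, on randomly augmented (8 dihedral variants,
equally likely) random LR patches with aligned HR patches.

## Implementation

The network stack is implemented directly in NumPy: stride-1
same-padded convolutions via im2col + matrix multiplication, explicit
backward passes for every layer (validated against finite differences),
Adam, and WN with exact gradient chaining to (v, g).  Layer caches are
stacks, so a module instance can be applied repeatedly in one forward
pass (weight sharing) provided backward calls mirror forward calls in
reverse.  Everything runs in float64 on CPU, which makes runs
bit-reproducible for a fixed seed.

## Parameters that matter

| parameter | meaning | default | why |
| --- | --- | --- | --- |
| s (`scale`) | SR factor | 2 | benchmark convention; {2,3,4} supported |
| G, B | groups × blocks | 10 × 20 | full-scale reference recipe |
| C (`width`) | feature channels | 64 | convention of the residual-attention SR lineage |
| d (`distill_channels`) | retained channels per step | 16 (= C/4) | makes the 4-slice concat exactly C; requires 3d < C |
| r (`reduction_ratio`) | attention bottleneck | 16 | squeeze-and-excitation convention; C must divide by r |
| branches | attention kernel sizes | (3, 5) | multi-scale gating; () = plain channel attention |
| lr₀, T | initial LR, halving period | 1e−4, 2e5 iters | full-scale recipe |
| batch, patch | batch size, LR patch side | 10, 48 px | full-scale recipe; patch is the LR side (HR side = 48 s) |

**Desk scale.**  Tests and `scripts/acceptance.py` use a tiny
configuration (G = 2, B = 2, C = 16, d = 4, r = 4, scale 2, ~98k
parameters) and a short recipe (`idman.experiments.DESK_TRAIN_CONFIG`:
lr₀ = 2e−3 halved every 500 iterations, 16-px LR patches, batch 10,
2000 iterations on 200 phantoms of 64×64).  The higher lr₀ and shorter
halving period are the standard Adam regime for a network this small
trained this briefly; the full-scale defaults remain on `TrainConfig`.
These problem sizes are the package's own desk-scale choices so that
every stage runs in minutes on one CPU core.

## Synthetic phantoms

The generator emulates the features of CT slices that matter to SR:
a smooth low-intensity background (blurred noise field, sigma
`background_smoothness` = 6 px), `n_ellipses` = 3 soft-edged elliptical
"organs" with well-separated mean attenuations (evenly spaced, shuffled
slots so histograms keep one mode per organ), one sharp-edged
bone-like elliptical ring near peak intensity, mild intra-organ
texture, and additive Gaussian noise (sd 2 display units, "mild" by CT
standards).  When `n_ellipses` = 0 the image is a pure smooth
background (no bone ring or texture), which gives the generator a
clean no-structure regime for testing.

What phantoms do **not** emulate: CT reconstruction physics (streaks,
beam hardening, ring artifacts), correlated/Poisson-like noise,
anatomical variety, 12-bit Hounsfield dynamics, or inter-slice
context.  Passing the desk-scale tests therefore shows that the
pipeline learns and that SR beats interpolation on CT-like structure —
it does not certify clinical image quality.

## Degradation and metrics

Bicubic resampling uses the Keys cubic-convolution kernel (a = −0.5),
separable, with coordinates clamped at borders and per-pixel weight
renormalization (constants are exact fixed points).  On shrink with
antialiasing the kernel is widened by the scale ratio — the convention
of the resizer commonly used to prepare SR benchmark data.  HR images
whose dimensions are not divisible by s are center-cropped.

PSNR = 10·log10((2^bits − 1)²/MSE) dB; MSE = 0 is reported as +inf and
flagged, and means aggregate the finite values.  SSIM uses the original
Gaussian-window definition (11×11, σ = 1.5, K₁ = 0.01, K₂ = 0.03,
population statistics, valid-region average); it matches
scikit-image's implementation configured to the same definition to
1e−9, which the tests verify.  Both metrics are computed after clipping
and quantization to the declared bit depth, with a border of `scale`
pixels shaved from both methods (configurable, including 0 — whether
published SR numbers shave borders varies, so both modes exist).

## Numerical and design choices

- Channel split takes the FIRST d channels as the retained slice; any
  fixed convention is equivalent up to the preceding convolution's
  channel permutation, and a fixed one keeps runs reproducible.
- The per-branch 1×1 reduction/expansion pairs are independent between
  branches, and the branch convolutions before and after the bottleneck
  do not share weights.
- Attention-branch convolutions act on the 1×1 pooled descriptor with
  same padding, so only their center taps contribute; the loop oracle
  in the tests exploits exactly this.
- Initialization is Kaiming fan-in normal for convolution weights and
  zero biases; under WN, v is initialized to the drawn weight and g to
  its norm, which leaves the initial forward pass unchanged (tested).
- The group-level skip adds the *group input* (not the shallow
  feature) to the group's trailing convolution output.
- Adam uses bias-corrected moments; gradient clipping exists in config
  but is off by default.
- Train-loop history counts *completed* iterations; the recorded lr is
  the one applied at the step just taken.

## Tiling caveat

`idman sr` processes large inputs in overlapping tiles and trims the
overlap before stitching.  Because the attention gates pool globally,
a tile's gate statistics differ slightly from the full image's, so
tiled and untiled outputs are only approximately equal for a trained
model; they are exactly equal (beyond the convolutional receptive
field) when the gates are input-independent, which is how the
tiling-equivalence test constructs its oracle.  The default overlap of
8 LR pixels keeps seams visually negligible.

## Known limitations

- CPU/NumPy only: full-scale training (10×20 blocks, 2e5+ iterations)
  is out of reach; the package is built to be *verifiable* at desk
  scale, not to reproduce published benchmark scores.
- Grayscale single-slice path only; no color, no 3-D context.
- The desk-scale ablation grid records cell PSNRs but does not assert
  an ordering: tiny models at short budgets need not rank modules the
  way full-scale training does.
- The feedback reading of the reconstruction stage is one of several
  defensible interpretations of "local feedback"; it is therefore
  opt-in (`n_refine`) rather than default.
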