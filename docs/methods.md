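# Methods

## Image-formation model

A thin fluorescent sample is described by a nonnegative density s(u) on a
pixel grid (0-based row/col coordinates, pixel centers at integers).  The
multispot illumination of frame i is a square lattice of diffraction-limited
foci,

    p_i(u) = sum_j delta(r - b_ij) (*) h_ex(u),

with lattice period `spacing_px` (default 16) and per-frame offset taken from
a row-major scan of the unit cell with step `step_px`; a unit step needs
spacing^2 frames (256 at the default geometry), a step of q divides that by
q^2.  The camera frame is

    I_i(x) = integral p_i(u) s(u) h_em(x - u) du,

implemented as a pointwise product followed by zero-padded FFT convolution.
Shot noise is a Poisson draw on `photon_scale * I` rescaled back, followed by
additive Gaussian read noise and clipping at zero (detector counts are
nonnegative, and downstream ratios need nonnegativity).

Both PSFs are normalized 2D Gaussians truncated at +/-4 sigma (odd side).
The in-focus width uses the Airy-core approximation sigma = 0.21 lambda/NA;
the defaults lambda_em = 560 nm, NA = 1.1, pixel 130 nm give sigma ~0.82 px.
The excitation PSF defaults to the same width, with an optional
squared-Gaussian mode (sigma/sqrt(2)) for two-photon excitation; neither the
excitation wavelength used in simulation nor two-photon squaring is pinned
down by the hardware description, so both are configuration options rather
than asserted defaults.  Defocus grows the width geometrically,
sigma(dz) = sqrt(sigma_0^2 + (0.5 NA dz / n)^2) with n = 1.33 (water), which
is monotone and adequate for the role the defocused PSF plays here
(an out-of-focus background channel, not a quantitative 3D model).

Synthetic samples are the spoke (Siemens-star) target
rho(r, theta) ∝ 1 + cos(k theta) (default k = 48, randomized per training
sample), plus filament (smoothed random walks) and blob (Gaussian mixture)
phantoms for structural diversity.  The spoke pattern is centered on the
pixel at (size//2, size//2) so its theta = 0 crest runs through pixel
centers.

Noise defaults (`photon_scale = 4000`, `gauss_sigma = 0.002`) put peak raw
frame intensities at a few hundred detected photons; the defocus training
scheme drops the budget tenfold (`photon_scale = 400`) to emulate deep-tissue
low-SNR acquisition.  Exact experimental noise magnitudes are not derivable
from the instrument description, so these are stated simulation conditions.

## Conventional reconstruction

1. **Lattice detection** — Gaussian denoise (sigma 1 px), local maxima with
   an exclusion radius of half the expected spacing, discarding peaks below
   0.3 of the global maximum.  With oracle mode the schedule's foci are used
   directly; on noiseless simulated stacks the two modes agree to 1e-6.
2. **Pinholing** — each pixel is multiplied by a unit-peak Gaussian pinhole
   centered on its *nearest* focus; the subimage partition is therefore the
   Voronoi partition of the lattice, equivalent to square crops at the
   spacings used but free of overlap bookkeeping.  Pinhole sigma defaults to
   the emission-PSF sigma (~1 resel, the ISM convention).  Ties in the
   nearest-focus assignment go to the lexicographically smallest focus
   coordinate, for determinism.
3. **Local scaling / reassignment** — pixel x assigned to focus b deposits
   its full value at integer position x + b on the doubled (2W x 2H) canvas,
   i.e. at (x + b)/2 in original units: the half-distance reassignment rule,
   exactly flux-conserving.  Real-valued detected foci are rounded at the
   deposition step.
4. **Summation and deconvolution** — reassigned frames are summed and
   deconvolved by Richardson–Lucy (scikit-image backend) with the emission
   PSF resampled at half the pixel size (sigma doubled in pixel units).  The
   iteration count is a free parameter; 20 is the default.  For per-frame
   training targets RL runs on each single-frame reconstruction instead
   (`rl_per_frame`); the baseline stack reconstruction deconvolves once after
   summation.

One subtlety of the forward model: with unit-step full coverage the pixelwise
sum of all raw frames ("wide-field image") equals s (*) h_em, because the
unit-sum excitation kernels tile to a constant — the excitation PSF drops out
of the summed image entirely.  The property tests assert this identity.

## Network

An encoder–decoder with dense skip connections.  Four encoder stages
(two Conv3x3-BN-ReLU each; widths [32, 64, 128, 256] by default) with 2x2
max pooling between stages, the fourth acting as bottleneck.  Three decoder
stages upsample by nearest-neighbor interpolation (avoiding transposed-conv
checkerboard artifacts) followed by a channel-halving 1x1 convolution,
concatenate the skip path, and apply two Conv3x3-BN-ReLU blocks.  Skip paths
run through dense blocks: an initial 3x3 convolution, L bottleneck layers
(BN-ReLU-Conv1x1 -> BN-ReLU-Conv3x3, growth rate k, each consuming the
concatenation of all predecessors), and a transition
(BN-ReLU-Conv1x1-BN-ReLU) restoring the input channel count; {L=0} is an
identity.  The three configurations {L=0}, {L=3,k=32}, {L=5,k=8} are
assigned deepest-to-shallowest by default — the assignment is configurable
because it is a genuinely open choice.  The output block upsamples once more
(this realizes the 2x of the local-scaling step) and maps the 32 channels to
one through a 3x3 and then a 1x1 convolution ("two convolutional blocks with
different kernel sizes" admits several readings; this is the minimal one),
ending in ReLU so images are nonnegative.  Dropout (p = 0.5) sits between
successive decoder stages.

Ablation toggles swap dense skips for plain concatenation or residual
blocks, nearest-neighbor upsampling for transposed convolution, and remove
BN or dropout; every combination must produce a working forward pass.

The implementation runs on a small reverse-mode autodiff engine over numpy
(float32): tap-decomposed GEMM convolutions, fused batch normalization, 2x2
max/average pooling, nearest upsampling, reflect padding, separable fixed
1D filters, dropout, and Adam.  Every differentiable op is checked against
central finite differences (directional derivatives, since float32 pointwise
differences are noisy).  The final 1x1 convolution's bias is initialized to
+0.1: with a zero-mean initialization the output ReLU can start saturated on
all-negative pre-activations, which zeroes every gradient and freezes
training permanently.

## Loss

    L = alpha (1 - MS-SSIM(Y, Ybar)) + (1 - alpha) mean(G (*) |Y - Ybar|),

alpha = 0.75.  G is the unit-sum 9x9 sigma-1.5 Gaussian; "pointwise
multiplication of the l1 loss with G" is implemented as local Gaussian
aggregation of the absolute error (convolution with reflect boundary, so a
constant error e contributes exactly (1-alpha) e) — a literal 9x9 pointwise
product against a full image is dimensionally impossible.

MS-SSIM uses 11x11 sigma-1.5 Gaussian windows with valid-window statistics,
2x2 mean downsampling between scales, contrast/structure terms at every
scale and the luminance term at the coarsest, exponents
beta = [0.1, 0.3, 0.3, 0.2, 0.1] (M = 5).  Following standard implementations
the coarsest scale exponentiates the mean of the full l*cs map, so M = 1
with beta = [1] reduces *exactly* to single-scale SSIM — the cross-check the
test suite performs against the metrics module.  M = 5 needs images of at
least 176 px; smaller patches reduce M automatically and renormalize beta to
preserve its total (the 128 px training targets use M = 4).  Stability
constants are C1 = (0.01 R)^2, C2 = (0.03 R)^2 with R = 1 on normalized
data; intermediate scale terms are clamped at 1e-8 before fractional powers.

## Training data and loop

A training pair is (noisy raw frame, conventional single-frame reconstruction
of the noiseless frame).  Per-frame targets (pinhole + reassign + per-frame
RL) make the pairs well-defined and the learned stack reconstruction
composable: at inference every frame passes the network in evaluation mode
and the outputs are summed.  Samples are spoke targets with lobe counts
drawn uniformly from [16, 80) (60%), filaments (20%) and blobs (20%); scan
positions are drawn uniformly from the schedule.

Inputs and targets are divided by their own dataset maxima (raw frames and
reassigned/deconvolved targets live on different intensity scales; a single
joint constant would compress one of them), both constants are stored in the
checkpoint and inverted at inference.  The train/validation split is a seeded
70/30 shuffle.  The reference protocol is 5120 pairs, Adam at lr 1e-3,
50 epochs, batch 8, keeping the weights with the lowest validation loss.

The *defocus* scheme renders each frame twice — through the in-focus
emission PSF and a 3 um defocused one — and sums the two, with a tenfold
lower photon budget; targets come from the focused-only render, so the
network learns to reject out-of-focus background.

The *fewer-frames* (4-shift) scheme renders, for every base position of a
step-2 scan, four frames with the lattice additionally shifted by
{(0,0),(0,1),(1,0),(1,1)}; the input is the noisy (0,0) frame and the target
the sum of the four single-frame reconstructions.  A model trained this way
reconstructs from a stack with four times fewer frames.

## Scaled-down study sizes

The acceptance-level learning studies run at desk scale, chosen as the
smallest sizes at which the claims are meaningful: 200 pairs of 64 px frames
(128 px targets), 10 epochs, batch 8, lr 1e-3, ten seeds, with the
reduced-width preset `NetworkConfig.small()` (encoder widths [6, 12, 16, 16],
dense configs {L=0}, {L=1,k=8}, {L=1,k=4}, dropout off).  The success
criteria are direction-only: validation loss must drop below its untrained
value and the model must beat nearest-neighbor 2x upsampling of its input in
mean validation SSIM, in at least 9 of 10 seeds; and on a held-out step-2
stack the fine-tuned 4-shift model must track the full step-1 conventional
reference more closely (SSIM) than the conventional reconstruction of the
same reduced stack.  Absolute metric values at these sizes are not
comparable to full-scale training.

## What the synthetic data does and does not emulate

The generator reproduces the geometry (lattice, scan, pixel size), Gaussian
optics, and Poisson/Gaussian noise of a multifocal acquisition.  It does not
model vectorial/aberrated PSFs, axial structure beyond the two-plane defocus
mixture, camera gain or EMCCD excess noise, sample motion, or the background
statistics of real tissue.  Passing tests therefore validate the algorithms
under the stated model, not instrument-level performance.

## Numerical choices and degenerate inputs

- Convolutions zero-pad; flux statements in tests use interior lattice
  offsets where border truncation is negligible or exactly zero.
- FFT round-off can produce tiny negative values; rendered images are
  clipped at zero.
- PSFs with sigma below 0.2 px are rejected as unresolvable at the chosen
  pixel size.
- The RSE/RSP resolution scaling function is a Gaussian blur (golden-section
  search on sigma in [0, 10] px, 60 iterations, compared against the
  sigma = 0 boundary) composed with a closed-form affine intensity fit —
  the reference tool's exact estimator is unspecified, and this surrogate
  recovers constructed (sigma, a, b) triples to the tested tolerances.
- Fidelity metrics quantize both images to a shared 0–255 range
  (round-half-even) first; PSNR uses MAX = 255 — the convention under which
  published PSNR/MSE pairs are mutually consistent, although the printed
  PSNR formula omits the MAX term; NRMSE divides by the ground-truth range;
  SSIM uses c1 = (0.01*255)^2, c2 = (0.03*255)^2.
- All-zero frames raise a no-foci error in detection; stacks abort when more
  than 10% of frames fail detection.
- Identical images report an infinite PSNR sentinel; flat ground truth makes
  NRMSE undefined and raises.

## Known limitations

- The numpy training loop is single-threaded and CPU-bound; it is sized for
  the study scales above, not for 5120-pair production training.
- Checkpoints store raw arrays via `npz`; there is no versioning beyond the
  embedded architecture config.
- Lattice detection assumes the nominal spacing is known (it is, for a
  configured instrument); it does not estimate the period blindly.
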