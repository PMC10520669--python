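# msim

Multifocal structured illumination microscopy (MSIM) in Python: a forward
simulator, the conventional four-step pixel-reassignment reconstruction, and a
dense-skip encoder–decoder network that learns to map raw multifocal frames
directly to super-resolution images.

MSIM parallelizes image scanning microscopy: a sparse square lattice of
excitation foci (period 16 px here) is scanned across the sample, one camera
frame per lattice position, and the stack is computationally recombined into
an image with up to a 2x lateral resolution gain.  The conventional route —
digital pinholing around each focus, half-distance pixel reassignment onto a
doubled grid, summation, and Richardson–Lucy deconvolution — is accurate but
slow and needs the full frame set.  The learned route replaces all four steps
with a single network evaluation per frame, and, trained on suitably
constructed pairs, still works when the scan step is doubled so only a quarter
of the frames are recorded.

## What is implemented

- **Forward model** (`msim.simulate`) — spoke (Siemens-star) and random
  structure phantoms; Gaussian PSFs `sigma = 0.21 lambda/NA` with a
  geometric-optics defocus term; illumination schedules
  `p_i(u) = sum_j delta(r - b_ij) (*) h_ex`; image formation
  `I_i(x) = integral p_i(u) s(u) h_em(x-u) du`; Poisson + Gaussian noise.
- **Conventional reconstruction** (`msim.reconstruct`) — lattice detection by
  local maxima, Gaussian digital pinholes over a nearest-focus partition,
  exact flux-conserving reassignment onto the 2W x 2H canvas, summation, and
  Richardson–Lucy deconvolution.
- **Network** (`msim.network`) — four two-conv encoder stages with three
  max-pool reductions, three nearest-neighbor-upsampling decoder stages whose
  skip connections pass through dense blocks ({L=0}, {L=3,k=32}, {L=5,k=8}),
  and an output block mapping 32 channels to one nonnegative 2x-upsampled
  channel.  Built on a small numpy reverse-mode autodiff engine
  (`msim.autograd`) that is gradient-checked in the test suite.
- **Loss and training** (`msim.training`) —
  `L = alpha (1 - MS-SSIM) + (1 - alpha) mean(G (*) |Y - Ybar|)` with
  `alpha = 0.75` and a unit-sum 9x9 sigma-1.5 Gaussian G; three pair-generation
  schemes (standard, 3 um defocus mixture, and the fourfold fewer-frames
  4-shift scheme); Adam training with per-epoch validation and
  best-checkpoint retention; per-frame inference summed over a stack.
- **Metrics** (`msim.metrics`) — 8-bit PSNR/NRMSE/MSE/SSIM, resolution-scaled
  error and Pearson coefficient (RSE/RSP) with a fitted Gaussian resolution
  scaling function, error maps, and FWHM profiling.

## Worked example

```python
import numpy as np
from msim import (SampleMap, build_schedule, make_gaussian_psf,
                  simulate_stack, widefield, reconstruct_conventional,
                  ReconOptions)
from msim.metrics import fwhm

px = 65.0
psf_ex = make_gaussian_psf(pixel_size_nm=px, role="excitation")
psf_em = make_gaussian_psf(pixel_size_nm=px, role="emission")

point = np.zeros((64, 64)); point[32, 32] = 1.0
stack = simulate_stack(SampleMap(point, px), build_schedule((64, 64), 16, 1),
                       psf_ex, psf_em, noise=None)
print(stack.frames.shape)                  # (256, 64, 64)

wf = widefield(stack)
sr = reconstruct_conventional(stack, ReconOptions(psf_em=psf_em))
print(sr.image.shape)                      # (128, 128)
print(round(fwhm(wf[32], spacing_nm=px), 1))          # 251.7
print(round(fwhm(sr.image[64], spacing_nm=px / 2), 1))  # 79.0
```

The 256-frame unit-step scan of the 16 px lattice produces a wide-field image
whose point response has a FWHM of ~252 nm (the emission diffraction limit at
these optics).  Pixel reassignment alone narrows an isolated emitter by about
sqrt(2); the 20 Richardson–Lucy iterations sharpen this noiseless point
further, to ~79 nm on the doubled grid.  On extended, noisy samples the
practical gain is the ~2x of the method.

The same pipeline is scriptable from the shell:

```sh
msim simulate --sample spoke --size 256 --spacing 16 --step 1 --seed 7 --out stack.tif
msim reconstruct --method conventional --stack stack.tif --out sr.tif
msim evaluate --ref a.tif --test b.tif --out report.json
```

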