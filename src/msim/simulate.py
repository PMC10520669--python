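"""Forward simulation of multifocal structured illumination microscopy (MSIM).

An MSIM acquisition excites the sample with a sparse square lattice of
diffraction-limited foci and records one camera frame per lattice position.
Scanning the lattice over its unit cell covers the field of view.  This module
generates synthetic fluorophore-density maps, Gaussian PSF models, illumination
schedules, and noisy raw multifocal stacks:

    p_i(u) = sum_j delta(r - b_ij) (*) h_ex(u)       multispot pattern
    I_i(x) = integral p_i(u) s(u) h_em(x - u) du     raw frame

with Poisson (shot) and additive Gaussian (read) noise applied to each frame.

Conventions: 0-based (row, col) coordinates, pixel centers at integers, foci at
integer pixels, convolutions zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "SampleMap",
    "PsfKernel",
    "IlluminationSchedule",
    "RawStack",
    "make_spoke_sample",
    "make_random_structure_sample",
    "make_gaussian_psf",
    "build_schedule",
    "render_pattern",
    "render_raw_frame",
    "render_defocus_mixture",
    "corrupt",
    "simulate_stack",
    "widefield",
]

# Default optical parameters: emission wavelength, numerical aperture and
# camera pixel size of a water-immersion two-photon MSIM system.
DEFAULT_WAVELENGTH_NM = 560.0
DEFAULT_NA = 1.1
DEFAULT_PIXEL_SIZE_NM = 130.0
DEFAULT_SPACING_PX = 16
# Gaussian approximation of the Airy core: sigma = 0.21 * lambda / NA.
AIRY_SIGMA_FACTOR = 0.21
# Geometric-optics defocus blur growth uses the refractive index of water.
DEFAULT_N_MEDIUM = 1.33


class InvalidParameterError(ValueError):
    """Raised when a simulation parameter is physically or geometrically invalid."""


@dataclass
class SampleMap:
    """Ground-truth 2D fluorophore density on a pixel grid."""

    density: np.ndarray
    pixel_size_nm: float
    descriptor: str = ""

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.density.ndim != 2 or min(self.density.shape) < 16:
            raise InvalidParameterError("sample grid must be 2D with both dims >= 16")
        if not np.all(np.isfinite(self.density)) or np.any(self.density < 0):
            raise InvalidParameterError("density must be finite and nonnegative")
        if self.pixel_size_nm <= 0:
            raise InvalidParameterError("pixel_size_nm must be positive")


@dataclass
class PsfKernel:
    """Normalized 2D Gaussian kernel standing in for an excitation or emission PSF."""

    kernel: np.ndarray
    sigma_px: float
    wavelength_nm: float
    na: float
    defocus_um: float = 0.0
    role: str = "emission"

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.ndim != 2 or self.kernel.shape[0] % 2 == 0 or self.kernel.shape[1] % 2 == 0:
            raise InvalidParameterError("PSF kernel must be 2D with odd side lengths")
        if np.any(self.kernel < 0):
            raise InvalidParameterError("PSF kernel must be nonnegative")
        if abs(self.kernel.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("PSF kernel must sum to 1 within 1e-9")
        if self.role not in ("excitation", "emission"):
            raise InvalidParameterError(f"unknown PSF role {self.role!r}")


@dataclass
class IlluminationSchedule:
    """Lattice of focus positions b_ij for each of the m scan frames.

    ``foci[i]`` is an integer array of shape (n, 2) holding (row, col) focus
    positions of frame i; ``scan_offsets[i]`` is the (dy, dx) lattice offset.
    """

    frame_shape: tuple[int, int]
    spacing_px: int
    step_px: int
    n_frames: int
    foci: list[np.ndarray]
    scan_offsets: list[tuple[int, int]]


@dataclass
class RawStack:
    """m raw multifocal frames plus acquisition metadata and noise provenance."""

    frames: np.ndarray
    schedule: IlluminationSchedule
    pixel_size_nm: float
    noise: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (m, H, W) array")
        if self.schedule is not None:
            if self.frames.shape[0] != self.schedule.n_frames:
                raise InvalidParameterError("frame count does not match schedule")
            if self.frames.shape[1:] != tuple(self.schedule.frame_shape):
                raise InvalidParameterError("frame shape does not match schedule")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise InvalidParameterError("frames must be finite and nonnegative")


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------

def make_spoke_sample(
    size_px: int,
    n_lobes: int = 48,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> SampleMap:
    """Radial spoke (Siemens-star) test target, density 1 + cos(n_lobes * theta).

    The angular spoke period shrinks linearly toward the center, so a single
    target probes a continuous range of spatial frequencies.  Peak density is
    normalized to 1.  The pattern is centered on the pixel at (size//2,
    size//2) so the theta = 0 crest runs exactly through pixel centers.
    """
    if size_px < 32:
        raise InvalidParameterError("size_px must be >= 32")
    if n_lobes < 1:
        raise InvalidParameterError("n_lobes must be >= 1")
    center = float(size_px // 2)
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    theta = np.arctan2(yy - center, xx - center)
    density = 0.5 * (1.0 + np.cos(n_lobes * theta))
    return SampleMap(density, pixel_size_nm, descriptor=f"spoke n_lobes={n_lobes}")


def make_random_structure_sample(
    size_px: int,
    style: str = "filaments",
    seed: int = 0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> SampleMap:
    """Random filamentous or blob-like sample for diversifying training data.

    ``filaments`` draws smooth random-walk curves with a Gaussian cross
    profile (microtubule-like); ``blobs`` draws an intensity mixture of
    isotropic Gaussian spots (vesicle/mitochondria-like).  Deterministic under
    ``seed``; peak normalized to 1.
    """
    if size_px < 32:
        raise InvalidParameterError("size_px must be >= 32")
    if style not in ("filaments", "blobs"):
        raise InvalidParameterError(f"unknown style {style!r}")
    rng = np.random.default_rng(seed)
    img = np.zeros((size_px, size_px), dtype=np.float64)
    if style == "filaments":
        n_curves = rng.integers(4, 9)
        n_steps = size_px * 3
        for _ in range(n_curves):
            pos = rng.uniform(0, size_px, size=2)
            ang = rng.uniform(0, 2 * np.pi)
            for _ in range(n_steps):
                ang += rng.normal(0.0, 0.15)
                pos = pos + np.array([np.sin(ang), np.cos(ang)])
                r, c = int(round(pos[0])), int(round(pos[1]))
                if 0 <= r < size_px and 0 <= c < size_px:
                    img[r, c] += 1.0
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, sigma=0.8)
        img = np.clip(img, 0.0, np.percentile(img[img > 0], 95) if np.any(img > 0) else 1.0)
    else:
        n_blobs = rng.integers(10, 30)
        yy, xx = np.mgrid[0:size_px, 0:size_px]
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, size_px, size=2)
            sig = rng.uniform(1.5, size_px / 16)
            amp = rng.uniform(0.3, 1.0)
            img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    peak = img.max()
    if peak > 0:
        img /= peak
    return SampleMap(img, pixel_size_nm, descriptor=f"{style} seed={seed}")


# ---------------------------------------------------------------------------
# PSFs
# ---------------------------------------------------------------------------

def defocus_sigma_nm(
    sigma0_nm: float, na: float, defocus_um: float, n_medium: float = DEFAULT_N_MEDIUM
) -> float:
    """Lateral Gaussian width at defocus: sqrt(sigma0^2 + (0.5 NA dz / n)^2).

    Geometric-optics cone blur added in quadrature to the in-focus width;
    monotone in the defocus distance.
    """
    blur_nm = 0.5 * na * (defocus_um * 1000.0) / n_medium
    return float(np.hypot(sigma0_nm, blur_nm))


def make_gaussian_psf(
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    na: float = DEFAULT_NA,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    defocus_um: float = 0.0,
    role: str = "emission",
    n_medium: float = DEFAULT_N_MEDIUM,
    sigma_nm: float | None = None,
    squared: bool = False,
) -> PsfKernel:
    """Gaussian PSF model truncated at +/-4 sigma and normalized to unit sum.

    The in-focus width defaults to the Airy-core approximation
    sigma = 0.21 * lambda / NA; pass ``sigma_nm`` to override.  ``squared``
    squares the Gaussian before normalization (two-photon excitation
    sharpening), which narrows sigma by sqrt(2).
    """
    if min(wavelength_nm, na, pixel_size_nm) <= 0:
        raise InvalidParameterError("wavelength, NA and pixel size must be positive")
    if defocus_um < 0:
        raise InvalidParameterError("defocus_um must be >= 0")
    sigma0 = AIRY_SIGMA_FACTOR * wavelength_nm / na if sigma_nm is None else float(sigma_nm)
    sigma = defocus_sigma_nm(sigma0, na, defocus_um, n_medium)
    sigma_px = sigma / pixel_size_nm
    if squared:
        sigma_px /= np.sqrt(2.0)
    if sigma_px < 0.2:
        raise InvalidParameterError(
            f"sigma_px={sigma_px:.3f} < 0.2: PSF unresolvable at this pixel size"
        )
    radius = int(np.ceil(4.0 * sigma_px))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    gauss = np.exp(-(ax**2) / (2.0 * sigma_px**2))
    kernel = np.outer(gauss, gauss)
    kernel /= kernel.sum()
    return PsfKernel(
        kernel=kernel,
        sigma_px=float(sigma_px),
        wavelength_nm=float(wavelength_nm),
        na=float(na),
        defocus_um=float(defocus_um),
        role=role,
    )


# ---------------------------------------------------------------------------
# Illumination schedule
# ---------------------------------------------------------------------------

def build_schedule(
    frame_shape: tuple[int, int],
    spacing_px: int = DEFAULT_SPACING_PX,
    step_px: int = 1,
) -> IlluminationSchedule:
    """Scan schedule: lattice offsets enumerate the step grid in row-major order.

    With step 1 the m = spacing^2 frames tile the full unit cell; with step q
    (q | spacing) m = (spacing/q)^2, a q^2-fold reduction in raw frames.
    """
    H, W = frame_shape
    if spacing_px <= 0 or step_px <= 0:
        raise InvalidParameterError("spacing_px and step_px must be positive")
    if H % spacing_px or W % spacing_px:
        raise InvalidParameterError("spacing_px must divide both frame dimensions")
    if spacing_px % step_px:
        raise InvalidParameterError("step_px must divide spacing_px")
    offsets = [
        (dy, dx)
        for dy in range(0, spacing_px, step_px)
        for dx in range(0, spacing_px, step_px)
    ]
    rows = np.arange(0, H, spacing_px)
    cols = np.arange(0, W, spacing_px)
    base = np.array([(r, c) for r in rows for c in cols], dtype=np.int64)
    foci = [base + np.array(off, dtype=np.int64) for off in offsets]
    # offsets < spacing and spacing divides the frame, so all foci are in bounds
    return IlluminationSchedule(
        frame_shape=(H, W),
        spacing_px=spacing_px,
        step_px=step_px,
        n_frames=len(offsets),
        foci=foci,
        scan_offsets=offsets,
    )


def render_pattern(
    schedule: IlluminationSchedule, frame_index: int, psf_ex: PsfKernel
) -> np.ndarray:
    """Multispot illumination pattern: delta comb at the foci convolved with h_ex."""
    if not 0 <= frame_index < schedule.n_frames:
        raise IndexError(f"frame_index {frame_index} out of range [0, {schedule.n_frames})")
    comb = np.zeros(schedule.frame_shape, dtype=np.float64)
    pts = schedule.foci[frame_index]
    np.add.at(comb, (pts[:, 0], pts[:, 1]), 1.0)
    if psf_ex.kernel.shape == (1, 1):
        return comb * psf_ex.kernel[0, 0]
    pattern = fftconvolve(comb, psf_ex.kernel, mode="same")
    return np.clip(pattern, 0.0, None)


def render_raw_frame(
    sample: SampleMap, pattern: np.ndarray, psf_em: PsfKernel
) -> np.ndarray:
    """Noiseless raw frame: (pattern * sample) blurred by the emission PSF.

    Pointwise product then zero-padded convolution, the camera-plane image
    I(x) = integral p(u) s(u) h_em(x - u) du.
    """
    if pattern.shape != sample.density.shape:
        raise InvalidParameterError("pattern and sample shapes must match")
    excited = pattern * sample.density
    frame = fftconvolve(excited, psf_em.kernel, mode="same")
    return np.clip(frame, 0.0, None)


def render_defocus_mixture(
    sample: SampleMap,
    pattern: np.ndarray,
    psf_em_focused: PsfKernel,
    psf_em_defocused: PsfKernel,
) -> np.ndarray:
    """In-focus frame plus an out-of-focus copy, emulating a thick sample.

    The same excited fluorophore map is imaged once through the in-focus
    emission PSF and once through a defocused one, and the two are summed.
    """
    return render_raw_frame(sample, pattern, psf_em_focused) + render_raw_frame(
        sample, pattern, psf_em_defocused
    )


def corrupt(
    frame: np.ndarray,
    gauss_sigma: float = 0.0,
    photon_scale: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Shot + read noise: Poisson draw at photon_scale, then additive Gaussian.

    ``photon_scale`` converts intensity to expected photon counts (higher is
    cleaner); ``None`` disables shot noise.  Negative excursions from the
    Gaussian stage are clipped at zero, as detector counts are nonnegative.
    """
    if gauss_sigma < 0:
        raise InvalidParameterError("gauss_sigma must be >= 0")
    if photon_scale is not None and photon_scale <= 0:
        raise InvalidParameterError("photon_scale must be positive or None")
    rng = np.random.default_rng(seed)
    out = np.asarray(frame, dtype=np.float64)
    if photon_scale is not None:
        out = rng.poisson(out * photon_scale).astype(np.float64) / photon_scale
    if gauss_sigma > 0:
        out = out + rng.normal(0.0, gauss_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


def simulate_stack(
    sample: SampleMap,
    schedule: IlluminationSchedule,
    psf_ex: PsfKernel,
    psf_em: PsfKernel,
    noise: dict | None = None,
    seed: int | None = None,
    defocus_psf: PsfKernel | None = None,
) -> RawStack:
    """Render and corrupt one raw frame per schedule entry (frame i uses seed+i)."""
    if tuple(schedule.frame_shape) != sample.density.shape:
        raise InvalidParameterError("sample shape must match schedule frame_shape")
    noise = dict(noise or {})
    gauss_sigma = float(noise.get("gauss_sigma", 0.0))
    photon_scale = noise.get("photon_scale")
    frames = np.empty((schedule.n_frames, *schedule.frame_shape), dtype=np.float64)
    for i in range(schedule.n_frames):
        pattern = render_pattern(schedule, i, psf_ex)
        if defocus_psf is not None:
            frame = render_defocus_mixture(sample, pattern, psf_em, defocus_psf)
        else:
            frame = render_raw_frame(sample, pattern, psf_em)
        if gauss_sigma > 0 or photon_scale is not None:
            frame = corrupt(
                frame,
                gauss_sigma,
                photon_scale,
                seed=None if seed is None else seed + i,
            )
        frames[i] = frame
    return RawStack(
        frames=frames,
        schedule=schedule,
        pixel_size_nm=sample.pixel_size_nm,
        noise={"gauss_sigma": gauss_sigma, "photon_scale": photon_scale},
        seed=seed,
    )


def widefield(stack: RawStack) -> np.ndarray:
    """Wide-field (diffraction-limited) image: pixelwise sum over all raw frames."""
    if stack.frames.shape[0] == 0:
        raise InvalidParameterError("empty stack")
    return stack.frames.sum(axis=0)
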