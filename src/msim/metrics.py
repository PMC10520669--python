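"""Quantitative evaluation of reconstructed images.

Fidelity metrics (PSNR, NRMSE, MSE, SSIM) follow the 8-bit convention: both
images of a pair are linearly rescaled to a shared 0–255 range and rounded
(half-even) before comparison, PSNR uses MAX = 255, and SSIM uses the
Wang-2004 settings (11x11 Gaussian window, sigma 1.5, c1 = (0.01*255)^2,
c2 = (0.03*255)^2).

Artifact metrics follow the resolution-scaling approach: the super-resolution
image is downsampled to the reference grid, blurred by an optimized Gaussian
(the resolution scaling function) and affinely matched to the reference; the
residual yields the resolution-scaled error (RSE, root mean square) and the
resolution-scaled Pearson coefficient (RSP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.metrics import structural_similarity

from .reconstruct import SRImage
from .simulate import InvalidParameterError

__all__ = [
    "MetricsReport",
    "ErrorMap",
    "quantize_pair_8bit",
    "psnr_nrmse_mse",
    "ssim",
    "resolution_scale",
    "rse_rsp",
    "error_map",
    "pixelwise_diff",
    "fwhm",
    "evaluate_pair",
]

MAX_8BIT = 255.0


@dataclass
class MetricsReport:
    psnr_db: float
    nrmse: float
    mse: float
    ssim: float
    n_pixels: int
    bit_depth: int = 8

    def to_dict(self) -> dict:
        return {
            "psnr_db": self.psnr_db,
            "nrmse": self.nrmse,
            "mse": self.mse,
            "ssim": self.ssim,
            "n_pixels": self.n_pixels,
            "bit_depth": self.bit_depth,
        }


@dataclass
class ErrorMap:
    map: np.ndarray
    rse: float
    rsp: float
    scale_a: float
    scale_b: float
    blur_sigma: float


def quantize_pair_8bit(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly rescale both images to a shared 0–255 range, round half-even."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return np.zeros_like(a), np.zeros_like(b)
    scale = MAX_8BIT / (hi - lo)
    return np.round((a - lo) * scale), np.round((b - lo) * scale)


def psnr_nrmse_mse(Y: np.ndarray, Ybar: np.ndarray) -> tuple[float, float, float]:
    """8-bit PSNR (MAX = 255), NRMSE (ground-truth range), and MSE.

    ``Y`` is the ground truth, ``Ybar`` the estimate.  Identical images
    report MSE 0, NRMSE 0, and an infinite PSNR sentinel.
    """
    if Y.shape != Ybar.shape:
        raise InvalidParameterError("images must share a shape")
    yq, bq = quantize_pair_8bit(Y, Ybar)
    if yq.max() == yq.min():
        raise InvalidParameterError("flat ground-truth image: NRMSE undefined")
    mse = float(np.mean((yq - bq) ** 2))
    if mse == 0.0:
        return float("inf"), 0.0, 0.0
    psnr = 20.0 * np.log10(MAX_8BIT / np.sqrt(mse))
    nrmse = float(np.sqrt(mse) / (yq.max() - yq.min()))
    return float(psnr), nrmse, mse


def ssim(Y: np.ndarray, Ybar: np.ndarray) -> float:
    """Mean SSIM over 11x11 sigma-1.5 Gaussian windows, 8-bit convention."""
    if Y.shape != Ybar.shape:
        raise InvalidParameterError("images must share a shape")
    yq, bq = quantize_pair_8bit(Y, Ybar)
    return float(
        structural_similarity(
            yq,
            bq,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=MAX_8BIT,
        )
    )


# ---------------------------------------------------------------------------
# Resolution-scaled error metrics
# ---------------------------------------------------------------------------

def _downsample2(img: np.ndarray) -> np.ndarray:
    H, W = img.shape
    return img.reshape(H // 2, 2, W // 2, 2).mean(axis=(1, 3))


def _affine_fit(x: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
    """Closed-form least-squares a, b minimizing ||a x + b - ref||^2; returns (a, b, sse)."""
    xm, rm = x.mean(), ref.mean()
    vx = np.mean((x - xm) ** 2)
    cov = np.mean((x - xm) * (ref - rm))
    a = 0.0 if vx == 0 else cov / vx
    b = rm - a * xm
    sse = float(np.mean((a * x + b - ref) ** 2))
    return float(a), float(b), sse


def resolution_scale(
    sr: SRImage | np.ndarray, reference: np.ndarray, sigma_max: float = 10.0
) -> tuple[np.ndarray, float, float, float]:
    """Fit the resolution scaling function mapping an SR image onto its reference.

    The SR image (2x grid) is 2x2 block-averaged onto the reference grid,
    then the Gaussian blur width sigma (golden-section search on
    [0, sigma_max] px) and affine intensity parameters a, b (closed form) are
    chosen to minimize the RMS mismatch.  Returns (I_RS, a, b, sigma).
    """
    img = sr.image if isinstance(sr, SRImage) else np.asarray(sr, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if img.shape != tuple(2 * s for s in reference.shape):
        raise InvalidParameterError("SR image dims must be exactly 2x the reference dims")
    ds = _downsample2(img)

    def objective(sig: float) -> tuple[float, float, float, np.ndarray]:
        blurred = gaussian_filter(ds, sig) if sig > 1e-12 else ds
        a, b, sse = _affine_fit(blurred, reference)
        return sse, a, b, blurred

    # golden-section search for the blur width
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    lo, hi = 0.0, float(sigma_max)
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1, f2 = objective(x1)[0], objective(x2)[0]
    for _ in range(60):
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - invphi * (hi - lo)
            f1 = objective(x1)[0]
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + invphi * (hi - lo)
            f2 = objective(x2)[0]
    # compare the interior optimum against the sigma = 0 boundary
    cands = [0.0, (lo + hi) / 2.0]
    best = min(cands, key=lambda s: objective(s)[0])
    sse, a, b, blurred = objective(best)
    if not np.isfinite(sse):
        raise InvalidParameterError("resolution-scale optimization diverged")
    return a * blurred + b, a, b, float(best)


def rse_rsp(reference: np.ndarray, i_rs: np.ndarray) -> tuple[float, float]:
    """Resolution-scaled error (RMS difference) and Pearson coefficient."""
    reference = np.asarray(reference, dtype=np.float64)
    i_rs = np.asarray(i_rs, dtype=np.float64)
    if reference.shape != i_rs.shape:
        raise InvalidParameterError("images must share a shape")
    rse = float(np.sqrt(np.mean((reference - i_rs) ** 2)))
    rc = reference - reference.mean()
    ic = i_rs - i_rs.mean()
    denom = np.sqrt((rc**2).sum() * (ic**2).sum())
    if denom == 0:
        raise InvalidParameterError("zero-variance input: RSP undefined")
    return rse, float((rc * ic).sum() / denom)


def error_map(reference: np.ndarray, sr: SRImage | np.ndarray) -> ErrorMap:
    """Per-pixel |reference - I_RS| map with global RSE/RSP scores."""
    i_rs, a, b, sig = resolution_scale(sr, reference)
    rse, rsp = rse_rsp(reference, i_rs)
    return ErrorMap(
        map=np.abs(np.asarray(reference, dtype=np.float64) - i_rs),
        rse=rse,
        rsp=rsp,
        scale_a=a,
        scale_b=b,
        blur_sigma=sig,
    )


def pixelwise_diff(img_a: np.ndarray, img_b: np.ndarray) -> np.ndarray:
    """Pixelwise absolute difference |A - B| between two reconstructions."""
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidParameterError("images must share a shape")
    return np.abs(a - b)


def fwhm(profile: np.ndarray, spacing_nm: float = 1.0) -> float:
    """Full width at half maximum of a 1D intensity profile.

    Linear interpolation locates the half-maximum crossing on each side of
    the (unique) global maximum; the width is their separation times the
    sample spacing.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size < 3:
        raise InvalidParameterError("profile must be 1D with >= 3 samples")
    imax = int(np.argmax(p))
    half = p[imax] / 2.0
    # walk left
    left = None
    for i in range(imax, 0, -1):
        if p[i - 1] <= half <= p[i]:
            frac = (p[i] - half) / (p[i] - p[i - 1]) if p[i] != p[i - 1] else 0.0
            left = i - frac
            break
    right = None
    for i in range(imax, p.size - 1):
        if p[i + 1] <= half <= p[i]:
            frac = (p[i] - half) / (p[i] - p[i + 1]) if p[i] != p[i + 1] else 0.0
            right = i + frac
            break
    if left is None or right is None:
        raise InvalidParameterError("no half-maximum crossing on one side of the peak")
    return float((right - left) * spacing_nm)


def evaluate_pair(reference: np.ndarray, test: np.ndarray) -> MetricsReport:
    """All 8-bit fidelity metrics of an (reference, estimate) image pair."""
    psnr, nrmse, mse = psnr_nrmse_mse(reference, test)
    return MetricsReport(
        psnr_db=psnr,
        nrmse=nrmse,
        mse=mse,
        ssim=ssim(reference, test),
        n_pixels=int(np.prod(reference.shape)),
    )
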