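"""Composite loss, training-pair generation, the training loop, and stack inference.

The loss combines perceptual and pixel fidelity terms:

    L = alpha * (1 - MS-SSIM(Y, Ybar)) + (1 - alpha) * mean(G (*) |Y - Ybar|)

with alpha = 0.75 and G a unit-sum 9x9 Gaussian (sigma 1.5) that aggregates
the absolute error locally before averaging.  MS-SSIM evaluates the SSIM
contrast/structure terms over a dyadic pyramid of M scales with per-scale
exponents beta, the luminance term entering only at the coarsest scale.

Training pairs are purely simulated: a noisy raw multifocal frame as input,
and the conventional single-frame reconstruction (pinhole + reassign +
per-frame Richardson–Lucy) of the noiseless frame as target.  Three schemes
are provided: ``standard``, ``defocus`` (in-focus + 3 um defocused emission
mixture with elevated shot noise, for thick samples), and ``shifted4`` (the
fewer-frames scheme: the target is the sum of four reconstructions at lattice
offsets {(0,0),(0,1),(1,0),(1,1)} while the scan runs at step 2, a fourfold
frame reduction).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .network import MsimNet, NetworkConfig
from .reconstruct import FociSet, ReconOptions, SRImage, reconstruct_single_frame
from .simulate import (
    IlluminationSchedule,
    InvalidParameterError,
    PsfKernel,
    RawStack,
    SampleMap,
    build_schedule,
    corrupt,
    make_gaussian_psf,
    make_random_structure_sample,
    make_spoke_sample,
    render_defocus_mixture,
    render_pattern,
    render_raw_frame,
)

__all__ = [
    "LossConfig",
    "TrainConfig",
    "PairDataset",
    "ms_ssim",
    "loss",
    "make_training_pairs",
    "make_shifted_pairs",
    "make_defocus_pairs",
    "train",
    "infer_stack",
    "save_checkpoint",
    "load_checkpoint",
]

SSIM_WIN = 11
SSIM_WIN_SIGMA = 1.5

# Photon budget chosen so peak raw-frame intensities correspond to a few
# hundred detected photons (realistic camera shot noise); the defocus scheme
# uses a much lower budget to emulate the low-SNR deep-tissue condition.
DEFAULT_NOISE = {"gauss_sigma": 0.002, "photon_scale": 4000.0}
HIGH_NOISE = {"gauss_sigma": 0.004, "photon_scale": 400.0}


@dataclass
class LossConfig:
    alpha: float = 0.75
    g_kernel_size: int = 9
    g_sigma: float = 1.5
    ms_scales: int = 5
    beta: list[float] = field(default_factory=lambda: [0.1, 0.3, 0.3, 0.2, 0.1])
    c1: float = 0.01**2
    c2: float = 0.03**2

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError("alpha must be in [0, 1]")
        if len(self.beta) != self.ms_scales:
            raise InvalidParameterError("beta length must equal ms_scales")
        if any(b <= 0 for b in self.beta):
            raise InvalidParameterError("all beta must be positive")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 50
    batch: int = 8
    split_train: float = 0.7
    n_pairs: int = 5120
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_train < 1.0:
            raise InvalidParameterError("split_train must be in (0, 1)")
        if self.batch < 1:
            raise InvalidParameterError("batch must be >= 1")


# ---------------------------------------------------------------------------
# MS-SSIM and the composite loss (differentiable)
# ---------------------------------------------------------------------------

def _gauss1d(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    return (g / g.sum()).astype(np.float32)


def _as_nchw(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    if t.data.ndim == 2:
        t = ag.reshape(t, (1, 1, *t.shape))
    elif t.data.ndim == 3:
        t = ag.reshape(t, (t.shape[0], 1, t.shape[1], t.shape[2]))
    return t


def _filter_valid(x: Tensor, k1d: np.ndarray) -> Tensor:
    """Separable valid-mode filtering with a 1D kernel along both spatial axes."""
    return ag.filter1d_valid(ag.filter1d_valid(x, k1d, axis=2), k1d, axis=3)


def min_size_for_scales(m: int) -> int:
    """Smallest image side for which M dyadic scales keep a full SSIM window."""
    return SSIM_WIN * 2 ** (m - 1)


def effective_scales(cfg: LossConfig, shape: tuple[int, int]) -> tuple[int, list[float]]:
    """Reduce M for small patches; renormalize beta to preserve its total."""
    m = cfg.ms_scales
    while m > 1 and min(shape) < min_size_for_scales(m):
        m -= 1
    beta = np.asarray(cfg.beta[:m], dtype=np.float64)
    beta = beta * (sum(cfg.beta) / beta.sum())
    return m, beta.tolist()


def ms_ssim(Y, Ybar, cfg: LossConfig | None = None) -> Tensor:
    """Multi-scale SSIM on [0, 1]-normalized images (differentiable).

    Contrast/structure terms are averaged over valid 11x11 (sigma 1.5)
    Gaussian windows at every scale; the coarsest scale uses the mean of the
    full luminance-times-cs SSIM map, so M = 1 reduces exactly to
    single-scale SSIM.  Scales are linked by 2x2 mean downsampling.
    """
    cfg = cfg or LossConfig()
    y, yb = _as_nchw(Y), _as_nchw(Ybar)
    if y.shape != yb.shape:
        raise InvalidParameterError("images must share a shape")
    m = cfg.ms_scales
    need = min_size_for_scales(m)
    if min(y.shape[2], y.shape[3]) < need:
        raise InvalidParameterError(
            f"image side {min(y.shape[2], y.shape[3])} too small for M={m} scales; "
            f"minimum is {need} px"
        )
    beta = list(cfg.beta)
    k1d = _gauss1d(SSIM_WIN, SSIM_WIN_SIGMA)
    c1, c2 = cfg.c1, cfg.c2
    eps = 1e-8
    result = None
    for j in range(m):
        mu_y = _filter_valid(y, k1d)
        mu_b = _filter_valid(yb, k1d)
        s_yy = ag.sub(_filter_valid(ag.mul(y, y), k1d), ag.mul(mu_y, mu_y))
        s_bb = ag.sub(_filter_valid(ag.mul(yb, yb), k1d), ag.mul(mu_b, mu_b))
        s_yb = ag.sub(_filter_valid(ag.mul(y, yb), k1d), ag.mul(mu_y, mu_b))
        cs_map = ag.div(
            ag.add(ag.mul(s_yb, 2.0), c2), ag.add(ag.add(s_yy, s_bb), c2)
        )
        if j < m - 1:
            term = ag.clamp_min(ag.mean_(cs_map), eps)
            y, yb = ag.avgpool2(y), ag.avgpool2(yb)
        else:
            l_map = ag.div(
                ag.add(ag.mul(ag.mul(mu_y, mu_b), 2.0), c1),
                ag.add(ag.add(ag.mul(mu_y, mu_y), ag.mul(mu_b, mu_b)), c1),
            )
            term = ag.mean_(ag.mul(l_map, cs_map))
            if m == 1 and abs(beta[0] - 1.0) < 1e-12:
                # exact single-scale SSIM (no positivity clamp needed)
                return term
            term = ag.clamp_min(term, eps)
        powed = ag.pow_scalar(term, beta[j])
        result = powed if result is None else ag.mul(result, powed)
    return result


def loss(Y, Ybar, cfg: LossConfig | None = None) -> Tensor:
    """alpha (1 - MS-SSIM) + (1 - alpha) Gaussian-weighted mean absolute error.

    The 9x9 sigma-1.5 Gaussian is unit-sum and applied with reflect boundary
    handling, so a spatially constant error e contributes exactly
    (1 - alpha) e.  M is reduced automatically for patches too small for the
    configured scale count (beta renormalized).
    """
    cfg = cfg or LossConfig()
    y, yb = _as_nchw(Y), _as_nchw(Ybar)
    m, beta = effective_scales(cfg, (y.shape[2], y.shape[3]))
    ms_cfg = LossConfig(
        alpha=cfg.alpha,
        g_kernel_size=cfg.g_kernel_size,
        g_sigma=cfg.g_sigma,
        ms_scales=m,
        beta=beta,
        c1=cfg.c1,
        c2=cfg.c2,
    )
    ms = ms_ssim(y, yb, ms_cfg)
    diff = ag.abs_(ag.sub(y, yb))
    g1d = _gauss1d(cfg.g_kernel_size, cfg.g_sigma)
    padded = ag.pad_reflect2d(diff, cfg.g_kernel_size // 2)
    l1 = ag.mean_(_filter_valid(padded, g1d))
    return ag.add(
        ag.mul(ag.sub(1.0, ms), cfg.alpha), ag.mul(l1, 1.0 - cfg.alpha)
    )


# ---------------------------------------------------------------------------
# Training-pair generation
# ---------------------------------------------------------------------------

@dataclass
class PairDataset:
    """In-memory dataset of (raw frame, SR target) pairs, normalized to [0, 1]."""

    inputs: np.ndarray  # (n, 1, H, W)
    targets: np.ndarray  # (n, 1, 2H, 2W)
    scheme: str
    seed: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    input_max: float
    target_max: float

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def manifest(self) -> dict:
        return {
            "n_pairs": len(self),
            "scheme": self.scheme,
            "seed": self.seed,
            "n_train": int(self.train_idx.size),
            "n_val": int(self.val_idx.size),
            "input_shape": list(self.inputs.shape[2:]),
            "target_shape": list(self.targets.shape[2:]),
            "input_max": self.input_max,
            "target_max": self.target_max,
        }


def _default_psfs(pixel_size_nm: float) -> tuple[PsfKernel, PsfKernel]:
    ex = make_gaussian_psf(pixel_size_nm=pixel_size_nm, role="excitation")
    em = make_gaussian_psf(pixel_size_nm=pixel_size_nm, role="emission")
    return ex, em


def _random_sample(rng: np.random.Generator, size_px: int, pixel_size_nm: float) -> SampleMap:
    """Spoke target with randomized lobe count, or a random structure sample."""
    u = rng.random()
    if u < 0.6:
        return make_spoke_sample(size_px, int(rng.integers(16, 80)), pixel_size_nm)
    style = "filaments" if u < 0.8 else "blobs"
    return make_random_structure_sample(
        size_px, style, int(rng.integers(0, 2**31 - 1)), pixel_size_nm
    )


def _finalize(
    inputs: list[np.ndarray],
    targets: list[np.ndarray],
    scheme: str,
    seed: int,
    split_train: float,
) -> PairDataset:
    x = np.stack(inputs).astype(np.float32)[:, None]
    t = np.stack(targets).astype(np.float32)[:, None]
    input_max = float(x.max())
    target_max = float(t.max())
    if input_max <= 0 or target_max <= 0:
        raise InvalidParameterError("degenerate dataset: all-zero inputs or targets")
    x /= input_max
    t /= target_max
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    n_train = int(round(split_train * len(x)))
    return PairDataset(
        inputs=x,
        targets=t,
        scheme=scheme,
        seed=seed,
        train_idx=order[:n_train],
        val_idx=order[n_train:],
        input_max=input_max,
        target_max=target_max,
    )


def make_training_pairs(
    samples: list[SampleMap] | None = None,
    schedule: IlluminationSchedule | None = None,
    recon_opts: ReconOptions | None = None,
    n_pairs: int = 5120,
    seed: int = 0,
    size_px: int = 64,
    spacing_px: int = 16,
    pixel_size_nm: float = 130.0,
    noise: dict | None = None,
    split_train: float = 0.7,
    scheme: str = "standard",
    defocus_um: float | None = None,
) -> PairDataset:
    """Standard training pairs: noisy raw frame -> single-frame reconstruction.

    Each pair picks a random sample (spoke target with randomized lobe count,
    or a random structure) and a random scan position; the input is the
    Poisson+Gaussian-corrupted raw frame, the target the conventional
    single-frame reconstruction (pinhole, reassign, per-frame
    Richardson–Lucy) of the *noiseless* frame.  Inputs and targets are
    normalized by their dataset maxima (stored for inference); the 70/30
    train/validation split is a seeded shuffle.
    """
    if n_pairs < 2:
        raise InvalidParameterError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = build_schedule((size_px, size_px), spacing_px, 1)
    psf_ex, psf_em = _default_psfs(pixel_size_nm)
    defocus_psf = None
    if defocus_um is not None:
        defocus_psf = make_gaussian_psf(
            pixel_size_nm=pixel_size_nm, defocus_um=defocus_um, role="emission"
        )
    if recon_opts is None:
        recon_opts = ReconOptions(psf_em=psf_em, rl_per_frame=True, rl_iterations=20)
    noise = dict(DEFAULT_NOISE if noise is None else noise)
    inputs, targets = [], []
    while len(inputs) < n_pairs:
        sample = (
            samples[len(inputs) % len(samples)]
            if samples
            else _random_sample(rng, size_px, pixel_size_nm)
        )
        if not np.any(sample.density > 0):
            warnings.warn("skipping all-zero sample")
            continue
        i = int(rng.integers(schedule.n_frames))
        pattern = render_pattern(schedule, i, psf_ex)
        if defocus_psf is not None:
            clean = render_defocus_mixture(sample, pattern, psf_em, defocus_psf)
            clean_target_frame = render_raw_frame(sample, pattern, psf_em)
        else:
            clean = render_raw_frame(sample, pattern, psf_em)
            clean_target_frame = clean
        noisy = corrupt(
            clean,
            noise.get("gauss_sigma", 0.0),
            noise.get("photon_scale"),
            seed=int(rng.integers(2**31 - 1)),
        )
        foci = FociSet(schedule.foci[i].astype(np.float64), "oracle")
        target = reconstruct_single_frame(clean_target_frame, foci, recon_opts).image
        inputs.append(noisy)
        targets.append(target)
    return _finalize(inputs, targets, scheme, seed, split_train)


def make_defocus_pairs(
    samples: list[SampleMap] | None = None,
    n_pairs: int = 5120,
    seed: int = 0,
    size_px: int = 64,
    spacing_px: int = 16,
    pixel_size_nm: float = 130.0,
    defocus_um: float = 3.0,
    noise: dict | None = None,
    split_train: float = 0.7,
) -> PairDataset:
    """Thick-sample pairs: inputs mix in-focus and 3 um defocused emission.

    The defocused copy emulates out-of-focus background; shot noise is
    elevated (low photon budget).  Targets are reconstructed from the
    focused-only render, teaching the network to reject the background.
    """
    return make_training_pairs(
        samples=samples,
        n_pairs=n_pairs,
        seed=seed,
        size_px=size_px,
        spacing_px=spacing_px,
        pixel_size_nm=pixel_size_nm,
        noise=dict(HIGH_NOISE if noise is None else noise),
        split_train=split_train,
        scheme="defocus",
        defocus_um=defocus_um,
    )


def _offset_foci(shape: tuple[int, int], spacing: int, offset: tuple[int, int]) -> np.ndarray:
    rows = np.arange(offset[0] % spacing, shape[0], spacing)
    cols = np.arange(offset[1] % spacing, shape[1], spacing)
    return np.array([(r, c) for r in rows for c in cols], dtype=np.int64)


def make_shifted_pairs(
    samples: list[SampleMap] | SampleMap,
    spacing_px: int = 16,
    seed: int = 0,
    n_pairs: int | None = None,
    pixel_size_nm: float = 130.0,
    noise: dict | None = None,
    split_train: float = 0.7,
) -> PairDataset:
    """Fewer-frames pairs: one step-2 frame in, the 4-shift reconstruction sum out.

    For each base scan position of a step-2 schedule, four raw frames are
    rendered with the lattice at offsets {(0,0),(0,1),(1,0),(1,1)}; the input
    is the noisy (0,0) frame and the target the sum of the four single-frame
    reconstructions, so the network learns to fill in scan positions that the
    fourfold-reduced acquisition skips.
    """
    if spacing_px % 2:
        raise InvalidParameterError("spacing_px must be divisible by 2")
    if isinstance(samples, SampleMap):
        samples = [samples]
    rng = np.random.default_rng(seed)
    shape = samples[0].density.shape
    psf_ex, psf_em = _default_psfs(pixel_size_nm)
    opts = ReconOptions(psf_em=psf_em, rl_per_frame=True, rl_iterations=20)
    noise = dict(DEFAULT_NOISE if noise is None else noise)
    base_offsets = [
        (dy, dx)
        for dy in range(0, spacing_px, 2)
        for dx in range(0, spacing_px, 2)
    ]
    inputs, targets = [], []
    si = 0
    while n_pairs is None or len(inputs) < n_pairs:
        if si >= len(samples):
            if n_pairs is None:
                break
            samples.append(_random_sample(rng, shape[0], pixel_size_nm))
        sample = samples[si]
        si += 1
        for base in base_offsets:
            target = np.zeros((2 * shape[0], 2 * shape[1]))
            input_frame = None
            for sub in ((0, 0), (0, 1), (1, 0), (1, 1)):
                off = (base[0] + sub[0], base[1] + sub[1])
                pts = _offset_foci(shape, spacing_px, off)
                comb = np.zeros(shape)
                comb[pts[:, 0], pts[:, 1]] = 1.0
                from scipy.signal import fftconvolve

                pattern = np.clip(fftconvolve(comb, psf_ex.kernel, mode="same"), 0, None)
                clean = render_raw_frame(sample, pattern, psf_em)
                foci = FociSet(pts.astype(np.float64), "oracle")
                target += reconstruct_single_frame(clean, foci, opts).image
                if sub == (0, 0):
                    input_frame = corrupt(
                        clean,
                        noise.get("gauss_sigma", 0.0),
                        noise.get("photon_scale"),
                        seed=int(rng.integers(2**31 - 1)),
                    )
            inputs.append(input_frame)
            targets.append(target)
            if n_pairs is not None and len(inputs) >= n_pairs:
                break
    return _finalize(inputs, targets, "shifted4", seed, split_train)


# ---------------------------------------------------------------------------
# Training loop and inference
# ---------------------------------------------------------------------------

def _eval_loss(model: MsimNet, dataset: PairDataset, idx: np.ndarray,
               loss_cfg: LossConfig, batch: int) -> float:
    model.eval()
    total, n = 0.0, 0
    for s in range(0, idx.size, batch):
        sel = idx[s : s + batch]
        pred = model(Tensor(dataset.inputs[sel]))
        lval = loss(pred, Tensor(dataset.targets[sel]), loss_cfg).item()
        total += lval * sel.size
        n += sel.size
    return total / max(n, 1)


def train(
    model: MsimNet,
    dataset: PairDataset,
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> tuple[MsimNet, list[dict]]:
    """Adam training with per-epoch validation; the best-validation weights win.

    ``history[0]`` records the validation loss of the untrained model; each
    subsequent entry holds the mean train loss and validation loss of one
    epoch.  A NaN loss aborts with a diagnostic.  The model is left loaded
    with the best-validation checkpoint.
    """
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    if dataset.train_idx.size == 0 or dataset.val_idx.size == 0:
        raise InvalidParameterError("both train and validation splits must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = ag.Adam(model.parameters(), lr=cfg.lr)
    history: list[dict] = []
    val0 = _eval_loss(model, dataset, dataset.val_idx, loss_cfg, cfg.batch)
    history.append({"epoch": 0, "train_loss": float("nan"), "val_loss": val0})
    best_val, best_state = val0, model.state_dict()
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        order = rng.permutation(dataset.train_idx)
        ep_loss, nb = 0.0, 0
        for s in range(0, order.size, cfg.batch):
            sel = order[s : s + cfg.batch]
            opt.zero_grad()
            pred = model(Tensor(dataset.inputs[sel]))
            lt = loss(pred, Tensor(dataset.targets[sel]), loss_cfg)
            lval = lt.item()
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at epoch {epoch}, batch {nb}: "
                    "reduce the learning rate or check input normalization"
                )
            lt.backward()
            opt.step()
            ep_loss += lval
            nb += 1
        val = _eval_loss(model, dataset, dataset.val_idx, loss_cfg, cfg.batch)
        history.append({"epoch": epoch, "train_loss": ep_loss / max(nb, 1), "val_loss": val})
        if val < best_val:
            best_val, best_state = val, model.state_dict()
    model.load_state_dict(best_state)
    model.eval()
    return model, history


def save_checkpoint(
    model: MsimNet, path, input_max: float = 1.0, target_max: float = 1.0
) -> None:
    """Serialize weights, buffers, the architecture config, and normalization."""
    meta = json.dumps(
        {
            "config": model.config.to_dict(),
            "input_max": input_max,
            "target_max": target_max,
        }
    )
    np.savez(path, __meta__=np.array(meta), **model.state_dict())


def load_checkpoint(path) -> tuple[MsimNet, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = MsimNet(NetworkConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    model.eval()
    return model, {"input_max": meta["input_max"], "target_max": meta["target_max"]}


def infer_stack(
    model: MsimNet,
    stack: RawStack,
    input_max: float = 1.0,
    target_max: float = 1.0,
) -> SRImage:
    """Per-frame forward pass in evaluation mode, summed into one SR image.

    Frames are divided by the stored training normalization before the
    forward pass and outputs rescaled by the target normalization.  Frames
    whose dimensions are not divisible by 8 are reflect-padded and the output
    cropped back (with a warning).
    """
    model.eval()
    m, H, W = stack.frames.shape
    pad_h = (-H) % 8
    pad_w = (-W) % 8
    if pad_h or pad_w:
        warnings.warn(
            f"frame dims ({H}, {W}) not divisible by 8; reflect-padding to "
            f"({H + pad_h}, {W + pad_w}) and cropping the output"
        )
    acc = np.zeros((2 * H, 2 * W), dtype=np.float64)
    for i in range(m):
        frame = stack.frames[i] / input_max
        if pad_h or pad_w:
            frame = np.pad(frame, ((0, pad_h), (0, pad_w)), mode="reflect")
        out = model(Tensor(frame.astype(np.float32)[None, None])).data[0, 0]
        acc += out[: 2 * H, : 2 * W].astype(np.float64) * target_max
    return SRImage(
        image=np.clip(acc, 0.0, None),
        pixel_size_nm=stack.pixel_size_nm / 2.0,
        provenance="deep",
        n_frames_used=m,
    )
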