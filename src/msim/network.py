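"""Dense-skip encoder–decoder network mapping a raw multifocal frame to a 2x SR image.

A U-net-style architecture: four two-conv encoder stages (three 2x2 max-pool
reductions, the fourth stage acting as bottleneck), three decoder stages that
upsample by nearest-neighbor interpolation followed by a channel-halving 1x1
convolution, and skip connections routed through DenseNet-style dense blocks
of configurable depth L and growth rate k instead of plain concatenation.  A
final output block upsamples once more and maps the 32 feature channels to a
single nonnegative grayscale channel, so a W x H input frame yields a 2W x 2H
super-resolution image — matching the 2x "local scaling" of conventional
pixel-reassignment reconstruction.

Ablation toggles cover plain-concatenation and residual skips, transposed
convolution upsampling, and removal of batch normalization or dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Module, Tensor

__all__ = ["NetworkConfig", "MsimNet"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``dense_configs`` are ordered from the deepest skip (encoder stage 3) to
    the shallowest (stage 1); each entry is a dict with keys ``L`` (number of
    dense layers; 0 = identity pass-through) and ``k`` (growth rate, required
    when L > 0).
    """

    encoder_widths: list[int] = field(default_factory=lambda: [32, 64, 128, 256])
    dense_configs: list[dict] = field(
        default_factory=lambda: [{"L": 0}, {"L": 3, "k": 32}, {"L": 5, "k": 8}]
    )
    dropout_p: float = 0.5
    conv_kernel: int = 3
    skip_mode: str = "dense"  # "dense" | "concat" | "residual"
    upsample_mode: str = "nearest"  # "nearest" | "transposed"
    use_bn: bool = True
    use_dropout: bool = True
    output_kernels: tuple[int, int] = (3, 1)

    def __post_init__(self) -> None:
        if len(self.encoder_widths) != 4:
            raise ValueError("encoder_widths must list exactly 4 stages")
        if len(self.dense_configs) != 3:
            raise ValueError("dense_configs must list exactly 3 skip connections")
        for cfg in self.dense_configs:
            if cfg.get("L", 0) > 0 and "k" not in cfg:
                raise ValueError("growth rate k required when L > 0")
        if self.skip_mode not in ("dense", "concat", "residual"):
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}")
        if self.upsample_mode not in ("nearest", "transposed"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    @classmethod
    def small(cls) -> "NetworkConfig":
        """Reduced-width preset for CPU-scale training studies."""
        return cls(
            encoder_widths=[6, 12, 16, 16],
            dense_configs=[{"L": 0}, {"L": 1, "k": 8}, {"L": 1, "k": 4}],
            use_dropout=False,
        )

    def to_dict(self) -> dict:
        return {
            "encoder_widths": list(self.encoder_widths),
            "dense_configs": [dict(c) for c in self.dense_configs],
            "dropout_p": self.dropout_p,
            "conv_kernel": self.conv_kernel,
            "skip_mode": self.skip_mode,
            "upsample_mode": self.upsample_mode,
            "use_bn": self.use_bn,
            "use_dropout": self.use_dropout,
            "output_kernels": tuple(self.output_kernels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["output_kernels"] = tuple(d.get("output_kernels", (3, 1)))
        return cls(**d)


class ConvBNReLU(Module):
    def __init__(self, c_in, c_out, k, rng, use_bn=True):
        super().__init__()
        self.conv = ag.Conv2d(c_in, c_out, k, pad=k // 2, rng=rng)
        self.bn = ag.BatchNorm2d(c_out) if use_bn else None

    def __call__(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return ag.relu(x)


class DownBlock(Module):
    """Two Conv(3x3)-BN-ReLU stages; pooling happens between blocks, not inside."""

    def __init__(self, c_in, width, k, rng, use_bn=True):
        super().__init__()
        self.c1 = ConvBNReLU(c_in, width, k, rng, use_bn)
        self.c2 = ConvBNReLU(width, width, k, rng, use_bn)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x))


class _BnReluConv(Module):
    """Pre-activation convolution: BN-ReLU-Conv (BN optional)."""

    def __init__(self, c_in, c_out, k, rng, use_bn=True):
        super().__init__()
        self.bn = ag.BatchNorm2d(c_in) if use_bn else None
        self.conv = ag.Conv2d(c_in, c_out, k, pad=k // 2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        if self.bn is not None:
            x = self.bn(x)
        return self.conv(ag.relu(x))


class DenseConnection(Module):
    """Dense block on a skip path: X_l = H_l(Concat(X_0 ... X_{l-1})).

    L = 0 is an identity pass-through.  Otherwise an initial 3x3 convolution
    produces X_0 (same channel count as the input); each of the L bottleneck
    layers (BN-ReLU-Conv1x1 -> BN-ReLU-Conv3x3) emits k channels from the
    concatenation of all predecessors; a transition layer
    (BN-ReLU-Conv1x1-BN-ReLU) restores the input channel count.
    """

    def __init__(self, c: int, L: int, k: int | None, rng, use_bn=True):
        super().__init__()
        self.L = L
        if L == 0:
            return
        self.initial = ag.Conv2d(c, c, 3, pad=1, rng=rng)
        layers = []
        for l in range(L):
            c_in = c + l * k
            layers.append(_BnReluConv(c_in, k, 1, rng, use_bn))
            layers.append(_BnReluConv(k, k, 3, rng, use_bn))
        self.bottlenecks = layers
        self.trans = _BnReluConv(c + L * k, c, 1, rng, use_bn)
        self.trans_bn = ag.BatchNorm2d(c) if use_bn else None

    def __call__(self, x: Tensor) -> Tensor:
        if self.L == 0:
            return x
        feats = [self.initial(x)]
        for l in range(self.L):
            h = ag.concat(feats, axis=1) if len(feats) > 1 else feats[0]
            h = self.bottlenecks[2 * l](h)
            h = self.bottlenecks[2 * l + 1](h)
            feats.append(h)
        out = self.trans(ag.concat(feats, axis=1))
        if self.trans_bn is not None:
            out = self.trans_bn(out)
        return ag.relu(out)


class ResidualSkip(Module):
    """Residual block alternative for the ablation study (channels preserved)."""

    def __init__(self, c: int, rng, use_bn=True):
        super().__init__()
        self.c1 = ConvBNReLU(c, c, 3, rng, use_bn)
        self.conv2 = ag.Conv2d(c, c, 3, pad=1, rng=rng)
        self.bn2 = ag.BatchNorm2d(c) if use_bn else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.c1(x))
        if self.bn2 is not None:
            h = self.bn2(h)
        return ag.relu(ag.add(h, x))


class UpBlock(Module):
    """Decoder stage: upsample 2x, halve channels, merge the (dense) skip, convolve."""

    def __init__(self, c_in, skip_c, c_out, k, dense_cfg, cfg: NetworkConfig, rng):
        super().__init__()
        half = max(c_in // 2, 1)
        self.mode = cfg.upsample_mode
        if self.mode == "nearest":
            self.reduce = ag.Conv2d(c_in, half, 1, pad=0, rng=rng)
        else:
            self.up = ag.ConvTranspose2x2(c_in, half, rng=rng)
        if cfg.skip_mode == "dense":
            self.skip = DenseConnection(
                skip_c, dense_cfg.get("L", 0), dense_cfg.get("k"), rng, cfg.use_bn
            )
        elif cfg.skip_mode == "residual":
            self.skip = ResidualSkip(skip_c, rng, cfg.use_bn)
        else:
            self.skip = None
        self.c1 = ConvBNReLU(half + skip_c, c_out, k, rng, cfg.use_bn)
        self.c2 = ConvBNReLU(c_out, c_out, k, rng, cfg.use_bn)

    def __call__(self, x: Tensor, skip_feat: Tensor) -> Tensor:
        if self.mode == "nearest":
            x = self.reduce(ag.upsample_nearest2(x))
        else:
            x = self.up(x)
        s = self.skip(skip_feat) if self.skip is not None else skip_feat
        h = ag.concat([s, x], axis=1)
        return self.c2(self.c1(h))


class OutputBlock(Module):
    """Nearest-neighbor 2x upsampling then a 3x3 and a 1x1 convolution to 1 channel.

    The extra upsampling implements the 2x rescaling of the local-scaling
    step; the final ReLU guarantees a nonnegative image.
    """

    def __init__(self, c_in, kernels, rng, use_bn=True):
        super().__init__()
        k1, k2 = kernels
        self.c1 = ConvBNReLU(c_in, c_in, k1, rng, use_bn)
        self.c2 = ag.Conv2d(c_in, 1, k2, pad=k2 // 2, rng=rng)
        # start the final ReLU alive: an all-negative pre-activation at init
        # would zero every gradient and freeze the network permanently
        self.c2.bias.data[:] = 0.1

    def __call__(self, x: Tensor) -> Tensor:
        x = self.c1(ag.upsample_nearest2(x))
        return ag.relu(self.c2(x))


class MsimNet(Module):
    """The full raw-frame -> super-resolution network."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or NetworkConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        w = cfg.encoder_widths
        k = cfg.conv_kernel
        self.d1 = DownBlock(1, w[0], k, rng, cfg.use_bn)
        self.d2 = DownBlock(w[0], w[1], k, rng, cfg.use_bn)
        self.d3 = DownBlock(w[1], w[2], k, rng, cfg.use_bn)
        self.d4 = DownBlock(w[2], w[3], k, rng, cfg.use_bn)
        # dense_configs[0] serves the deepest skip (d3), [2] the shallowest (d1)
        self.u1 = UpBlock(w[3], w[2], w[2], k, cfg.dense_configs[0], cfg, rng)
        self.u2 = UpBlock(w[2], w[1], w[1], k, cfg.dense_configs[1], cfg, rng)
        self.u3 = UpBlock(w[1], w[0], w[0], k, cfg.dense_configs[2], cfg, rng)
        self.drop = (
            ag.Dropout(cfg.dropout_p, self._dropout_rng) if cfg.use_dropout else None
        )
        self.out = OutputBlock(w[0], cfg.output_kernels, rng, cfg.use_bn)

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim == 2:
            x = ag.reshape(x, (1, 1, *x.shape))
        N, C, H, W = x.shape
        if H % 8 or W % 8:
            raise ValueError(
                f"input spatial dims ({H}, {W}) must be divisible by 8 "
                "(three pooling stages); pad the frame first"
            )
        e1 = self.d1(x)
        e2 = self.d2(ag.maxpool2(e1))
        e3 = self.d3(ag.maxpool2(e2))
        e4 = self.d4(ag.maxpool2(e3))
        h = self.u1(e4, e3)
        if self.drop is not None:
            h = self.drop(h)
        h = self.u2(h, e2)
        if self.drop is not None:
            h = self.drop(h)
        h = self.u3(h, e1)
        return self.out(h)

    forward = __call__
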