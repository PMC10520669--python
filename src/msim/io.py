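"""File formats, run configuration, and deterministic fixtures.

Raw stacks and SR images travel as multi-page TIFF (float32 internally,
uint8/uint16 accepted on read) with a JSON sidecar carrying the acquisition
geometry (lattice spacing, scan step, pixel size, noise, seed) so a stack can
be round-tripped losslessly together with its schedule.  Run configuration is
YAML or JSON with a strict schema: unknown keys are rejected with their
dotted path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simulate import (
    InvalidParameterError,
    RawStack,
    build_schedule,
    make_gaussian_psf,
    make_spoke_sample,
    simulate_stack,
    SampleMap,
)

__all__ = [
    "UnsupportedFormatError",
    "ConfigError",
    "read_stack",
    "write_stack",
    "write_image",
    "read_image",
    "load_config",
    "default_config",
    "FixtureSet",
    "make_fixtures",
    "save_pseudocolor",
]

log = logging.getLogger("msim")


class UnsupportedFormatError(ValueError):
    """Raised for multi-channel / RGB TIFF input."""


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: RawStack, path, dtype: str = "float32") -> None:
    """Write a raw stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    frames = stack.frames
    if dtype == "float32":
        data = frames.astype(np.float32)
        scale = 1.0
    elif dtype == "uint16":
        scale = 65535.0 / frames.max() if frames.max() > 0 else 1.0
        data = np.round(frames * scale).astype(np.uint16)
    else:
        raise UnsupportedFormatError(f"unsupported export dtype {dtype!r}")
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "n_frames": int(frames.shape[0]),
        "frame_shape": list(frames.shape[1:]),
        "pixel_size_nm": stack.pixel_size_nm,
        "noise": stack.noise,
        "seed": stack.seed,
        "scale": scale,
    }
    if stack.schedule is not None:
        meta["spacing_px"] = stack.schedule.spacing_px
        meta["step_px"] = stack.schedule.step_px
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> RawStack:
    """Read a multi-page single-channel TIFF stack (+ sidecar if present)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise UnsupportedFormatError("RGB/multi-channel TIFF input is not supported")
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise UnsupportedFormatError("expected a single-channel multi-page TIFF")
    if arr.dtype not in (np.uint8, np.uint16, np.float32, np.float64):
        raise UnsupportedFormatError(f"unsupported TIFF dtype {arr.dtype}")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    frames = arr.astype(np.float64)
    if meta.get("scale", 1.0) not in (1.0, None):
        frames = frames / meta["scale"]
    schedule = None
    if "spacing_px" in meta:
        schedule = build_schedule(
            tuple(meta["frame_shape"]), meta["spacing_px"], meta["step_px"]
        )
        if schedule.n_frames != frames.shape[0]:
            schedule = None
    return RawStack(
        frames=frames,
        schedule=schedule,
        pixel_size_nm=float(meta.get("pixel_size_nm", 130.0)),
        noise=meta.get("noise", {}),
        seed=meta.get("seed"),
    )


def write_image(img: np.ndarray, path, pixel_size_nm: float | None = None,
                provenance: dict | None = None) -> None:
    """Write a single 2D image as float32 TIFF with an optional JSON sidecar."""
    tifffile.imwrite(Path(path), np.asarray(img, dtype=np.float32),
                     photometric="minisblack")
    if provenance is not None or pixel_size_nm is not None:
        meta = dict(provenance or {})
        if pixel_size_nm is not None:
            meta["pixel_size_nm"] = pixel_size_nm
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_image(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise UnsupportedFormatError("expected a single 2D image")
    return arr.astype(np.float64)


def save_pseudocolor(img: np.ndarray, path, cmap: str = "magma") -> None:
    """Optional pseudocolored PNG export for visualization (never quantitative)."""
    import matplotlib.image

    img = np.asarray(img, dtype=np.float64)
    rng = img.max() - img.min()
    norm = (img - img.min()) / rng if rng > 0 else np.zeros_like(img)
    matplotlib.image.imsave(Path(path), norm, cmap=cmap)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    return {
        "seed": 0,
        "log_level": "INFO",
        "simulate": {
            "sample": "spoke",
            "size": 256,
            "n_lobes": 48,
            "spacing": 16,
            "step": 1,
            "pixel_size_nm": 130.0,
            "gauss_sigma": 0.002,
            "photon_scale": 4000.0,
        },
        "network": {
            "encoder_widths": [32, 64, 128, 256],
            "dense_configs": [{"L": 0}, {"L": 3, "k": 32}, {"L": 5, "k": 8}],
            "dropout_p": 0.5,
            "conv_kernel": 3,
            "skip_mode": "dense",
            "upsample_mode": "nearest",
            "use_bn": True,
            "use_dropout": True,
            "output_kernels": [3, 1],
        },
        "loss": {
            "alpha": 0.75,
            "g_kernel_size": 9,
            "g_sigma": 1.5,
            "ms_scales": 5,
            "beta": [0.1, 0.3, 0.3, 0.2, 0.1],
        },
        "train": {
            "lr": 1e-3,
            "epochs": 50,
            "batch": 8,
            "split_train": 0.7,
            "n_pairs": 5120,
        },
        "reconstruct": {
            "foci_mode": "oracle",
            "pinhole_sigma_px": None,
            "denoise_sigma": 1.0,
            "threshold_frac": 0.3,
            "rl_iterations": 20,
            "rl_per_frame": False,
        },
        "evaluate": {"bit_depth": 8},
    }


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in (user or {}).items():
        dotted = f"{path}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {dotted}")
        if isinstance(defaults[key], dict) and key != "dense_configs":
            if not isinstance(value, dict):
                raise ConfigError(f"section {dotted} must be a mapping")
            out[key] = _merge(defaults[key], value, dotted + ".")
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load YAML/JSON run configuration, fill defaults, reject unknown keys."""
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError("configuration root must be a mapping")
    cfg = _merge(default_config(), user)
    if overrides:
        cfg = _merge(cfg, overrides)
    log.debug("resolved config: %s", json.dumps(cfg))
    return cfg


def dump_config(cfg: dict, out_path) -> None:
    """Serialize the resolved configuration next to a produced artifact."""
    Path(str(out_path) + ".config.json").write_text(json.dumps(cfg, indent=1))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureSet:
    """Named deterministic instances with content hashes, for tests and demos."""

    entries: dict  # name -> {"path": str, "sha256": str}

    def hash_of(self, name: str) -> str:
        return self.entries[name]["sha256"]


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr, dtype=np.float32).tobytes()).hexdigest()


def make_fixtures(outdir, seed: int = 0) -> FixtureSet:
    """Generate the small named instances used by the test-suite and examples.

    spoke-64: 64 px default spoke target; bead-64: single point emitter;
    stack-64-s8: noisy 64-frame stack at lattice spacing 8, unit step.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}

    spoke = make_spoke_sample(64, 48)
    p = outdir / "spoke-64.tif"
    write_image(spoke.density, p)
    entries["spoke-64"] = {"path": str(p), "sha256": _digest(spoke.density)}

    bead = np.zeros((64, 64))
    bead[32, 32] = 1.0
    p = outdir / "bead-64.tif"
    write_image(bead, p)
    entries["bead-64"] = {"path": str(p), "sha256": _digest(bead)}

    schedule = build_schedule((64, 64), 8, 1)
    psf_ex = make_gaussian_psf(role="excitation")
    psf_em = make_gaussian_psf(role="emission")
    stack = simulate_stack(
        spoke, schedule, psf_ex, psf_em,
        noise={"gauss_sigma": 0.002, "photon_scale": 4000.0}, seed=seed,
    )
    p = outdir / "stack-64-s8.tif"
    write_stack(stack, p)
    entries["stack-64-s8"] = {"path": str(p), "sha256": _digest(stack.frames)}

    return FixtureSet(entries=entries)
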