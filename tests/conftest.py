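import numpy as np
import pytest

from msim.simulate import (
    build_schedule,
    make_gaussian_psf,
    make_spoke_sample,
    simulate_stack,
)


@pytest.fixture(scope="session")
def psf_ex():
    return make_gaussian_psf(role="excitation")


@pytest.fixture(scope="session")
def psf_em():
    return make_gaussian_psf(role="emission")


@pytest.fixture(scope="session")
def spoke64():
    return make_spoke_sample(64, 48)


@pytest.fixture(scope="session")
def schedule_64_16():
    return build_schedule((64, 64), 16, 1)


@pytest.fixture(scope="session")
def noiseless_stack64(spoke64, schedule_64_16, psf_ex, psf_em):
    return simulate_stack(spoke64, schedule_64_16, psf_ex, psf_em, noise=None)


def brute_force_frame(sample: np.ndarray, pattern: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct O(N^2 K^2) evaluation of I(x) = sum_u p(u) s(u) h(x - u), zero padded."""
    H, W = sample.shape
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    excited = pattern * sample
    out = np.zeros((H, W))
    for uy in range(H):
        for ux in range(W):
            v = excited[uy, ux]
            if v == 0.0:
                continue
            for dy in range(-rh, rh + 1):
                for dx in range(-rw, rw + 1):
                    y, x = uy + dy, ux + dx
                    if 0 <= y < H and 0 <= x < W:
                        out[y, x] += v * kernel[rh + dy, rw + dx]
    return out
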