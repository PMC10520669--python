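"""Conventional reconstruction tests: detection, pinholing, reassignment, RL."""

import numpy as np
import pytest

from msim.reconstruct import (
    FociSet,
    NoFociError,
    ReconOptions,
    apply_pinholes,
    detect_lattice,
    reassign_frame,
    reconstruct_conventional,
    reconstruct_single_frame,
    richardson_lucy,
    sum_stack,
)
from msim.simulate import (
    IlluminationSchedule,
    InvalidParameterError,
    PsfKernel,
    SampleMap,
    build_schedule,
    make_gaussian_psf,
    render_pattern,
    render_raw_frame,
    simulate_stack,
    widefield,
)
from msim.metrics import fwhm


def interior_schedule(shape=(64, 64), spacing=16, offsets=((6, 6), (6, 10), (10, 6), (10, 10))):
    """Hand-built schedule whose foci all sit well away from the borders."""
    foci = []
    for off in offsets:
        rows = np.arange(off[0], shape[0] - spacing // 2, spacing)
        cols = np.arange(off[1], shape[1] - spacing // 2, spacing)
        foci.append(np.array([(r, c) for r in rows for c in cols], dtype=np.int64))
    return IlluminationSchedule(
        frame_shape=shape,
        spacing_px=spacing,
        step_px=spacing // 2,
        n_frames=len(offsets),
        foci=foci,
        scan_offsets=list(offsets),
    )


def brute_force_reassign(frame: np.ndarray, foci: np.ndarray) -> np.ndarray:
    """Half-distance pixel reassignment mapped onto the doubled grid."""
    H, W = frame.shape
    out = np.zeros((2 * H, 2 * W))
    for y in range(H):
        for x in range(W):
            d2 = (foci[:, 0] - y) ** 2 + (foci[:, 1] - x) ** 2
            cand = np.flatnonzero(np.isclose(d2, d2.min()))
            # ties toward the lexicographically smallest focus coordinate
            order = np.lexsort((foci[cand, 1], foci[cand, 0]))
            b = foci[cand[order[0]]]
            # destination (x + b)/2 in original units = x + b on the 2x grid
            rr = int(round(y + b[0]))
            cc = int(round(x + b[1]))
            out[min(rr, 2 * H - 1), min(cc, 2 * W - 1)] += frame[y, x]
    return out


class TestDetectLattice:
    def test_recovers_oracle_foci_exactly(self, psf_ex, psf_em):
        sch = interior_schedule()
        uniform = SampleMap(np.ones((64, 64)), 130.0)
        pat = render_pattern(sch, 0, psf_ex)
        frame = render_raw_frame(uniform, pat, psf_em)
        det = detect_lattice(frame, expected_spacing_px=16)
        assert det.coords.shape[0] == sch.foci[0].shape[0]
        assert np.array_equal(np.sort(det.coords, axis=0), np.sort(sch.foci[0].astype(float), axis=0))

    def test_detected_count_on_full_lattice(self, psf_ex, psf_em, spoke64):
        sch = build_schedule((64, 64), 16, 1)
        idx = sch.scan_offsets.index((8, 8))
        uniform = SampleMap(np.ones((64, 64)), 130.0)
        frame = render_raw_frame(uniform, render_pattern(sch, idx, psf_ex), psf_em)
        det = detect_lattice(frame, 16)
        assert det.coords.shape[0] == (64 // 16) ** 2

    def test_all_zero_frame(self):
        with pytest.raises(NoFociError):
            detect_lattice(np.zeros((64, 64)), 16)


class TestPinholes:
    def test_value_at_focus_unchanged(self):
        frame = np.random.default_rng(0).random((32, 32)) + 1.0
        foci = FociSet(np.array([[10.0, 12.0]]))
        out = apply_pinholes(frame, foci, pinhole_sigma_px=2.0)
        assert out[10, 12] == pytest.approx(frame[10, 12])

    def test_far_pixels_heavily_attenuated(self):
        frame = np.ones((32, 32))
        foci = FociSet(np.array([[16.0, 16.0]]))
        out = apply_pinholes(frame, foci, pinhole_sigma_px=2.0)
        d = np.hypot(np.arange(32)[:, None] - 16, np.arange(32)[None] - 16)
        assert np.all(out[d >= 6.0] <= 0.02)

    def test_total_never_increases(self):
        frame = np.random.default_rng(1).random((32, 32))
        foci = FociSet(np.array([[8.0, 8.0], [24.0, 24.0]]))
        out = apply_pinholes(frame, foci, 1.5)
        assert out.sum() <= frame.sum()
        assert np.all(out <= frame + 1e-15)

    def test_nonpositive_sigma(self):
        with pytest.raises(InvalidParameterError):
            apply_pinholes(np.ones((16, 16)), FociSet(np.array([[4.0, 4.0]])), 0.0)


class TestReassignment:
    def test_pixel_at_focus_maps_to_doubled_position(self):
        frame = np.zeros((16, 16))
        frame[5, 7] = 3.0
        out = reassign_frame(frame, FociSet(np.array([[5.0, 7.0]])))
        assert out[10, 14] == 3.0
        assert out.sum() == 3.0

    def test_half_distance_displacement(self):
        frame = np.zeros((16, 16))
        frame[5, 10] = 1.0  # displaced d = (0, 3) from the focus at (5, 7)
        out = reassign_frame(frame, FociSet(np.array([[5.0, 7.0]])))
        assert out[10, 17] == 1.0  # 2b + d

    @pytest.mark.parametrize("n_foci", [1, 4])
    def test_matches_brute_force_oracle(self, n_foci):
        rng = np.random.default_rng(42)
        for trial in range(5):
            frame = rng.random((32, 32))
            foci = rng.integers(2, 30, size=(n_foci, 2)).astype(float)
            got = reassign_frame(frame, FociSet(foci.copy()))
            want = brute_force_reassign(frame, foci)
            assert np.array_equal(got, want)

    def test_flux_conserved_exactly(self):
        rng = np.random.default_rng(7)
        frame = rng.random((32, 32))
        foci = FociSet(np.array([[8.0, 8.0], [8.0, 24.0], [24.0, 8.0], [24.0, 24.0]]))
        out = reassign_frame(frame, foci)
        assert out.sum() == pytest.approx(frame.sum(), rel=1e-12)
        assert out.shape == (64, 64)


class TestSumStack:
    def test_identities(self):
        rng = np.random.default_rng(0)
        frames = rng.random((5, 8, 8))
        s = sum_stack(frames)
        assert np.array_equal(sum_stack(frames[[0]]), frames[0])
        assert np.allclose(s, sum_stack(frames[::-1]))
        assert s.sum() == pytest.approx(frames.sum(), rel=1e-9)
        with pytest.raises(InvalidParameterError):
            sum_stack(np.empty((0, 8, 8)))


class TestRichardsonLucy:
    def test_zero_iterations_identity(self, psf_em):
        img = np.random.default_rng(0).random((33, 33))
        assert np.array_equal(richardson_lucy(img, psf_em, 0), img)

    def test_flux_approximately_conserved(self, psf_em):
        img = np.zeros((48, 48))
        img[20:28, 20:28] = np.random.default_rng(1).random((8, 8)) + 0.5
        from scipy.signal import fftconvolve

        blurred = np.clip(fftconvolve(img, psf_em.kernel, mode="same"), 0, None)
        out = richardson_lucy(blurred, psf_em, 20)
        assert out.sum() == pytest.approx(blurred.sum(), rel=0.01)

    def test_peak_sharpening_on_blurred_point(self, psf_em):
        img = np.zeros((33, 33))
        r = psf_em.kernel.shape[0] // 2
        img[16 - r : 16 + r + 1, 16 - r : 16 + r + 1] = psf_em.kernel
        out = richardson_lucy(img, psf_em, 20)
        assert out.max() > img.max()

    def test_unnormalized_kernel_rejected(self):
        bad = PsfKernel(np.ones((3, 3)) / 9.0, 1.0, 560.0, 1.1)
        bad.kernel = bad.kernel * 2.0
        with pytest.raises(InvalidParameterError):
            richardson_lucy(np.ones((16, 16)), bad, 5)


class TestFullPipeline:
    def test_output_dimensions_doubled(self, spoke64, psf_ex, psf_em):
        sch = build_schedule((64, 64), 16, 2)
        stack = simulate_stack(spoke64, sch, psf_ex, psf_em, noise=None)
        sr = reconstruct_conventional(stack, ReconOptions(psf_em=psf_em))
        assert sr.image.shape == (128, 128)
        assert sr.pixel_size_nm == pytest.approx(spoke64.pixel_size_nm / 2)
        assert sr.provenance == "conventional"

    def test_deterministic(self, spoke64, psf_ex, psf_em):
        sch = build_schedule((64, 64), 16, 2)
        stack = simulate_stack(spoke64, sch, psf_ex, psf_em, noise=None)
        a = reconstruct_conventional(stack, ReconOptions(psf_em=psf_em))
        b = reconstruct_conventional(stack, ReconOptions(psf_em=psf_em))
        assert np.array_equal(a.image, b.image)

    def test_detected_equals_oracle_on_clean_interior_lattice(self, psf_ex, psf_em):
        sch = interior_schedule()
        sample = SampleMap(0.5 + 0.5 * np.random.default_rng(0).random((64, 64)), 130.0)
        stack = simulate_stack(sample, sch, psf_ex, psf_em, noise=None)
        oracle = reconstruct_conventional(stack, ReconOptions(psf_em=psf_em, foci_mode="oracle"))
        detected = reconstruct_conventional(stack, ReconOptions(psf_em=psf_em, foci_mode="detected"))
        assert np.abs(oracle.image - detected.image).max() <= 1e-6 * oracle.image.max()

    def test_single_frame_sum_equals_stack_reconstruction(self, spoke64, psf_ex, psf_em):
        sch = build_schedule((64, 64), 16, 4)
        stack = simulate_stack(spoke64, sch, psf_ex, psf_em, noise=None)
        opts = ReconOptions(psf_em=psf_em, rl_iterations=0)
        total = np.zeros((128, 128))
        for i in range(sch.n_frames):
            foci = FociSet(sch.foci[i].astype(float), "oracle")
            total += reconstruct_single_frame(stack.frames[i], foci, opts).image
        full = reconstruct_conventional(stack, opts)
        assert np.abs(total - full.image).max() < 1e-9

    def test_zero_frame_single_reconstruction(self, psf_em):
        opts = ReconOptions(psf_em=psf_em, rl_iterations=0)
        out = reconstruct_single_frame(
            np.zeros((32, 32)), FociSet(np.array([[8.0, 8.0]])), opts
        )
        assert np.all(out.image == 0)

    def test_adding_frames_never_decreases_total(self, spoke64, psf_ex, psf_em):
        sch = build_schedule((64, 64), 16, 4)
        stack = simulate_stack(spoke64, sch, psf_ex, psf_em, noise=None)
        opts = ReconOptions(psf_em=psf_em, rl_iterations=0)
        totals = []
        acc = np.zeros((128, 128))
        for i in range(sch.n_frames):
            foci = FociSet(sch.foci[i].astype(float), "oracle")
            acc = acc + reconstruct_single_frame(stack.frames[i], foci, opts).image
            totals.append(acc.sum())
        assert np.all(np.diff(totals) >= 0)


class TestResolutionGain:
    def test_point_emitter_fwhm_improves(self):
        """Pixel reassignment + deconvolution must beat wide-field resolution."""
        px = 65.0  # finer sampling keeps the FWHM estimate stable
        psf_ex = make_gaussian_psf(pixel_size_nm=px, role="excitation")
        psf_em = make_gaussian_psf(pixel_size_nm=px, role="emission")
        point = np.zeros((64, 64))
        point[32, 32] = 1.0
        sample = SampleMap(point, px)
        sch = build_schedule((64, 64), 16, 1)
        stack = simulate_stack(sample, sch, psf_ex, psf_em, noise=None)
        wf = widefield(stack)
        fwhm_wf = fwhm(wf[32], spacing_nm=px)
        sr = reconstruct_conventional(stack, ReconOptions(psf_em=psf_em))
        peak = np.unravel_index(np.argmax(sr.image), sr.image.shape)
        fwhm_sr = fwhm(sr.image[peak[0]], spacing_nm=px / 2)
        assert fwhm_sr <= 0.8 * fwhm_wf
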