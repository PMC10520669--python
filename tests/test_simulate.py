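"""Forward-model tests: samples, PSFs, schedules, rendering, noise."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve

from msim.simulate import (
    InvalidParameterError,
    PsfKernel,
    build_schedule,
    corrupt,
    make_gaussian_psf,
    make_random_structure_sample,
    make_spoke_sample,
    render_defocus_mixture,
    render_pattern,
    render_raw_frame,
    simulate_stack,
    widefield,
)
from conftest import brute_force_frame


def circle_profile(density: np.ndarray, radius: float, n: int = 3600) -> np.ndarray:
    c = float(density.shape[0] // 2)
    ang = np.deg2rad(np.arange(n) * 360.0 / n)
    rows = c + radius * np.sin(ang)
    cols = c + radius * np.cos(ang)
    return map_coordinates(density, [rows, cols], order=1)


def count_strict_maxima_circular(v: np.ndarray) -> int:
    left = np.roll(v, 1)
    right = np.roll(v, -1)
    return int(np.sum((v > left) & (v > right)))


class TestSpokeSample:
    def test_peak_on_spoke_axis(self):
        s = make_spoke_sample(512, 48)
        # theta = 0 along +x from center: density at the spoke crest is the max
        c = float(512 // 2)
        vals = map_coordinates(s.density, [[c], [c + 100.0]], order=1)
        assert vals[0] == pytest.approx(1.0, abs=1e-3)
        assert s.density.max() == pytest.approx(1.0)

    def test_zero_between_spokes(self):
        s = make_spoke_sample(512, 48)
        c = float(512 // 2)
        th = np.pi / 48
        r = 100.0
        val = map_coordinates(
            s.density, [[c + r * np.sin(th)], [c + r * np.cos(th)]], order=3
        )[0]
        assert val == pytest.approx(0.0, abs=5e-3)

    def test_48_maxima_on_circle(self):
        s = make_spoke_sample(512, 48)
        prof = circle_profile(s.density, 100.0)
        assert count_strict_maxima_circular(prof) == 48

    @pytest.mark.parametrize("bad", [dict(size_px=16), dict(size_px=64, n_lobes=0)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            make_spoke_sample(**{"size_px": 64, "n_lobes": 48, **bad})


class TestRandomStructure:
    def test_deterministic_under_seed(self):
        a = make_random_structure_sample(64, "filaments", seed=5)
        b = make_random_structure_sample(64, "filaments", seed=5)
        assert np.array_equal(a.density, b.density)

    def test_different_seeds_differ(self):
        a = make_random_structure_sample(64, "blobs", seed=1)
        b = make_random_structure_sample(64, "blobs", seed=2)
        assert not np.array_equal(a.density, b.density)

    def test_filament_sparsity(self):
        fracs = [
            np.mean(make_random_structure_sample(64, "filaments", seed=s).density > 1e-3)
            for s in range(10)
        ]
        assert all(0.01 <= f <= 0.5 for f in fracs)

    def test_unknown_style(self):
        with pytest.raises(InvalidParameterError):
            make_random_structure_sample(64, "squares", seed=0)


class TestGaussianPsf:
    def test_width_matches_airy_core_approximation(self):
        psf = make_gaussian_psf(560.0, 1.1, 130.0)
        expected_sigma = (0.21 * 560.0 / 1.1) / 130.0
        assert psf.sigma_px == pytest.approx(expected_sigma, rel=1e-12)
        # fit a 1D Gaussian to the central row as an independent width oracle
        row = psf.kernel[psf.kernel.shape[0] // 2]
        x = np.arange(row.size, dtype=float)

        def g(x, a, mu, sig):
            return a * np.exp(-((x - mu) ** 2) / (2 * sig**2))

        popt, _ = curve_fit(g, x, row, p0=[row.max(), row.size // 2, 1.0])
        fitted_fwhm = 2.3548 * abs(popt[2])
        assert fitted_fwhm == pytest.approx(2.3548 * expected_sigma, rel=0.05)

    def test_unit_sum_and_symmetry(self):
        psf = make_gaussian_psf(488.0, 1.4, 65.0)
        assert psf.kernel.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(psf.kernel, psf.kernel[::-1, ::-1])
        assert psf.kernel.shape[0] % 2 == 1

    def test_defocus_widens(self):
        p0 = make_gaussian_psf(defocus_um=0.0)
        p3 = make_gaussian_psf(defocus_um=3.0)
        assert p3.sigma_px > p0.sigma_px

    def test_unresolvable_sampling_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_gaussian_psf(560.0, 1.1, pixel_size_nm=1000.0)


class TestSchedule:
    def test_frame_counts_at_default_geometry(self):
        assert build_schedule((256, 256), 16, 1).n_frames == 256
        assert build_schedule((256, 256), 16, 2).n_frames == 64

    def test_foci_per_frame(self):
        sch = build_schedule((256, 256), 16, 2)
        for f in sch.foci:
            assert f.shape[0] == (256 // 16) ** 2

    @pytest.mark.parametrize("spacing", [8, 16])
    @pytest.mark.parametrize("step", [1, 2, 4])
    def test_cardinality_invariant(self, spacing, step):
        sch = build_schedule((64, 64), spacing, step)
        assert sch.n_frames * step**2 == spacing**2
        offsets = set(sch.scan_offsets)
        assert len(offsets) == sch.n_frames
        if step == 1:
            assert offsets == {(dy, dx) for dy in range(spacing) for dx in range(spacing)}
        # square lattice with the stated period in every frame
        f0 = sch.foci[0]
        rows = np.unique(f0[:, 0])
        assert np.all(np.diff(rows) == spacing)
        assert all(np.all((f[:, 0] >= 0) & (f[:, 0] < 64)) for f in sch.foci)

    def test_invalid_geometry(self):
        with pytest.raises(InvalidParameterError):
            build_schedule((60, 64), 16, 1)
        with pytest.raises(InvalidParameterError):
            build_schedule((64, 64), 16, 3)


class TestRenderPattern:
    def test_identity_kernel_gives_comb(self, schedule_64_16):
        ident = PsfKernel(np.ones((1, 1)), 0.5, 560.0, 1.1, role="excitation")
        pat = render_pattern(schedule_64_16, 0, ident)
        comb = np.zeros((64, 64))
        pts = schedule_64_16.foci[0]
        comb[pts[:, 0], pts[:, 1]] = 1.0
        assert np.array_equal(pat, comb)

    def test_total_intensity_is_focus_count(self, schedule_64_16, psf_ex):
        # interior-offset frame: every unit-sum kernel lies fully inside
        idx = schedule_64_16.scan_offsets.index((8, 8))
        pat = render_pattern(schedule_64_16, idx, psf_ex)
        n = schedule_64_16.foci[idx].shape[0]
        assert pat.sum() == pytest.approx(n, rel=1e-6)

    def test_value_at_isolated_focus_is_kernel_peak(self, psf_ex):
        sch = build_schedule((64, 64), 16, 1)
        # offset (8, 8): all foci at least 8 px from the border, spacing >> sigma
        idx = sch.scan_offsets.index((8, 8))
        pat = render_pattern(sch, idx, psf_ex)
        f = sch.foci[idx][5]
        assert pat[f[0], f[1]] == pytest.approx(psf_ex.kernel.max(), rel=1e-6)

    def test_index_out_of_range(self, schedule_64_16, psf_ex):
        with pytest.raises(IndexError):
            render_pattern(schedule_64_16, schedule_64_16.n_frames, psf_ex)


class TestRenderRawFrame:
    def test_zero_sample(self, schedule_64_16, psf_ex, psf_em):
        from msim.simulate import SampleMap

        zero = SampleMap(np.zeros((64, 64)) + 0.0, 130.0)
        zero.density[:] = 0
        pat = render_pattern(schedule_64_16, 0, psf_ex)
        assert np.all(render_raw_frame(zero, pat, psf_em) == 0)

    def test_flux_conservation_constant_sample(self, schedule_64_16, psf_ex, psf_em):
        from msim.simulate import SampleMap

        const = SampleMap(np.full((64, 64), 2.5), 130.0)
        idx = schedule_64_16.scan_offsets.index((8, 8))
        pat = render_pattern(schedule_64_16, idx, psf_ex)
        frame = render_raw_frame(const, pat, psf_em)
        # interior foci: emission blur loses no flux at borders
        assert frame.sum() == pytest.approx(2.5 * pat.sum(), rel=1e-4)

    def test_matches_brute_force_oracle(self, psf_ex, psf_em):
        rng = np.random.default_rng(3)
        from msim.simulate import SampleMap

        sample = SampleMap(rng.random((64, 64)), 130.0)
        sch = build_schedule((64, 64), 16, 1)
        pat = render_pattern(sch, 37, psf_ex)
        fast = render_raw_frame(sample, pat, psf_em)
        slow = brute_force_frame(sample.density, pat, psf_em.kernel)
        assert np.abs(fast - slow).max() <= 1e-6 * slow.max()

    def test_point_sample_gives_shifted_psf(self, psf_em):
        from msim.simulate import SampleMap

        sch = build_schedule((64, 64), 16, 1)
        idx = sch.scan_offsets.index((8, 8))
        point = np.zeros((64, 64))
        f = sch.foci[idx][5]
        point[f[0], f[1]] = 1.0
        sample = SampleMap(point, 130.0)
        pat = np.ones((64, 64))
        frame = render_raw_frame(sample, pat, psf_em)
        r = psf_em.kernel.shape[0] // 2
        sub = frame[f[0] - r : f[0] + r + 1, f[1] - r : f[1] + r + 1]
        assert np.abs(sub - psf_em.kernel).max() < 1e-9

    def test_linearity(self, psf_ex, psf_em):
        from msim.simulate import SampleMap

        rng = np.random.default_rng(11)
        s1 = rng.random((64, 64))
        s2 = rng.random((64, 64))
        sch = build_schedule((64, 64), 16, 1)
        pat = render_pattern(sch, 9, psf_ex)
        lhs = render_raw_frame(SampleMap(2.0 * s1 + 3.0 * s2, 130.0), pat, psf_em)
        rhs = 2.0 * render_raw_frame(SampleMap(s1, 130.0), pat, psf_em) + 3.0 * render_raw_frame(
            SampleMap(s2, 130.0), pat, psf_em
        )
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_shape_mismatch(self, spoke64, psf_em):
        with pytest.raises(InvalidParameterError):
            render_raw_frame(spoke64, np.ones((32, 32)), psf_em)


class TestDefocusMixture:
    def test_equal_kernels_double(self, spoke64, schedule_64_16, psf_ex, psf_em):
        pat = render_pattern(schedule_64_16, 0, psf_ex)
        single = render_raw_frame(spoke64, pat, psf_em)
        mix = render_defocus_mixture(spoke64, pat, psf_em, psf_em)
        assert np.allclose(mix, 2.0 * single)

    def test_flux_bookkeeping(self, spoke64, schedule_64_16, psf_ex, psf_em):
        # modest defocus keeps the blurred kernel inside the 64 px frame,
        # so the two-copy sum carries exactly twice the single-frame flux
        defoc = make_gaussian_psf(defocus_um=0.5)
        idx = schedule_64_16.scan_offsets.index((8, 8))
        pat = render_pattern(schedule_64_16, idx, psf_ex)
        single = render_raw_frame(spoke64, pat, psf_em)
        mix = render_defocus_mixture(spoke64, pat, psf_em, defoc)
        assert mix.sum() == pytest.approx(2.0 * single.sum(), rel=0.02)


class TestCorrupt:
    def test_deterministic(self):
        frame = np.random.default_rng(0).random((32, 32)) * 10
        a = corrupt(frame, 0.5, 100.0, seed=42)
        b = corrupt(frame, 0.5, 100.0, seed=42)
        assert np.array_equal(a, b)

    def test_high_photon_scale_near_clean(self):
        frame = 1.0 + np.random.default_rng(1).random((64, 64))
        noisy = corrupt(frame, 0.0, 1e6, seed=0)
        assert np.mean(np.abs(noisy - frame) / frame) < 0.01

    def test_nonnegative_output(self):
        frame = np.full((16, 16), 0.01)
        noisy = corrupt(frame, 5.0, None, seed=3)
        assert noisy.min() >= 0

    def test_negative_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            corrupt(np.ones((16, 16)), -1.0, None, seed=0)


class TestSimulateStack:
    def test_shapes_and_reproducibility(self, spoke64, schedule_64_16, psf_ex, psf_em):
        kw = dict(noise={"gauss_sigma": 0.01, "photon_scale": 1000.0}, seed=7)
        a = simulate_stack(spoke64, schedule_64_16, psf_ex, psf_em, **kw)
        b = simulate_stack(spoke64, schedule_64_16, psf_ex, psf_em, **kw)
        assert a.frames.shape == (256, 64, 64)
        assert np.array_equal(a.frames, b.frames)

    def test_widefield_equals_emission_blur(self, noiseless_stack64, spoke64, psf_em):
        """Unit-step full coverage: sum_i p_i = 1, so the frame sum is s (*) h_em."""
        wf = widefield(noiseless_stack64)
        expected = fftconvolve(spoke64.density, psf_em.kernel, mode="same")
        m = 16  # away from a spacing-wide border
        inner = np.s_[m:-m, m:-m]
        assert np.abs(wf[inner] - expected[inner]).max() <= 0.02 * expected[inner].max()

    def test_widefield_sum_identities(self, noiseless_stack64):
        wf = widefield(noiseless_stack64)
        assert wf.sum() == pytest.approx(noiseless_stack64.frames.sum(), rel=1e-9)

    def test_single_frame_widefield(self, spoke64, psf_ex, psf_em):
        from msim.simulate import RawStack

        sch = build_schedule((64, 64), 16, 2)
        stack = simulate_stack(spoke64, sch, psf_ex, psf_em, noise=None)
        one = RawStack(stack.frames[:1].copy(), None, 130.0)
        assert np.array_equal(widefield(one), one.frames[0])
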