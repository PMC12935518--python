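import numpy as np
import pytest
import scipy.stats

from radnps import (
    ImageFrame,
    Nps2D,
    NpsConfig,
    average_periodograms,
    detrend_tile,
    extract_analysis_roi,
    nps_pipeline,
    radial_profile,
    theoretical_white_nps,
    tile_local_rois,
    tile_periodogram,
)

from conftest import NYQUIST, PIXEL_MM, white_frame


def frame_of(pixels, spacing=PIXEL_MM):
    return ImageFrame(pixels, spacing, spacing)


class TestExtractRoi:
    def test_center_crop_of_full_detector_matrix(self):
        frame = frame_of(np.zeros((2800, 3408)))
        roi = extract_analysis_roi(frame, 1400, 1704, size=1024)
        assert roi.shape == (1024, 1024)
        assert roi.spacing_row == PIXEL_MM

    def test_identity_crop(self):
        rng = np.random.default_rng(0)
        frame = frame_of(rng.normal(size=(256, 256)))
        roi = extract_analysis_roi(frame, 128, 128, size=256)
        assert np.array_equal(roi.pixels, frame.pixels)

    def test_out_of_bounds_reports_extents(self):
        frame = frame_of(np.zeros((2800, 3408)))
        with pytest.raises(ValueError, match=r"-512"):
            extract_analysis_roi(frame, 0, 0, size=1024)


class TestTiling:
    def test_non_overlapping_grid_has_16_tiles(self):
        roi = frame_of(np.zeros((1024, 1024)))
        stack = tile_local_rois(roi, tile_size=256, overlap=0)
        assert len(stack.tiles) == 16
        assert stack.offsets[0] == (0, 0) and stack.offsets[-1] == (768, 768)

    def test_single_tile(self):
        roi = frame_of(np.zeros((256, 256)))
        stack = tile_local_rois(roi, tile_size=256)
        assert len(stack.tiles) == 1 and stack.offsets == [(0, 0)]

    def test_half_overlap_grid_has_49_tiles(self):
        roi = frame_of(np.zeros((1024, 1024)))
        stack = tile_local_rois(roi, tile_size=256, overlap=0.5)
        assert len(stack.tiles) == 49

    def test_tile_larger_than_roi_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            tile_local_rois(frame_of(np.zeros((256, 256))), tile_size=512)

    def test_non_divisible_roi_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            tile_local_rois(frame_of(np.zeros((300, 300))), tile_size=256)


class TestDetrend:
    def test_constant_tile_gives_zero_residual(self):
        assert np.allclose(detrend_tile(np.full((32, 32), 7.0)), 0.0)

    def test_exact_quadratic_surface_removed(self):
        n = 64
        y, x = np.mgrid[0:n, 0:n].astype(float)
        tile = 3.0 + 0.2 * x - 0.1 * y + 0.01 * x * x - 0.02 * x * y + 0.005 * y * y
        resid = detrend_tile(tile, order=2)
        assert np.max(np.abs(resid)) <= 1e-8 * np.max(np.abs(tile))

    def test_matches_independent_normal_equations_fit(self):
        # brute-force least-squares oracle in raw pixel coordinates;
        # the residual is invariant to the coordinate parameterisation
        rng = np.random.default_rng(3)
        n = 256
        tile = rng.normal(0.0, 10.0, (n, n))
        y, x = np.mgrid[0:n, 0:n].astype(float)
        A = np.column_stack([np.ones(n * n), x.ravel(), y.ravel(),
                             (x * x).ravel(), (x * y).ravel(), (y * y).ravel()])
        beta = np.linalg.solve(A.T @ A, A.T @ tile.ravel())
        oracle = (tile.ravel() - A @ beta).reshape(n, n)
        resid = detrend_tile(tile, order=2)
        np.testing.assert_allclose(resid, oracle, atol=1e-8)
        # fitting 6 parameters removes ~6/n^2 of the variance
        expect = 100.0 * (1 - 6 / n**2)
        assert np.isclose(resid.var(), oracle.var(), rtol=1e-12)
        assert abs(resid.var() - expect) < 3 * 100.0 * np.sqrt(2 / n**2)

    def test_residual_orthogonal_to_basis(self):
        rng = np.random.default_rng(4)
        tile = rng.normal(size=(64, 64))
        resid = detrend_tile(tile, order=2)
        t = np.linspace(-1, 1, 64)
        yy, xx = np.meshgrid(t, t, indexing="ij")
        energy = np.sum(tile**2)
        for term in (np.ones_like(xx), xx, yy, xx * xx, xx * yy, yy * yy):
            assert abs(np.sum(resid * term)) <= 1e-6 * energy

    def test_non_square_tile_rejected(self):
        with pytest.raises(ValueError, match="square"):
            detrend_tile(np.zeros((32, 64)))


class TestPeriodogram:
    def test_zero_input_gives_zero_power(self):
        nps = tile_periodogram(np.zeros((32, 32)), PIXEL_MM, PIXEL_MM)
        assert np.all(nps.power == 0)
        assert np.isclose(nps.freq_step_row, 1 / (32 * PIXEL_MM))

    def test_pure_cosine_concentrates_in_conjugate_bins(self):
        S, A, k = 64, 3.0, 5
        m = np.arange(S)
        fluct = A * np.cos(2 * np.pi * k * m / S)[None, :] * np.ones((S, 1))
        nps = tile_periodogram(fluct, PIXEL_MM, PIXEL_MM)
        expected = (PIXEL_MM**2 / S**2) * (A * S * S / 2) ** 2
        assert np.isclose(nps.power[0, k], expected, rtol=1e-9)
        assert np.isclose(nps.power[0, S - k], expected, rtol=1e-9)
        off = nps.power.copy()
        off[0, k] = off[0, S - k] = 0
        assert np.all(off < 1e-9 * expected)

    def test_matches_direct_dft_oracle_on_16x16(self):
        rng = np.random.default_rng(5)
        S = 16
        fluct = rng.normal(size=(S, S))
        m = np.arange(S)
        w = np.exp(-2j * np.pi * np.outer(m, m) / S)  # direct O(N^4) DFT
        dft = w @ fluct @ w.T
        oracle = (PIXEL_MM**2 / S**2) * np.abs(dft) ** 2
        nps = tile_periodogram(fluct, PIXEL_MM, PIXEL_MM)
        np.testing.assert_allclose(nps.power, oracle, rtol=1e-9, atol=1e-15)

    def test_parseval_conservation(self):
        rng = np.random.default_rng(6)
        fluct = detrend_tile(rng.normal(0, 10, (128, 128)))
        nps = tile_periodogram(fluct, PIXEL_MM, PIXEL_MM)
        lhs = nps.power.sum() * nps.freq_step_row * nps.freq_step_col
        rhs = np.mean(fluct**2)
        assert np.isclose(lhs, rhs, rtol=1e-6)

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            tile_periodogram(np.zeros((16, 16)), 0.0, 0.125)


class TestAveraging:
    def _spec(self, power):
        return Nps2D(power=power, freq_step_row=0.1, freq_step_col=0.1)

    def test_mean_and_counts(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.1, 1.0, (8, 8))
        same = average_periodograms([self._spec(x)] * 3)
        np.testing.assert_allclose(same.power, x)
        assert same.n_averaged == 3
        halved = average_periodograms([self._spec(np.zeros((8, 8))), self._spec(x)])
        np.testing.assert_allclose(halved.power, x / 2)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            average_periodograms(
                [self._spec(np.zeros((8, 8))), self._spec(np.zeros((16, 16)))]
            )

    def test_averaging_16_reduces_scatter_by_4(self):
        # Monte-Carlo: per-bin std over replicates of a 16-tile average is
        # ~1/4 of the single-tile std
        rng = np.random.default_rng(8)
        S, reps = 32, 120
        singles, means16 = [], []
        for _ in range(reps):
            specs = [
                tile_periodogram(detrend_tile(rng.normal(0, 5, (S, S))),
                                 PIXEL_MM, PIXEL_MM)
                for _ in range(16)
            ]
            singles.append(specs[0].power)
            means16.append(average_periodograms(specs).power)
        ratio = np.std(singles, axis=0) / np.std(means16, axis=0)
        # exclude DC and first row/col touched by detrending
        assert np.isclose(np.median(ratio[1:, 1:]), 4.0, rtol=0.25)


class TestRadialProfile:
    def _nps(self, power, du):
        return Nps2D(power=power, freq_step_row=du, freq_step_col=du)

    def test_constant_spectrum_gives_constant_bins(self):
        prof = radial_profile(self._nps(np.full((64, 64), 2.5), 0.03125))
        assert np.allclose(prof.value, 2.5)

    def test_bin_count_and_axis_for_256_grid(self):
        du = 1 / (256 * PIXEL_MM)
        prof = radial_profile(self._nps(np.ones((256, 256)), du))
        assert len(prof) == 128
        assert np.isclose(prof.freq[0], du)
        assert np.isclose(prof.freq[-1], NYQUIST)

    def test_matches_brute_force_binning_oracle(self):
        # radially symmetric spectrum f(r) = r^2, oracle loops over all
        # grid points independently
        S, du = 64, 0.05
        f = np.fft.fftfreq(S, d=1 / (S * du))
        rad = np.hypot(f[:, None], f[None, :])
        power = rad**2
        prof = radial_profile(self._nps(power, du))
        nyq = du * (S // 2)
        sums = {}
        counts = {}
        for i in range(S):
            for j in range(S):
                r = np.hypot(f[i], f[j])
                if r > nyq * (1 + 1e-12) or (i == 0 and j == 0):
                    continue
                k = int(round(r / du))
                sums[k] = sums.get(k, 0.0) + power[i, j]
                counts[k] = counts.get(k, 0) + 1
        for k, freq, val, cnt in zip(
            (prof.freq / du + 0.5).astype(int), prof.freq, prof.value, prof.count
        ):
            assert cnt == counts[k]
            assert np.isclose(val, sums[k] / counts[k], rtol=1e-12)

    def test_axis_exclusion_drops_axis_lines(self):
        S, du = 32, 0.1
        power = np.ones((S, S))
        power[0, :] = 100.0  # contaminated frequency axes
        power[:, 0] = 100.0
        prof = radial_profile(self._nps(power, du), exclude_axes=True)
        assert np.allclose(prof.value, 1.0)

    def test_anisotropic_grid_rejected(self):
        nps = Nps2D(power=np.ones((16, 16)), freq_step_row=0.1, freq_step_col=0.2)
        with pytest.raises(ValueError, match="isotropic"):
            radial_profile(nps)


class TestPipeline:
    def test_white_noise_level_is_sigma2_dx_dy(self):
        sigma = 50.0
        nps = nps_pipeline(white_frame(sigma, 1024, seed=10))
        level = theoretical_white_nps(sigma, PIXEL_MM)  # 39.0625
        # count-weighted band mean = mean over contributing grid points;
        # Hermitian symmetry halves the independent bins, hence the 2
        band = float(np.average(nps.value, weights=nps.count))
        rel_se = np.sqrt(2.0 / (16 * nps.count.sum()))
        assert abs(band - level) < 3 * level * rel_se

    def test_zero_noise_constant_frame_gives_zero(self):
        frame = ImageFrame(np.full((512, 512), 900.0), PIXEL_MM, PIXEL_MM)
        nps = nps_pipeline(frame, config=NpsConfig(roi_size=512))
        assert np.allclose(nps.value, 0.0, atol=1e-18)

    def test_white_noise_radial_nps_is_flat(self):
        # pooled over 100 seeds, the slope of value vs frequency is
        # statistically indistinguishable from zero
        curves = [
            nps_pipeline(white_frame(20.0, 256, seed=s),
                         config=NpsConfig(roi_size=256)).value
            for s in range(100)
        ]
        mean = np.mean(curves, axis=0)
        freq = nps_pipeline(white_frame(20.0, 256, seed=0),
                            config=NpsConfig(roi_size=256)).freq
        fit = scipy.stats.linregress(freq, mean)
        assert abs(fit.slope / fit.stderr) < 4

    def test_planar_gradient_leaves_nps_unchanged(self):
        frame = white_frame(30.0, 512, seed=11)
        base = nps_pipeline(frame, config=NpsConfig(roi_size=512))
        y, x = np.mgrid[0:512, 0:512].astype(float)
        ramped = frame.with_pixels(frame.pixels + 0.8 * x - 1.3 * y + 50.0)
        tilted = nps_pipeline(ramped, config=NpsConfig(roi_size=512))
        assert np.max(np.abs(tilted.value / base.value - 1)) < 0.005

    def test_white_noise_spectrum_matches_detrend_suppression(self, cfg512):
        # the polynomial detrend suppresses the lowest-frequency bins by an
        # exactly computable factor D(u, v); the measured white-noise NPS
        # matches sigma^2 dx dy x radial(D) in every bin, including the first
        from radnps.nps_core import Nps2D as _N, detrend_suppression

        sigma = 30.0
        curves = [
            nps_pipeline(white_frame(sigma, 512, seed=2300 + s), config=cfg512).value
            for s in range(50)
        ]
        measured = np.mean(curves, axis=0)
        du = 1 / (256 * PIXEL_MM)
        prof = radial_profile(
            _N(power=detrend_suppression(256, 2), freq_step_row=du, freq_step_col=du)
        )
        rel = measured / (theoretical_white_nps(sigma, PIXEL_MM) * prof.value) - 1
        assert prof.value[0] < 0.7  # first bin genuinely suppressed
        assert np.sqrt(np.mean(rel**2)) < 0.03

    def test_linear_filter_transfer_function(self, cfg512):
        # measured NPS of blurred white noise ~ sigma^2 dx dy |G|^2 D
        from radnps import DenoiserSpec, apply_denoiser
        from radnps.synthetic_data import transfer_function
        from radnps.nps_core import Nps2D as _N, detrend_suppression

        sigma = 30.0
        d = DenoiserSpec("gaussian_blur", kernel_sigma=0.6)
        curves = []
        for s in range(50):
            blurred = apply_denoiser(white_frame(sigma, 512, seed=100 + s), d)
            curves.append(nps_pipeline(blurred, config=cfg512).value)
        measured = np.mean(curves, axis=0)
        ref = nps_pipeline(white_frame(sigma, 512, seed=100), config=cfg512)
        g2 = transfer_function(d, 256) ** 2 * detrend_suppression(256, 2)
        prof = radial_profile(
            _N(power=g2, freq_step_row=1 / (256 * PIXEL_MM),
               freq_step_col=1 / (256 * PIXEL_MM))
        )
        theory = theoretical_white_nps(sigma, PIXEL_MM) * prof.value
        sel = ref.freq <= 0.8 * NYQUIST
        rel = measured[sel] / theory[sel] - 1
        assert np.sqrt(np.mean(rel**2)) < 0.05

    def test_overlap_variants_agree(self, cfg512):
        # half-overlap tiling estimates the same spectrum
        cfg_ov = NpsConfig(roi_size=512, overlap=0.5)
        d0, d5 = [], []
        for s in range(20):
            f = white_frame(25.0, 512, seed=200 + s)
            d0.append(np.mean(nps_pipeline(f, config=cfg512).value))
            d5.append(np.mean(nps_pipeline(f, config=cfg_ov).value))
        diff = np.array(d0) - np.array(d5)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < max(3 * se, 5e-3 * np.mean(d0))

    def test_small_frame_rejected(self):
        frame = ImageFrame(np.zeros((128, 128)), PIXEL_MM, PIXEL_MM)
        with pytest.raises(ValueError, match="minimum"):
            nps_pipeline(frame, config=NpsConfig(roi_size=128))
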