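"""Gridding, coil combination, upsampling and phasing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hpcardiac.phantom import make_coil_array
from hpcardiac.recon import (KSpaceFrame, SensitivityMaps,
                             conjugate_phase_recon, estimate_sensitivities,
                             forward_dft, grid_reconstruct, phase_correct,
                             roemer_combine, spiral_trajectory, upsample2x)


def gaussian_phantom(n, centers, widths, amps):
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.zeros((n, n))
    for (cy, cx), w, a in zip(centers, widths, amps):
        img += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / w)
    return img


class TestGridding:
    def test_dc_sample_gives_uniform_image(self):
        kf = KSpaceFrame(samples=np.array([1.0 + 0j]),
                         coords=np.zeros((1, 2)), times_ms=np.zeros(1),
                         dcf=np.ones(1))
        img = grid_reconstruct(kf, 16)
        center = img[8, 8]
        assert np.abs(img - center).max() / np.abs(center) < 1e-6

    def test_matches_conjugate_phase_dft_small_problem(self):
        n = 16
        traj = spiral_trajectory(n)
        phantom = gaussian_phantom(n, [(7, 8.5), (10, 5)], [8, 4], [1, 0.5])
        samples = forward_dft(phantom, traj.coords)
        kf = KSpaceFrame(samples=samples, coords=traj.coords,
                         times_ms=traj.times_ms, dcf=traj.dcf)
        grid = grid_reconstruct(kf, n)
        cp = conjugate_phase_recon(samples, traj.coords, traj.dcf, (n, n))
        rms = np.sqrt(np.mean(np.abs(grid - cp) ** 2))
        rms /= np.sqrt(np.mean(np.abs(cp) ** 2))
        assert rms < 0.02

    def test_round_trip_recovers_phantom(self):
        n = 32
        traj = spiral_trajectory(n)
        phantom = gaussian_phantom(n, [(14, 17), (20, 10)], [30, 12], [1, 0.6])
        samples = forward_dft(phantom, traj.coords)
        kf = KSpaceFrame(samples=samples, coords=traj.coords,
                         times_ms=traj.times_ms, dcf=traj.dcf)
        recon = grid_reconstruct(kf, n).real
        nrmse = np.sqrt(np.mean((recon - phantom) ** 2))
        nrmse /= np.sqrt(np.mean(phantom ** 2))
        assert nrmse < 0.05

    def test_linearity(self):
        n = 16
        traj = spiral_trajectory(n)
        rng = np.random.default_rng(0)
        s1 = rng.normal(size=traj.coords.shape[0]) + 0j
        s2 = rng.normal(size=traj.coords.shape[0]) + 0j

        def rec(s):
            return grid_reconstruct(
                KSpaceFrame(samples=s, coords=traj.coords,
                            times_ms=traj.times_ms, dcf=traj.dcf), n)

        np.testing.assert_allclose(rec(2.0 * s1 - 3.0 * s2),
                                   2.0 * rec(s1) - 3.0 * rec(s2),
                                   rtol=1e-10, atol=1e-12)

    def test_empty_samples_warns_and_returns_zero(self):
        kf = KSpaceFrame(samples=np.zeros(0, complex),
                         coords=np.zeros((0, 2)), times_ms=np.zeros(0),
                         dcf=np.zeros(0))
        with pytest.warns(UserWarning):
            img = grid_reconstruct(kf, 8)
        assert np.all(img == 0)


class TestSensitivities:
    def test_single_channel_is_unity_inside_mask(self):
        img = np.ones((1, 12, 12))
        sens = estimate_sensitivities(img, smooth_fwhm_vox=0)
        np.testing.assert_allclose(sens.maps[0][sens.mask], 1.0)

    def test_two_identical_channels(self):
        img = np.ones((2, 12, 12))
        sens = estimate_sensitivities(img, smooth_fwhm_vox=0)
        np.testing.assert_allclose(sens.maps[:, sens.mask], 1 / np.sqrt(2))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            estimate_sensitivities(np.zeros((2, 8, 8)))

    def test_recovers_simulated_sensitivity_shapes(self):
        coils = make_coil_array((1, 32, 32), seed=7)
        truth = coils.sensitivities[:, 0]
        obj = gaussian_phantom(32, [(15, 16)], [120], [1]) + 0.2
        sens = estimate_sensitivities(truth * obj)
        # the estimator recovers relative (RSS-normalized) sensitivities
        rss = np.sqrt(np.sum(np.abs(truth) ** 2, axis=0))
        est = np.abs(sens.maps[:, sens.mask])
        tru = np.abs(truth[:, sens.mask]) / rss[sens.mask]
        r = np.corrcoef(est.ravel(), tru.ravel())[0, 1]
        assert r > 0.95


class TestRoemer:
    def test_single_unit_channel_identity(self):
        img = (np.arange(16.0) + 1j).reshape(1, 4, 4)
        maps = SensitivityMaps(maps=np.ones((1, 4, 4), complex),
                               mask=np.ones((4, 4), bool))
        np.testing.assert_allclose(roemer_combine(img, maps), img[0])

    def test_exact_inverse_of_known_maps(self):
        coils = make_coil_array((1, 16, 16), seed=3)
        m = gaussian_phantom(16, [(8, 8)], [20], [1.0])
        chan = coils.sensitivities[:, 0] * m
        maps = SensitivityMaps(maps=coils.sensitivities[:, 0],
                               mask=np.ones((16, 16), bool))
        np.testing.assert_allclose(roemer_combine(chan, maps), m, atol=1e-12)

    def test_noise_variance_scaling_monte_carlo(self):
        """Equal-|s| channels: combined variance = sigma^2/(n_ch |s|^2)."""
        n_ch, mag, sigma = 4, 0.7, 1.0
        rng = np.random.default_rng(42)
        phases = np.exp(1j * rng.uniform(-np.pi, np.pi, n_ch))
        maps_arr = (mag * phases)[:, None, None] * np.ones((1, 50, 50))
        maps = SensitivityMaps(maps=maps_arr, mask=np.ones((50, 50), bool))
        noise = rng.normal(0, sigma, (n_ch, 50, 50)) \
            + 1j * rng.normal(0, sigma, (n_ch, 50, 50))
        combined = roemer_combine(noise, maps)
        expected = sigma ** 2 / (n_ch * mag ** 2)
        measured = np.var(combined.real)
        assert abs(measured - expected) / expected < 0.05


class TestUpsample:
    def test_constant_preserved(self):
        up = upsample2x(np.full((8, 8), 3.25), fermi=False)
        np.testing.assert_allclose(up, 3.25, rtol=1e-12)

    def test_impulse_gives_symmetric_kernel(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        up = upsample2x(img)
        assert np.argmax(np.abs(up)) == np.ravel_multi_index((16, 16), up.shape)
        # symmetric about the source voxel (now at 16, 16)
        for d in (1, 3, 5, 7):
            np.testing.assert_allclose(up[16, 16 + d], up[16, 16 - d],
                                       atol=1e-12)
            np.testing.assert_allclose(up[16 + d, 16], up[16 - d, 16],
                                       atol=1e-12)

    def test_original_samples_exact_without_window(self):
        rng = np.random.default_rng(5)
        img = rng.normal(size=(12, 12))
        up = upsample2x(img, fermi=False)
        assert np.abs(up[::2, ::2] - img).max() < 1e-9


class TestPhaseCorrect:
    def test_noiseless_inversion(self):
        t = np.arange(30)
        r = 5.0 * np.exp(-((t - 8) / 5.0) ** 2)
        for phi0 in (-2.9, -1.0, 0.3, 1.2, 2.5):
            phi, real = phase_correct((r * np.exp(1j * phi0))[:, None], axis=0)
            assert abs(phi[0] - phi0) < 1e-12
            np.testing.assert_allclose(real[:, 0], r, atol=1e-12)

    def test_beats_grid_search(self):
        """Closed-form phase never loses to a 3600-point grid search."""
        rng = np.random.default_rng(77)
        s = rng.normal(size=(30, 1000)) + 1j * rng.normal(size=(30, 1000))
        phi, real = phase_correct(s, axis=0)
        e_opt = np.sum(real ** 2, axis=0)
        e_best = np.zeros(1000)
        for p in np.linspace(-np.pi, np.pi, 3600, endpoint=False):
            e = np.sum((s * np.exp(-1j * p)).real ** 2, axis=0)
            e_best = np.maximum(e_best, e)
        assert np.all(e_opt >= e_best - 1e-9 * e_best)

    def test_pure_noise_stays_zero_mean(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=(30, 5000)) + 1j * rng.normal(size=(30, 5000))
        _, real = phase_correct(s, axis=0)
        vals = real.ravel()
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_all_zero_series_gets_zero_phase(self):
        phi, real = phase_correct(np.zeros((10, 3), complex), axis=0)
        assert np.all(phi == 0) and np.all(real == 0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(hnp.arrays(np.float64, (2, 8),
                      elements=st.floats(-10, 10, allow_nan=False)))
    def test_energy_optimality_property(self, parts):
        """For any complex series the closed-form phase captures at least
        as much real-channel energy as any probed rotation."""
        s = parts[0] + 1j * parts[1]
        phi, real = phase_correct(s[:, None], axis=0)
        e_opt = np.sum(real ** 2)
        for p in np.linspace(0, np.pi, 37):
            e = np.sum((s * np.exp(-1j * p)).real ** 2)
            assert e_opt >= e - 1e-9 * max(e, 1.0)
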