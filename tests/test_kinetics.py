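"""Forward model, inputless prediction and rate fitting."""

import numpy as np
import pytest

from hpcardiac.kinetics import (FlipSchedule, MetaboliteTimecourses,
                                RelaxationTimes, fit_inputless, fit_rate_maps,
                                forward_model, predict_inputless)
from hpcardiac.phantom import AIFModel


def ode_oracle(aif, k_pl, k_pb, relax, flips, m_p0=0.0, dt=1e-3):
    """Independent fine-step RK4 integration of the three-pool ODE with
    flip losses applied instantaneously at frame times."""
    times = flips.times
    cos = [np.cos(np.deg2rad(t)) for t in (flips.theta_pyruvate,
                                           flips.theta_lactate,
                                           flips.theta_bicarbonate)]
    y = np.array([m_p0, 0.0, 0.0])

    def deriv(y, t):
        p, l, b = y
        inp = aif(t) if aif is not None else 0.0
        return np.array([
            -(1.0 / relax.t1_pyruvate + k_pl + k_pb) * p + inp,
            -l / relax.t1_lactate + k_pl * p,
            -b / relax.t1_bicarbonate + k_pb * p,
        ])

    res = []
    n = int(round(times[-1] / dt))
    ti = 0
    for i in range(n + 1):
        t = i * dt
        while ti < len(times) and t >= times[ti] - 1e-12:
            res.append(y.copy())
            y = y * cos
            ti += 1
        k1 = deriv(y, t)
        k2 = deriv(y + dt / 2 * k1, t + dt / 2)
        k3 = deriv(y + dt / 2 * k2, t + dt / 2)
        k4 = deriv(y + dt * k3, t + dt)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return np.array(res).T


class TestForwardModel:
    def test_no_conversion_gives_zero_products(self, relax, flips30):
        tc = forward_model(AIFModel(), 0.0, 0.0, relax, flips30)
        assert np.all(tc.s_lactate == 0)
        assert np.all(tc.s_bicarbonate == 0)

    def test_pyruvate_only_decay_matches_closed_form(self, relax, flips30):
        tc = forward_model(None, 0.0, 0.0, relax, flips30, m_p0=1.0)
        n = np.arange(30)
        cos_p = np.cos(np.deg2rad(20.0))
        expected = cos_p ** n * np.exp(-flips30.times / relax.t1_pyruvate)
        np.testing.assert_allclose(tc.m_pyruvate, expected, rtol=1e-12)

    def test_matches_fine_step_ode_oracle(self, relax, flips30):
        """Bolus-delivered pyruvate: recursion vs 1 ms RK4 within 0.5%."""
        tc = forward_model(None, 0.02, 0.01, relax, flips30, m_p0=1.0)
        p, l, b = ode_oracle(None, 0.02, 0.01, relax, flips30, m_p0=1.0)
        for mine, oracle in ((tc.m_pyruvate, p), (tc.m_lactate, l),
                             (tc.m_bicarbonate, b)):
            sel = oracle > 1e-12
            rel = np.abs(mine[sel] - oracle[sel]) / oracle[sel]
            assert rel.max() < 5e-3

    def test_discretization_converges_with_finer_frames(self, relax):
        """With an external input the inter-frame interpolation error
        shrinks at least first-order as the frame interval is refined."""
        aif = AIFModel()
        errs = []
        for dt_frame in (3.6, 0.9):
            n = int(round(3.6 * 29 / dt_frame)) + 1
            flips = FlipSchedule(times=dt_frame * np.arange(n))
            tc = forward_model(aif, 0.02, 0.01, relax, flips)
            _, l, _ = ode_oracle(aif, 0.02, 0.01, relax, flips)
            sel = l > 1e-3 * l.max()
            errs.append(np.max(np.abs(tc.m_lactate[sel] - l[sel]) / l[sel]))
        assert errs[1] < errs[0] / 2

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError):
            FlipSchedule(times=np.array([0.0, 3.6, 3.6]))


class TestPredictInputless:
    def test_self_consistency_with_forward_model(self, relax, flips30):
        tc = forward_model(AIFModel(), 0.02, 0.01, relax, flips30)
        s_l, s_b = predict_inputless(tc.s_pyruvate, 0.02, 0.01, relax, flips30)
        np.testing.assert_allclose(s_l, tc.s_lactate, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(s_b, tc.s_bicarbonate, rtol=1e-12,
                                   atol=1e-15)

    def test_linearity_in_pyruvate_scale(self, relax, flips30):
        rng = np.random.default_rng(0)
        s_p = np.abs(rng.normal(1.0, 0.5, 30))
        l1, b1 = predict_inputless(s_p, 0.03, 0.01, relax, flips30)
        l2, b2 = predict_inputless(2.5 * s_p, 0.03, 0.01, relax, flips30)
        np.testing.assert_allclose(l2, 2.5 * l1, rtol=1e-12)
        np.testing.assert_allclose(b2, 2.5 * b1, rtol=1e-12)

    def test_matches_extended_precision_recursion(self, relax, flips30):
        """Brute-force long-double evaluation of the stated recursion."""
        rng = np.random.default_rng(1)
        s_p = np.abs(rng.normal(1.0, 0.5, 30))
        k_pl = 0.03
        sin_p, cos_p = np.sin(np.deg2rad(20.0)), np.cos(np.deg2rad(20.0))
        sin_l, cos_l = np.sin(np.deg2rad(30.0)), np.cos(np.deg2rad(30.0))
        t1l = np.longdouble(relax.t1_lactate)
        p_pre = s_p.astype(np.longdouble) / np.longdouble(sin_p)
        m = np.longdouble(0.0)
        expected = [float(m) * sin_l]
        for i in range(29):
            dt = np.longdouble(3.6)
            start, end = p_pre[i] * np.longdouble(cos_p), p_pre[i + 1]
            r = np.log(end / start) / dt
            a = r + 1 / t1l
            c = start * np.exp(-dt / t1l) * (np.exp(a * dt) - 1) / a
            m = m * np.longdouble(cos_l) * np.exp(-dt / t1l) \
                + np.longdouble(k_pl) * c
            expected.append(float(m * np.longdouble(sin_l)))
        s_l, _ = predict_inputless(s_p, k_pl, 0.0, relax, flips30)
        np.testing.assert_allclose(s_l, expected, rtol=1e-12)

    def test_zero_pyruvate_predicts_zero_products(self, relax, flips30):
        s_l, s_b = predict_inputless(np.zeros(30), 0.05, 0.02, relax, flips30)
        assert np.all(s_l == 0) and np.all(s_b == 0)


class TestFitInputless:
    def test_noiseless_recovery(self, relax, flips30):
        tc = forward_model(AIFModel(), 0.02, 0.01, relax, flips30)
        fit = fit_inputless(tc, relax, flips30)
        assert abs(fit.k_pl - 0.02) < 1e-3
        assert abs(fit.k_pb - 0.01) < 1e-3
        assert fit.converged

    def test_null_signal_gives_zero_rates(self, relax, flips30):
        tc = forward_model(AIFModel(), 0.0, 0.0, relax, flips30)
        fit = fit_inputless(tc, relax, flips30)
        assert abs(fit.k_pl) < 1e-12 and abs(fit.k_pb) < 1e-12

    def test_monte_carlo_bias_at_peak_snr_50(self, relax, flips30):
        """200 replicates at pyruvate-peak SNR 50: median k_PB within 10%."""
        tc = forward_model(AIFModel(), 0.02, 0.01, relax, flips30)
        sigma = tc.s_pyruvate.max() / 50.0
        rng = np.random.default_rng(12345)
        est = []
        for _ in range(200):
            noisy = MetaboliteTimecourses(
                s_pyruvate=tc.s_pyruvate + rng.normal(0, sigma, 30),
                s_lactate=tc.s_lactate + rng.normal(0, sigma, 30),
                s_bicarbonate=tc.s_bicarbonate + rng.normal(0, sigma, 30))
            fit = fit_inputless(noisy, relax, flips30)
            est.append((fit.k_pl, fit.k_pb))
        est = np.array(est)
        assert abs(np.median(est[:, 1]) - 0.01) < 0.1 * 0.01
        assert abs(np.median(est[:, 0]) - 0.02) < 0.1 * 0.02

    def test_flip_angle_invariance(self, relax):
        """Halving the lactate flip angle changes the signals but not the
        fitted rate — the model corrects for flip losses."""
        fits = []
        for theta_l in (15.0, 30.0):
            flips = FlipSchedule(times=3.6 * np.arange(30),
                                 theta_lactate=theta_l)
            tc = forward_model(AIFModel(), 0.02, 0.01, relax, flips)
            fits.append(fit_inputless(tc, relax, flips).k_pl)
        assert abs(fits[0] - fits[1]) / fits[1] < 0.01


class TestFitRateMaps:
    def test_empty_mask_warns_and_returns_nan(self, relax, flips30):
        imgs = np.zeros((3, 30, 4, 4))
        with pytest.warns(UserWarning):
            k_pl, k_pb = fit_rate_maps(imgs, np.zeros((4, 4), bool),
                                       relax, flips30)
        assert np.all(np.isnan(k_pl)) and np.all(np.isnan(k_pb))

    def test_masked_voxels_fitted_rest_nan(self, relax, flips30):
        tc = forward_model(AIFModel(), 0.02, 0.01, relax, flips30)
        imgs = np.zeros((3, 30, 2, 2))
        imgs[0, :, 0, 0] = tc.s_pyruvate
        imgs[1, :, 0, 0] = tc.s_lactate
        imgs[2, :, 0, 0] = tc.s_bicarbonate
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        k_pl, k_pb = fit_rate_maps(imgs, mask, relax, flips30)
        assert abs(k_pl[0, 0] - 0.02) < 1e-6
        assert np.isnan(k_pl[0, 1]) and np.isnan(k_pb[1, 1])
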