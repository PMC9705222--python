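import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadcal import (
    CalibrationConfig,
    NoiseJitterSpec,
    QuadratureError,
    ReflectorSet,
    analytic_extinction,
    calibrate,
    coherent_average,
    extinction_ratio,
    get_preset,
    make_kgrid,
    mirror_suppression,
    peak_shape_metrics,
    quadrature_geometry,
    reconstruct_aline,
    reconstruct_measurement,
    reconstruct_quadrature,
    simulate_mirror_measurement,
    simulate_mirror_sweep,
)
from quadcal.errors import GridMismatchError, IllConditionedError
from quadcal.reconstruct import evaluate_sweep, uniform_depth_bins


def _tone(N, b):
    n = np.arange(N)
    return 2 * np.pi * b * n / N


class TestQuadratureGeometry:
    def test_ideal(self):
        assert quadrature_geometry(1.0, np.pi / 2) == pytest.approx((1.0, 0.0))

    def test_sixty_degrees(self):
        a, b = quadrature_geometry(1.0, np.pi / 3)
        assert a == pytest.approx(2 / np.sqrt(3))
        assert b == pytest.approx(1 / np.sqrt(3))

    def test_three_by_three_coupler_angle(self):
        # 120-degree phase delay still reconstructs exactly
        a, b = quadrature_geometry(0.95, 2 * np.pi / 3)
        th = _tone(512, 40)
        s_i = np.cos(th)
        s_ii = (1 / 0.95) * np.cos(th - 2 * np.pi / 3)
        s_q = a * s_ii - b * s_i
        np.testing.assert_allclose(s_q, np.sin(th), atol=1e-12)

    def test_ill_conditioned(self):
        with pytest.raises(IllConditionedError):
            quadrature_geometry(1.0, 0.05)


class TestReconstructQuadrature:
    def test_identity_when_ideal(self):
        th = _tone(256, 20)
        s_i, s_ii = np.cos(th), np.cos(th + np.pi / 2)
        out = reconstruct_quadrature(
            s_i, s_ii, np.ones(256), np.full(256, np.pi / 2)
        )
        np.testing.assert_allclose(out, s_ii, atol=1e-12)

    def test_trig_identity_oracle(self):
        # s_II = (1/beta) cos(theta - dphi)  ->  s_Q = sin(theta)
        beta, dphi = 0.9, 1.2
        th = _tone(512, 37)
        s_i = np.cos(th)
        s_ii = (1 / beta) * np.cos(th - dphi)
        s_q = reconstruct_quadrature(
            s_i, s_ii, np.full(512, beta), np.full(512, dphi)
        )
        np.testing.assert_allclose(s_q, np.sin(th), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        beta=st.floats(0.8, 1.2),
        dphi=st.floats(0.3, np.pi - 0.3),
        b=st.integers(5, 100),
    )
    def test_appendix_ab_oracle_equivalence(self, beta, dphi, b):
        # pointwise formula == a*s_II - b*s_I linear combination
        th = _tone(256, b)
        s_i = np.cos(th)
        s_ii = (1 / beta) * np.cos(th - dphi)
        a_c, b_c = quadrature_geometry(beta, dphi)
        direct = reconstruct_quadrature(
            s_i, s_ii, np.full(256, beta), np.full(256, dphi)
        )
        np.testing.assert_allclose(direct, a_c * s_ii - b_c * s_i, atol=1e-12)

    def test_varying_dphi_profile(self):
        # dphi(k) swinging +-0.3 around pi/2: residual mirror below -100 dB
        N = 1024
        th = _tone(N, 100)
        k = np.linspace(-1, 1, N, endpoint=False)
        dphi = np.pi / 2 + 0.3 * np.sin(2 * k)
        beta = 1.0 + 0.05 * k
        s_i = np.cos(th)
        s_ii = (1 / beta) * np.cos(th + dphi)
        s_q = reconstruct_quadrature(s_i, s_ii, beta, dphi)
        spec = np.abs(np.fft.fftshift(np.fft.fft(s_i - 1j * s_q)))
        c = N // 2
        assert 20 * np.log10(spec[c - 100] / spec[c + 100]) < -100

    def test_conditioning_error(self):
        with pytest.raises(IllConditionedError):
            reconstruct_quadrature(
                np.ones(8), np.ones(8), np.ones(8), np.full(8, 0.01)
            )


class TestReconstructAline:
    def test_ideal_system_identity_corrections(self, grid1024, quiet):
        z = 128 * grid1024.zbar_spacing
        b = simulate_mirror_measurement(
            get_preset("ideal"), ReflectorSet([z], [1.0]), grid1024, quiet, 1
        )
        sweep = simulate_mirror_sweep(
            get_preset("ideal"), grid1024, quiet, uniform_depth_bins(grid1024, 12), 1
        )
        cs = calibrate(sweep)
        p = reconstruct_aline(b.ch_I[:, 0], b.ch_II[:, 0], cs)
        mag = np.abs(p.values)
        c = grid1024.N // 2
        assert np.argmax(mag) == c + 128
        assert mag[c - 128] < 1e-6 * mag[c + 128]

    def test_n_mismatch_raises(self, grid1024, grid256, quiet):
        sweep = simulate_mirror_sweep(
            get_preset("ideal"), grid1024, quiet, uniform_depth_bins(grid1024, 12), 1
        )
        cs = calibrate(sweep)
        with pytest.raises(GridMismatchError):
            reconstruct_aline(np.zeros(256), np.zeros(256), cs)

    def test_gauge_invariance(self, grid1024, quiet):
        # (c*beta_z, beta_k/c), (dphi_z+psi, dphi_k-psi) leave the
        # side-aware reconstruction unchanged.  The symmetry is exact when
        # the vectors describe the data exactly, so use the ground-truth
        # correction set of a leakage-free scene; with fitted vectors the
        # residual is O(fit error * psi).
        from quadcal import ChannelImbalance
        from quadcal.calibrate import CorrectionSet

        blc = get_preset("bandlimited")
        imb = ChannelImbalance(  # chromatic part only; flat depth response
            blc.A_I, blc.A_II, blc.Omega_I, blc.Omega_II
        )
        cs = CorrectionSet(
            beta_z=np.ones(grid1024.N),
            dphi_z=np.zeros(grid1024.N),
            beta_k=imb.beta_k(grid1024.k),
            dphi_k=imb.dphi_k(grid1024.k),
            grid=grid1024,
        )
        for bins in (200, -150):
            z = bins * grid1024.zbar_spacing
            b = simulate_mirror_measurement(
                imb, ReflectorSet([z], [1.0]), grid1024, quiet, 1, mode="dirac"
            )
            m = coherent_average(b)
            p0 = reconstruct_measurement(m, cs)
            p1 = reconstruct_measurement(m, cs.gauge_shift(1.3, 0.2))
            scale = np.max(np.abs(p0.values))
            np.testing.assert_allclose(p1.values, p0.values, atol=1e-10 * scale)

    def test_amplitude_gauge_invariance_two_sided(self, grid1024, quiet):
        # the amplitude-only gauge (c, psi=0) is also an exact symmetry of
        # the two-sided (imaging) reconstruction path
        imb = get_preset("realistic")
        sweep = simulate_mirror_sweep(
            imb, grid1024, quiet, uniform_depth_bins(grid1024, 15), 1
        )
        cs = calibrate(sweep)
        b = simulate_mirror_measurement(
            imb, ReflectorSet([0.4, -0.7], [1.0, 0.6]), grid1024, quiet, 1
        )
        p0 = reconstruct_aline(b.ch_I[:, 0], b.ch_II[:, 0], cs)
        p1 = reconstruct_aline(b.ch_I[:, 0], b.ch_II[:, 0], cs.gauge_shift(1.3, 0.0))
        scale = np.max(np.abs(p0.values))
        np.testing.assert_allclose(p1.values, p0.values, atol=1e-10 * scale)


class TestExtinctionMetrics:
    def test_perfect_tone_reports_numerical_floor(self):
        N = 1024
        th = _tone(N, 100)
        p = reconstruct_aline(np.cos(th), np.cos(th + np.pi / 2), mode="direct")
        rep = extinction_ratio(p, 100 * 2 * np.pi / N / 2)
        assert rep.extinction_db > 120

    def test_amp_mismatch_60db(self):
        # 1e-3 amplitude mismatch, direct reconstruction: suppression of the
        # mirror peak relative to single-channel processing = 60.0 dB
        N = 4096
        th = _tone(N, 512)
        s_i, s_ii = np.cos(th), 1.001 * np.sin(th)
        rec = reconstruct_aline(s_i, s_ii, mode="direct")
        ref = reconstruct_aline(s_i, s_ii, mode="standard")
        assert mirror_suppression(rec, ref) == pytest.approx(60.0, abs=0.1)

    def test_amp_mismatch_20db(self):
        N = 4096
        th = _tone(N, 512)
        s_i, s_ii = np.cos(th), 1.1 * np.sin(th)
        rec = reconstruct_aline(s_i, s_ii, mode="direct")
        ref = reconstruct_aline(s_i, s_ii, mode="standard")
        assert mirror_suppression(rec, ref) == pytest.approx(20.0, abs=0.1)

    def test_extinction_is_main_minus_mirror(self):
        N = 1024
        th = _tone(N, 80)
        p = reconstruct_aline(np.cos(th), 1.01 * np.sin(th), mode="direct")
        rep = extinction_ratio(p, -80 * np.pi / N * 2 / 2)
        assert rep.extinction_db == rep.main_db - rep.mirror_db
        assert rep.mirror_pos == pytest.approx(-rep.main_pos, abs=1e-9)


class TestAnalyticExtinction:
    def test_amp_only(self):
        assert analytic_extinction(QuadratureError(amp_mismatch=0.001)) == (
            pytest.approx(60.0)
        )

    def test_phase_only(self):
        assert analytic_extinction(QuadratureError(phase_offset=0.002)) == (
            pytest.approx(60.0)
        )

    def test_zero_error_inf(self):
        assert analytic_extinction(QuadratureError()) == float("inf")

    def test_measured_agreement_amp(self):
        # measured suppression matches the closed form within 0.1 dB for
        # errors <= 1%
        N = 4096
        th = _tone(N, 512)
        for eps in (0.01, 0.005, 0.001):
            rec = reconstruct_aline(np.cos(th), (1 + eps) * np.sin(th), mode="direct")
            ref = reconstruct_aline(np.cos(th), np.sin(th), mode="standard")
            measured = mirror_suppression(rec, ref)
            assert measured == pytest.approx(
                analytic_extinction(QuadratureError(amp_mismatch=eps)), abs=0.1
            )

    def test_measured_agreement_phase(self):
        # the phase-only closed form (2/dphi) corresponds to the
        # main-over-mirror ratio of the complex profile
        N = 4096
        th = _tone(N, 512)
        for dphi in (0.01, 0.002):
            rec = reconstruct_aline(
                np.cos(th), np.sin(th + dphi), mode="direct"
            )
            rep = extinction_ratio(rec, -512 * np.pi / N * 2 / 2)
            assert rep.extinction_db == pytest.approx(
                analytic_extinction(QuadratureError(phase_offset=dphi)), abs=0.1
            )


class TestPeakShape:
    def test_six_db_gain_fwhm_preserved(self):
        N = 2048
        th = _tone(N, 300)
        s_i = np.cos(th)
        pc = reconstruct_aline(s_i, -np.sin(th), mode="direct")
        ps = reconstruct_aline(s_i, s_i, mode="standard")
        gain, dfwhm, _ = peak_shape_metrics(pc, ps)
        assert gain == pytest.approx(20 * np.log10(2), abs=0.05)
        assert abs(dfwhm) < 0.1

    def test_noise_floor_3db(self):
        # independent equal-variance noise in the two channels raises the
        # floor of the complex profile by 3 dB (+- 0.3 over 20 seeds)
        N = 1024
        th = _tone(N, 150)
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n1 = 0.03 * rng.standard_normal(N)
            n2 = 0.03 * rng.standard_normal(N)
            pc = reconstruct_aline(
                np.cos(th) + n1, -np.sin(th) + n2, mode="direct"
            )
            ps = reconstruct_aline(np.cos(th) + n1, np.zeros(N), mode="standard")
            _, _, dfloor = peak_shape_metrics(pc, ps)
            diffs.append(dfloor)
        assert np.mean(diffs) == pytest.approx(3.0, abs=0.3)

    def test_reference_equals_input_gives_zeros(self):
        N = 512
        th = _tone(N, 60)
        p = reconstruct_aline(np.cos(th), np.cos(th), mode="standard")
        gain, dfwhm, dfloor = peak_shape_metrics(p, p)
        assert gain == 0.0 and dfwhm == 0.0 and dfloor == 0.0

    def test_energy_return_bookkeeping(self, grid1024, quiet):
        # calibrated main peak gain over single-channel = 20*log10(2);
        # |main_u| + |mirror_u| >= |main_cal| - tol
        imb = get_preset("realistic")
        sweep = simulate_mirror_sweep(
            imb, grid1024, quiet, uniform_depth_bins(grid1024, 15), 1
        )
        cs = calibrate(sweep)
        z = 220 * grid1024.zbar_spacing
        b = simulate_mirror_measurement(
            imb, ReflectorSet([z], [1.0]), grid1024, quiet, 1
        )
        m = coherent_average(b)
        cal = reconstruct_measurement(m, cs, "calibrated")
        std = reconstruct_measurement(m, None, "standard")
        gain, dfwhm, _ = peak_shape_metrics(cal, std)
        assert gain == pytest.approx(20 * np.log10(2), abs=0.05)
        assert abs(dfwhm) < 0.1
        c = grid1024.N // 2
        mag_std = np.abs(std.values)
        mag_cal = np.abs(cal.values)
        main_u = mag_std[c + 220]
        mirror_u = mag_std[c - 220]
        # exact to machine precision only for a perfectly calibrated
        # system; residual vector errors of a fitted calibration are at
        # the 1e-4 relative level
        assert main_u + mirror_u >= mag_cal[c + 220] * (1.0 - 1e-3)

    def test_energy_return_exact_ideal(self, grid1024, quiet):
        # with an ideal system the bookkeeping is exact
        imb = get_preset("ideal")
        sweep = simulate_mirror_sweep(
            imb, grid1024, quiet, uniform_depth_bins(grid1024, 12), 1
        )
        cs = calibrate(sweep)
        z = 220 * grid1024.zbar_spacing
        b = simulate_mirror_measurement(
            imb, ReflectorSet([z], [1.0]), grid1024, quiet, 1
        )
        m = coherent_average(b)
        cal = reconstruct_measurement(m, cs, "calibrated")
        std = reconstruct_measurement(m, None, "standard")
        c = grid1024.N // 2
        main_u = np.abs(std.values[c + 220])
        mirror_u = np.abs(std.values[c - 220])
        assert main_u + mirror_u >= np.abs(cal.values[c + 220]) - 1e-6


class TestResolutionPreservation:
    def test_fwhm_across_depths(self, grid1024, quiet):
        imb = get_preset("realistic")
        sweep = simulate_mirror_sweep(
            imb, grid1024, quiet, uniform_depth_bins(grid1024, 15), 1
        )
        cs = calibrate(sweep)
        for bins in (-350, -120, 90, 400):
            z = (bins + 0.4) * grid1024.zbar_spacing  # off-bin: finite FWHM
            b = simulate_mirror_measurement(
                imb, ReflectorSet([z], [1.0]), grid1024, quiet, 1
            )
            m = coherent_average(b)
            cal = reconstruct_measurement(m, cs, "calibrated")
            std = reconstruct_measurement(m, None, "standard")
            _, dfwhm, _ = peak_shape_metrics(cal, std)
            assert abs(dfwhm) < 0.1


class TestEvaluateSweep:
    def test_empty_heldout(self, grid1024, quiet):
        sweep = simulate_mirror_sweep(
            get_preset("ideal"), grid1024, quiet, uniform_depth_bins(grid1024, 12), 1
        )
        cs = calibrate(sweep)
        table = evaluate_sweep([], cs)
        assert table.empty

    def test_phantom_ghost_suppression(self, grid1024, quiet):
        # layered phantom: ghosts visible uncorrected, suppressed calibrated
        from quadcal import simulate_bscan_phantom

        imb = get_preset("realistic")
        sweep = simulate_mirror_sweep(
            imb, grid1024, quiet, uniform_depth_bins(grid1024, 15), 1
        )
        cs = calibrate(sweep)
        layers = ReflectorSet([0.5, 0.58, 0.66], [1.0, 0.7, 0.5])
        col = simulate_bscan_phantom(imb, grid1024, quiet, [layers], M=1)[0]
        m = coherent_average(col)
        direct = reconstruct_measurement(m, None, "direct")
        cal = reconstruct_measurement(m, cs, "calibrated")
        c = grid1024.N // 2
        ghost_bin = c - int(round(0.5 / grid1024.zbar_spacing))
        main_bin = c + int(round(0.5 / grid1024.zbar_spacing))
        gd = np.abs(direct.values[ghost_bin]) / np.abs(direct.values[main_bin])
        gc = np.abs(cal.values[ghost_bin]) / np.abs(cal.values[main_bin])
        assert gc < gd / 30  # ~30 dB further suppression
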