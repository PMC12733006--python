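"""LAOS decomposition: Fourier/Chebyshev round trips, measures, loops."""

import numpy as np
import pytest

import spc_rheoflow as sr
from spc_rheoflow import laos


def _random_spec(rng, max_order=9):
    orders = np.arange(1, max_order + 1, 2)
    e = {1: float(10.0 ** rng.uniform(1, 3))}
    v = {1: float(10.0 ** rng.uniform(0, 2))}
    for n in orders[1:]:
        e[int(n)] = float(rng.uniform(-0.2, 0.2) * e[1])
        v[int(n)] = float(rng.uniform(-0.2, 0.2) * v[1])
    return sr.WaveformSpec(gamma0=float(10.0 ** rng.uniform(-1, 0.5)),
                           omega=float(10.0 ** rng.uniform(-0.5, 0.5)),
                           e_coeffs=e, v_coeffs=v)


class TestDecompose:
    def test_linear_waveform_yields_first_harmonic_only(self):
        cyc = sr.make_laos_waveform(sr.WaveformSpec(
            gamma0=1.0, omega=1.0, e_coeffs={1: 100.0}, v_coeffs={1: 50.0}))
        sp = sr.decompose(cyc)
        assert sp.G_prime_n[0] == pytest.approx(100.0, rel=1e-10)
        assert sp.G_dprime_n[0] == pytest.approx(50.0, rel=1e-10)
        assert np.all(np.abs(sp.G_prime_n[1:]) <= 1e-10 * 100)
        assert np.all(np.abs(sp.G_dprime_n[1:]) <= 1e-10 * 100)

    def test_round_trip_recovers_all_coefficients_to_1e8(self):
        # generator -> decompose -> chebyshev equals generating set,
        # orders up to 9, 100 random specs
        rng = np.random.default_rng(1234)
        for _ in range(100):
            spec = _random_spec(rng)
            cyc = sr.make_laos_waveform(spec)
            cheb = sr.chebyshev_from_fourier(sr.decompose(cyc))
            for i, n in enumerate(cheb.orders):
                assert cheb.e[i] == pytest.approx(spec.e_coeffs[int(n)],
                                                  rel=1e-8, abs=1e-8)
                assert cheb.v[i] == pytest.approx(spec.v_coeffs[int(n)],
                                                  rel=1e-8, abs=1e-8)

    def test_matches_direct_projection_integrals(self):
        # brute-force oracle: trapezoid projections of sigma on sin/cos(n w t)
        spec = sr.WaveformSpec(gamma0=1.0, omega=1.0,
                               e_coeffs={1: 100.0, 3: 10.0, 5: 2.0},
                               v_coeffs={1: 50.0, 3: -5.0, 5: 1.0},
                               n_cycles=1, samples_per_cycle=10_000)
        cyc = sr.make_laos_waveform(spec)
        sp = sr.decompose(cyc)
        t = cyc.time
        for i, n in enumerate(sp.orders):
            a = 2 / len(t) * np.sum(cyc.stress * np.sin(n * t))
            b = 2 / len(t) * np.sum(cyc.stress * np.cos(n * t))
            assert sp.G_prime_n[i] == pytest.approx(a, rel=1e-8, abs=1e-8)
            assert sp.G_dprime_n[i] == pytest.approx(b, rel=1e-8, abs=1e-8)

    def test_start_time_invariance_via_phase_alignment(self):
        # same physical waveform sampled from a shifted start returns
        # identical harmonics after phase referencing
        spec = sr.WaveformSpec(gamma0=1.0, omega=1.0,
                               e_coeffs={1: 100.0, 3: 10.0},
                               v_coeffs={1: 50.0, 3: -5.0})
        cyc = sr.make_laos_waveform(spec)
        ref = sr.decompose(cyc)
        shift = 37  # samples
        rolled = laos.OscillatoryCycle(
            time=cyc.time, strain=np.roll(cyc.strain, -shift),
            strain_rate=np.roll(cyc.strain_rate, -shift),
            stress=np.roll(cyc.stress, -shift),
            gamma0=cyc.gamma0, omega=cyc.omega)
        got = sr.decompose(rolled)
        np.testing.assert_allclose(got.G_prime_n, ref.G_prime_n,
                                   rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(got.G_dprime_n, ref.G_dprime_n,
                                   rtol=1e-8, atol=1e-8)

    def test_residual_rms_equals_truncation_error(self):
        # stress reconstructed from retained harmonics leaves exactly the
        # truncated (order > max) content as residual
        spec = sr.WaveformSpec(gamma0=1.0, omega=1.0,
                               e_coeffs={1: 100.0, 5: 8.0},
                               v_coeffs={1: 50.0})
        cyc = sr.make_laos_waveform(spec)
        sp3 = sr.decompose(cyc, max_order=3)
        # order-5 term alone has RMS gamma0*|e5|/sqrt(2)
        assert sp3.residual_rms == pytest.approx(8.0 / np.sqrt(2), rel=1e-6)
        sp9 = sr.decompose(cyc, max_order=9)
        assert sp9.residual_rms < 1e-10

    def test_noise_power_reported_not_fit(self):
        spec = sr.WaveformSpec(gamma0=1.0, omega=1.0, e_coeffs={1: 100.0},
                               v_coeffs={1: 50.0}, noise_sd=1.0, seed=3)
        sp = sr.decompose(sr.make_laos_waveform(spec))
        assert sp.residual_rms == pytest.approx(1.0, rel=0.1)

    def test_e3_recovery_unbiased_under_noise(self):
        # 1% stress noise, many seeds: mean recovered e3/e1 is unbiased
        truth = 10.0 / 100.0
        vals = []
        for seed in range(300):
            spec = sr.WaveformSpec(gamma0=1.0, omega=1.0,
                                   e_coeffs={1: 100.0, 3: 10.0},
                                   v_coeffs={1: 50.0, 3: -5.0},
                                   noise_sd=1.2, seed=seed)
            cheb = sr.chebyshev_from_fourier(
                sr.decompose(sr.make_laos_waveform(spec), zero_tol=0.0))
            vals.append(cheb.e3_over_e1)
        sem = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - truth) < 4 * sem + 1e-4

    def test_nonuniform_sampling_rejected(self):
        t = np.linspace(0, 2 * np.pi, 257)[:-1].copy()
        t[5] += 1e-3
        with pytest.raises(ValueError, match="uniform"):
            laos.OscillatoryCycle(time=t, strain=np.sin(t),
                                  strain_rate=np.cos(t),
                                  stress=np.sin(t), gamma0=1.0, omega=1.0)

    def test_non_integer_cycle_count_rejected(self):
        t = np.arange(300) * (2 * np.pi / 256)  # 1.17 cycles
        cyc = laos.OscillatoryCycle(time=t, strain=np.sin(t),
                                    strain_rate=np.cos(t), stress=np.sin(t),
                                    gamma0=1.0, omega=1.0)
        with pytest.raises(ValueError, match="integer"):
            sr.decompose(cyc)


class TestChebyshevConversion:
    def test_sign_rule_at_third_order(self):
        sp = laos.HarmonicSpectrum(orders=[1, 3], G_prime_n=[100.0, -10.0],
                                   G_dprime_n=[50.0, 5.0], residual_rms=0.0,
                                   omega=1.0)
        cheb = sr.chebyshev_from_fourier(sp)
        assert cheb.coeff("e", 3) == pytest.approx(10.0)

    def test_viscous_division_rule(self):
        sp = laos.HarmonicSpectrum(orders=[3], G_prime_n=[0.0],
                                   G_dprime_n=[5.0], residual_rms=0.0)
        cheb = sr.chebyshev_from_fourier(sp, omega=2.0)
        assert cheb.coeff("v", 3) == pytest.approx(2.5)

    def test_invalid_omega_rejected(self):
        sp = laos.HarmonicSpectrum(orders=[1], G_prime_n=[1.0],
                                   G_dprime_n=[1.0], residual_rms=0.0)
        with pytest.raises(ValueError):
            sr.chebyshev_from_fourier(sp, omega=0.0)


class TestNonlinearMeasures:
    def test_series_forms_match_worked_values(self):
        cheb = laos.ChebyshevSet(orders=[1, 3], e=[100.0, 10.0],
                                 v=[50.0, -5.0])
        m = sr.nonlinear_measures(cheb)
        assert m.G_prime_M == pytest.approx(70.0)
        assert m.G_prime_L == pytest.approx(110.0)
        assert m.S == pytest.approx(40.0 / 110.0)
        assert m.eta_prime_M == pytest.approx(65.0)
        assert m.eta_prime_L == pytest.approx(45.0)
        assert m.T_ratio == pytest.approx(-20.0 / 45.0)

    def test_series_forms_match_slope_oracle(self):
        # independent oracle: numerical tangent at gamma=0 and secant at
        # gamma=+/-gamma0 of the reconstructed elastic/viscous projections
        rng = np.random.default_rng(7)
        for _ in range(20):
            cheb = laos.ChebyshevSet(
                orders=[1, 3, 5],
                e=[100.0, rng.uniform(-20, 20), rng.uniform(-5, 5)],
                v=[50.0, rng.uniform(-10, 10), rng.uniform(-3, 3)])
            m = sr.nonlinear_measures(cheb)
            GpM, GpL, etaM, etaL = laos.slope_measures(cheb)
            assert m.G_prime_M == pytest.approx(GpM, rel=5e-3, abs=1e-6)
            assert m.G_prime_L == pytest.approx(GpL, rel=1e-9)
            assert m.eta_prime_M == pytest.approx(etaM, rel=5e-3, abs=1e-6)
            assert m.eta_prime_L == pytest.approx(etaL, rel=1e-9)

    def test_linear_material_has_zero_ratios(self):
        cheb = laos.ChebyshevSet(orders=[1], e=[100.0], v=[50.0])
        m = sr.nonlinear_measures(cheb)
        assert m.S == 0.0 and m.T_ratio == 0.0

    def test_zero_denominator_marks_ratio_undefined(self):
        cheb = laos.ChebyshevSet(orders=[1, 3], e=[1.0, -1.0], v=[1.0, 1.0])
        m = sr.nonlinear_measures(cheb)
        assert np.isnan(m.S)


class TestLissajous:
    def test_purely_elastic_loop_has_zero_area(self):
        cyc = sr.make_laos_waveform(sr.WaveformSpec(
            gamma0=1.0, omega=1.0, e_coeffs={1: 100.0, 3: 5.0}, v_coeffs={}))
        loop = sr.lissajous(cyc)
        assert loop.enclosed_area_elastic == pytest.approx(0.0, abs=1e-8)

    def test_elastic_loop_area_equals_dissipation_identity(self):
        # energy identity: area of stress-strain loop = pi*gamma0^2*G''_1
        rng = np.random.default_rng(11)
        for _ in range(20):
            spec = _random_spec(rng)
            cyc = sr.make_laos_waveform(spec)
            loop = sr.lissajous(cyc)
            expect = np.pi * spec.gamma0**2 * spec.v_coeffs[1] * spec.omega
            assert loop.enclosed_area_elastic == pytest.approx(abs(expect),
                                                               rel=1e-3)

    def test_viscous_loop_area_equals_elastic_first_harmonic(self):
        # the stress-vs-rate loop encloses pi*gamma0^2*e1 (recoverable
        # energy analogue): it tracks the elastic first harmonic, not v1
        for e1, v1 in ((100.0, 50.0), (40.0, 50.0), (100.0, 10.0)):
            cyc = sr.make_laos_waveform(sr.WaveformSpec(
                gamma0=1.0, omega=1.0, e_coeffs={1: e1},
                v_coeffs={1: v1}))
            area = sr.lissajous(cyc).enclosed_area_viscous
            assert area == pytest.approx(np.pi * e1, rel=1e-3)
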