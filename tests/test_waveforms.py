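"""Closed-form wave profiles, their governing-equation residuals, and drivers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waveplast import (
    BranchError,
    CnoidalParams,
    ComplexField,
    GridError,
    NoiseParams,
    PlaneWaveSpec2D,
    ThetaGammaParams,
    TravelingWaveParams,
    add_gaussian_noise,
    cnoidal_profile,
    interference_field_2d,
    make_grid,
    profile_residuals,
    soliton_amplitude,
    soliton_profile,
    superpose,
    theta_gamma_field,
    traveling_field,
)

ALPHA, BETA = 0.8, -1.2
P_REF = TravelingWaveParams(ALPHA, BETA)


class TestSoliton:
    def test_peak_amplitude_closed_form(self):
        # A = -3*alpha/(2*beta) = 1.0 for the reference parameters
        assert soliton_amplitude(P_REF) == pytest.approx(1.0)
        assert soliton_profile(0.0, P_REF) == pytest.approx(1.0)

    def test_analytic_residual_of_profile_equation(self):
        # substitute the sech^2 profile into Phi'' = a*Phi + b*Phi^2 using
        # the exact second derivative 2*A*q^2*sech^2*(2*tanh^2 - sech^2)
        xi = np.linspace(-30, 30, 2001)
        q = 0.5 * np.sqrt(ALPHA)
        A = soliton_amplitude(P_REF)
        sech = 1.0 / np.cosh(q * xi)
        tanh = np.tanh(q * xi)
        phi = A * sech**2
        d2 = 2 * A * q**2 * sech**2 * (2 * tanh**2 - sech**2)
        assert np.max(np.abs(d2 - ALPHA * phi - BETA * phi**2)) < 1e-10

    def test_localization_and_symmetry(self):
        xi = np.linspace(-80, 80, 4001)
        phi = soliton_profile(xi, P_REF)
        far = np.abs(xi) > 40 / np.sqrt(ALPHA)
        assert np.all(np.abs(phi[far]) < 1e-8)
        assert np.allclose(phi, phi[::-1])

    @pytest.mark.parametrize(
        "alpha, beta, c1",
        [(-0.8, -1.2, 0.0), (0.8, 1.2, 0.0), (0.8, -1.2, 0.1)],
    )
    def test_branch_errors(self, alpha, beta, c1):
        with pytest.raises(BranchError):
            soliton_profile(0.0, TravelingWaveParams(alpha, beta, c1=c1))


class TestCnoidal:
    def test_roots_consistent_and_modulus_round_trip(self):
        p = CnoidalParams.from_modulus(ALPHA, BETA, 0.9)
        assert p.m == pytest.approx(0.9, abs=1e-12)
        r1, r2, r3 = p.roots
        assert r1 <= r2 <= r3
        # root triple satisfies the first-integral cubic
        for r in p.roots:
            assert 2 * BETA / 3 * r**3 + ALPHA * r**2 + p.c1 == pytest.approx(
                0.0, abs=1e-12
            )
        q = CnoidalParams.from_c1(ALPHA, BETA, p.c1)
        assert q.m == pytest.approx(p.m, abs=1e-9)

    def test_small_modulus_limit_is_sinusoid(self):
        p = CnoidalParams.from_modulus(ALPHA, BETA, 1e-4)
        xi = np.linspace(-5, 5, 1001)
        phi = cnoidal_profile(xi, p)
        mean = 0.5 * (p.roots[1] + p.roots[2])
        amp = 0.5 * (p.roots[2] - p.roots[1])
        fitted = mean + amp * np.cos(2 * p.nu * xi)
        assert np.max(np.abs(phi - fitted)) < 1e-3

    def test_large_modulus_limit_is_soliton(self):
        p = CnoidalParams.from_modulus(ALPHA, BETA, 1.0 - 1e-8)
        xi = np.linspace(-5, 5, 1001)
        assert np.max(
            np.abs(cnoidal_profile(xi, p) - soliton_profile(xi, P_REF))
        ) < 1e-3

    @pytest.mark.parametrize("m", [0.3, 0.9, 0.99])
    def test_first_integral_residual_small(self, m):
        p = CnoidalParams.from_modulus(ALPHA, BETA, m)
        xi = np.arange(-10, 10, 0.002)
        phi = cnoidal_profile(xi, p)
        tw = TravelingWaveParams(ALPHA, BETA, c1=p.c1)
        ode, integral = profile_residuals(phi, xi, tw)
        assert integral < 1e-6
        assert ode < 1e-5

    @pytest.mark.parametrize("m", [0.5, 0.95])
    def test_period_matches_elliptic_integral(self, m):
        # autocorrelation peak of the sampled profile vs 2K(m)/nu
        p = CnoidalParams.from_modulus(ALPHA, BETA, m)
        lam = p.wavelength
        nper, nsamp = 8, 4096
        dx = lam / nsamp
        xi = np.arange(nper * nsamp) * dx
        phi = cnoidal_profile(xi, p)
        phi = phi - phi.mean()
        # circular autocorrelation over a whole number of periods
        ac = np.fft.irfft(np.abs(np.fft.rfft(phi)) ** 2)
        start, end = int(0.5 * lam / dx), int(1.5 * lam / dx)
        lag = start + np.argmax(ac[start:end])
        assert lag * dx == pytest.approx(lam, rel=1e-3)

    def test_complex_roots_rejected(self):
        with pytest.raises(BranchError):
            CnoidalParams.from_c1(ALPHA, BETA, 1.0)  # c1 > 0: single real root


class TestProfileResiduals:
    def test_soliton_self_consistency_on_fine_grid(self):
        xi = np.arange(-20, 20, 0.01 / np.sqrt(ALPHA))
        phi = soliton_profile(xi, P_REF)
        ode, integral = profile_residuals(phi, xi, P_REF)
        assert ode < 1e-5 and integral < 1e-5

    def test_zero_profile_exact(self):
        xi = np.linspace(0, 10, 64)
        assert profile_residuals(np.zeros(64), xi, P_REF) == (0.0, 0.0)

    def test_sensitive_to_corrupted_alpha(self):
        xi = np.arange(-20, 20, 0.01)
        phi = soliton_profile(xi, P_REF)
        d_alpha = 0.2
        wrong = TravelingWaveParams(ALPHA + d_alpha, BETA)
        ode, _ = profile_residuals(phi, xi, wrong)
        assert ode > 0.1 * d_alpha * phi.max()

    def test_nonuniform_xi_rejected(self):
        xi = np.linspace(0, 1, 64) ** 2
        with pytest.raises(ValueError):
            profile_residuals(np.zeros(64), xi, P_REF)


class TestTravelingField:
    def test_t0_equals_raw_profile(self):
        g = make_grid(1, (-50, 50), 500)
        f = traveling_field(lambda xi: soliton_profile(xi, P_REF), g, 0.0, 1.0)
        assert np.allclose(f.values.real, soliton_profile(g.x, P_REF))
        assert np.all(f.values.imag == 0)

    def test_shift_identity_on_grid_multiples(self):
        # c*dt equal to a whole number of grid spacings -> exact roll
        g = make_grid(1, (-50, 50), 500)
        fn = lambda xi: soliton_profile(xi, P_REF)
        c, dt = 1.0, 5 * g.spacing[0]
        f1 = traveling_field(fn, g, 12.0, c)
        f0 = traveling_field(fn, g, 12.0 - dt, c)
        assert np.allclose(f1.values, np.roll(f0.values, 5), atol=1e-12)

    def test_periodic_wraparound_after_one_domain_length(self):
        g = make_grid(1, (-50, 50), 500)
        fn = lambda xi: soliton_profile(xi, P_REF)
        f0 = traveling_field(fn, g, 0.0, 1.0)
        fL = traveling_field(fn, g, 100.0, 1.0)
        assert np.allclose(f0.values, fL.values, atol=1e-12)

    def test_rejects_2d_grid(self):
        g = make_grid(2, (-1, 1), 16)
        with pytest.raises(GridError):
            traveling_field(lambda xi: xi, g, 0.0, 1.0)


class TestSuperposeAndNoise:
    def test_single_field_unchanged_and_cancellation(self):
        g = make_grid(1, (-50, 50), 500)
        f = traveling_field(lambda xi: soliton_profile(xi, P_REF), g, 0.0, 1.0)
        assert np.array_equal(superpose([f]).values, f.values)
        neg = ComplexField(g, -f.values)
        assert np.all(superpose([f, neg]).values == 0)

    def test_grid_mismatch_rejected(self):
        a = ComplexField(make_grid(1, (0, 1), 16), np.zeros(16, complex))
        b = ComplexField(make_grid(1, (0, 2), 16), np.zeros(16, complex))
        with pytest.raises(GridError):
            superpose([a, b])

    def test_constructive_beat_maxima(self):
        # two incommensurate cnoidal waves: somewhere their crests align,
        # so peak intensity approaches (max1 + max2)^2
        g = make_grid(1, (-50, 50), 2000)
        p1 = CnoidalParams.from_modulus(ALPHA, BETA, 0.9)
        p2 = CnoidalParams.from_modulus(ALPHA, BETA, 0.5)
        f1 = traveling_field(lambda xi: cnoidal_profile(xi, p1), g, 0.0, 1.0)
        f2 = traveling_field(lambda xi: cnoidal_profile(xi, p2), g, 0.0, 1.0)
        intensity = superpose([f1, f2]).intensity().values
        top = np.abs(f1.values).max() + np.abs(f2.values).max()
        assert intensity.max() > 0.9 * top**2
        # beat maximum sits where both components are near their crests
        i = int(np.argmax(intensity))
        assert np.abs(f1.values[i]) > 0.93 * np.abs(f1.values).max()
        assert np.abs(f2.values[i]) > 0.93 * np.abs(f2.values).max()

    def test_noise_identity_reproducibility_and_sd(self):
        g = make_grid(1, (0, 1), 100_000)
        f = ComplexField(g, np.zeros(g.shape, complex))
        assert np.array_equal(
            add_gaussian_noise(f, NoiseParams(0.0, 1)).values, f.values
        )
        n1 = add_gaussian_noise(f, NoiseParams(0.1, 42))
        n2 = add_gaussian_noise(f, NoiseParams(0.1, 42))
        assert np.array_equal(n1.values, n2.values)
        assert n1.values.real.std() == pytest.approx(0.1, abs=0.002)
        assert n1.values.imag.std() == pytest.approx(0.1, abs=0.002)


class TestThetaGamma:
    def test_zero_envelope_is_pure_carrier(self):
        g = make_grid(1, (-50, 50), 500)
        p = ThetaGammaParams(omega_gamma=1.0, c=1.0, amplitude=0.0)
        f = theta_gamma_field(g, 3.0, p)
        assert np.allclose(f.values.real, np.sin(1.0 * (g.x - 3.0)))

    def test_envelope_bound(self):
        g = make_grid(1, (-50, 50), 500)
        p = ThetaGammaParams(omega_gamma=1.0, amplitude=0.7)
        for t in np.linspace(0, 100, 37):
            assert np.max(np.abs(theta_gamma_field(g, t, p).values)) <= 1.7 + 1e-12

    def test_temporal_spectrum_carrier_plus_sidebands(self):
        # commensurate choice: carrier temporal frequency at bin 80 of the
        # record, theta at 1/8 of the carrier -> sidebands at bins 70, 90
        g = make_grid(1, (-50, 50), 500)
        f_theta = 1.0 / (16 * np.pi)
        p = ThetaGammaParams(omega_gamma=1.0, c=1.0, amplitude=0.8, f_theta=f_theta)
        T, n = 2 * np.pi * 80, 8192
        ts = np.arange(n) * (T / n)
        x0 = float(g.x[250])
        sig = (1 + p.amplitude * np.sin(2 * np.pi * p.f_theta * ts)) * np.sin(
            p.omega_gamma * (x0 - p.c * ts)
        )
        # closed form above must agree with the field evaluation
        probe = theta_gamma_field(g, float(ts[17]), p).values[250].real
        assert probe == pytest.approx(sig[17], abs=1e-12)
        P = np.abs(np.fft.rfft(sig)) ** 2
        assert set(np.argsort(P)[-3:]) == {70, 80, 90}


class TestInterference2D:
    def test_single_wave_constant_along_wavefront(self):
        g = make_grid(2, (-10, 10), 64)
        f = interference_field_2d(g, [PlaneWaveSpec2D(0.0)], 0.0)
        intensity = f.intensity().values
        # propagation along x: each column is constant in y
        assert np.max(np.ptp(intensity, axis=0)) < 1e-12

    def test_lattice_symmetry_rotations_exact(self):
        # rotating the wave set by its own lattice angle reproduces the
        # same direction set (a 180-degree wave aliases to 0 at t=0, when
        # cos is even in its argument), so the snapshot is identical
        # node-for-node
        g = make_grid(2, (-10, 10), 64)
        three = [PlaneWaveSpec2D(a) for a in (0.0, 60.0, 120.0)]
        rot3 = [PlaneWaveSpec2D(a + 60.0) for a in (0.0, 60.0, 120.0)]
        f = interference_field_2d(g, three, 0.0)
        fr = interference_field_2d(g, rot3, 0.0)
        assert np.allclose(f.intensity().values, fr.intensity().values, atol=1e-10)
        two = [PlaneWaveSpec2D(a) for a in (0.0, 90.0)]
        rot2 = [PlaneWaveSpec2D(a + 90.0) for a in (0.0, 90.0)]
        f2 = interference_field_2d(g, two, 0.0)
        fr2 = interference_field_2d(g, rot2, 0.0)
        assert np.allclose(f2.intensity().values, fr2.intensity().values, atol=1e-10)

    def test_empty_spec_list_rejected(self):
        g = make_grid(2, (-1, 1), 16)
        with pytest.raises(ValueError):
            interference_field_2d(g, [], 0.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    alpha=st.floats(0.2, 3.0),
    beta=st.floats(-3.0, -0.2),
    m=st.floats(0.05, 0.95),
)
def test_generated_profiles_satisfy_their_equations(alpha, beta, m):
    """Any cnoidal branch constructed from the roots keeps both residuals tiny."""
    p = CnoidalParams.from_modulus(alpha, beta, m)
    step = 0.002 / np.sqrt(alpha)
    xi = np.arange(-6 / np.sqrt(alpha), 6 / np.sqrt(alpha), step)
    phi = cnoidal_profile(xi, p)
    tw = TravelingWaveParams(alpha, beta, c1=p.c1)
    ode, integral = profile_residuals(phi, xi, tw)
    scale = max(1.0, np.abs(phi).max()) ** 3 * max(1.0, alpha)
    assert ode < 1e-5 * scale
    assert integral < 1e-6 * scale
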