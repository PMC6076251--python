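"""Unit and property tests for the per-wavenumber shear-bending dynamics."""

import math
from fractions import Fraction

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import eig

import filarelax as fx
from conftest import random_props

_PI = Fraction(math.pi)


def general_eigen_rates(props, q):
    """Oracle: generalized eigenvalues of the pencil (K, C), exact route.

    Builds the matrix entries in exact rational arithmetic from the
    primitive parameters, expands det(K - lam*C) by brute force, and
    solves the quadratic at 70 decimal digits.  Double-precision QZ
    cannot resolve the slow rate once the two rates are more than ~10
    decades apart, so exact arithmetic is the only reference able to
    certify the full parameter space.
    """
    E, G, r, kap, eta, eb, es, qq = (
        Fraction(x)
        for x in (
            props.E, props.G, props.r, props.kappa,
            props.eta, props.eta_b, props.eta_s, q,
        )
    )
    A = _PI * r**2
    I = _PI * r**4 / 4
    B, kS = E * I, kap * G * A
    c11 = eb * I * qq**2 + es * A
    c12 = qq * es * A
    c22 = es * A * qq**2 + eta
    k11 = B * qq**2 + kS
    k12 = qq * kS
    k22 = kS * qq**2
    a = c11 * c22 - c12**2
    b = -(c11 * k22 + c22 * k11 - 2 * c12 * k12)
    c = k11 * k22 - k12**2
    with mp.workdps(70):
        fa, fb, fc = (
            mp.mpf(x.numerator) / mp.mpf(x.denominator) for x in (a, b, c)
        )
        disc = mp.sqrt(fb * fb - 4 * fa * fc)
        lam_fast = (-fb + disc) / (2 * fa)
        lam_slow = (-fb - disc) / (2 * fa)
    return np.array(sorted([float(lam_slow), float(lam_fast)]))


class TestSectionProperties:
    @pytest.mark.parametrize(
        "r, A, I",
        [
            (1e-6, 3.14159e-12, 7.85398e-25),
            (12.5e-9, 4.9087e-16, 1.91748e-32),
        ],
    )
    def test_circular_section(self, r, A, I):
        a, i = fx.section_properties(r)
        assert a == pytest.approx(A, rel=1e-4)
        assert i == pytest.approx(I, rel=1e-4)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(fx.InvalidParameterError):
            fx.section_properties(0.0)

    def test_derived_fields_consistent(self, chromosome):
        assert chromosome.B == pytest.approx(chromosome.E * chromosome.I)
        assert chromosome.S == pytest.approx(chromosome.G * chromosome.A)


class TestOverdampedMatrices:
    def test_stiffness_entry_example(self, chromosome_7um):
        _, K = fx.overdamped_matrices(chromosome_7um, 2.2e5)
        assert K[1, 1] == pytest.approx(25.887, rel=1e-4)

    def test_drag_only_damping(self, chromosome):
        C, _ = fx.overdamped_matrices(chromosome, 1e5)
        assert np.allclose(C, [[0.0, 0.0], [0.0, chromosome.eta]])

    def test_det_k_closed_form(self, chromosome_7um):
        q = 3.3e5
        _, K = fx.overdamped_matrices(chromosome_7um, q)
        detK = (
            chromosome_7um.B * chromosome_7um.kappa * chromosome_7um.S * q**4
        )
        assert np.linalg.det(K) == pytest.approx(detK, rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matrices_symmetric_psd(self, seed):
        rng = np.random.default_rng(seed)
        props = random_props(rng)
        q = float(np.exp(rng.uniform(np.log(1e2), np.log(1e8))))
        C, K = fx.overdamped_matrices(props, q)
        for M in (C, K):
            assert np.allclose(M, M.T)
            assert np.min(np.linalg.eigvalsh(M)) >= -1e-9 * np.max(np.abs(M))


class TestQuadraticInvariants:
    def test_chromosome_scalars(self, chromosome_7um):
        """detC, Nbar, detK closed forms match independent hand expansion."""
        q = 2.2e5
        M, N, P = fx.quadratic_invariants(chromosome_7um, q)
        assert math.sqrt(M) == pytest.approx(6.231e-11, rel=1e-3)
        assert math.sqrt(P) == pytest.approx(4.920e-10, rel=1e-3)
        Nbar = 5.337e-10
        assert N == pytest.approx(
            Nbar**2 - 2 * 6.2316e-11 * 4.9199e-10, rel=1e-3
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_closed_forms_match_matrix_expansion(self, seed):
        """Invariants agree with brute-force determinant expansion."""
        rng = np.random.default_rng(100 + seed)
        props = random_props(rng)
        q = float(np.exp(rng.uniform(np.log(1e2), np.log(1e8))))
        C, K = fx.overdamped_matrices(props, q)
        detC = np.linalg.det(C)
        detK = np.linalg.det(K)
        Nbar = (
            C[0, 0] * K[1, 1] + C[1, 1] * K[0, 0] - 2 * C[0, 1] * K[0, 1]
        )
        M, N, P = fx.quadratic_invariants(props, q)
        assert M == pytest.approx(detC**2, rel=1e-10)
        assert P == pytest.approx(detK**2, rel=1e-10)
        assert N == pytest.approx(Nbar**2 - 2 * detC * detK, rel=1e-6)

    def test_zero_dissipation_degenerate(self):
        props = fx.FilamentProperties(E=500, G=227, r=1e-6)
        with pytest.raises(fx.DegenerateSystemError):
            fx.quadratic_invariants(props, 1e5)

    def test_roots_are_squared_rates(self, chromosome_7um):
        q = 2.2e5
        M, N, P = fx.quadratic_invariants(chromosome_7um, q)
        spec = fx.relaxation_times(chromosome_7um, q)
        for tau in (spec.tau1, spec.tau2):
            x = 1.0 / tau**2
            assert M * x**2 - N * x + P == pytest.approx(
                0.0, abs=1e-8 * max(M * x**2, P)
            )


class TestRelaxationTimes:
    def test_table_row_18p5(self, chromosome):
        """Forward evaluation at the 18.5-um arm's fitted coefficients."""
        props = chromosome.with_internal_friction(93.0, 210.0)
        q = math.pi / (2 * 18.5e-6)
        spec = fx.relaxation_times(props, q)
        assert spec.tau1 == pytest.approx(0.235, rel=0.01)
        assert spec.tau2 == pytest.approx(1.229, rel=0.01)

    def test_seven_um_coefficients_at_dominant_q(self, chromosome_7um):
        spec = fx.relaxation_times(chromosome_7um, 2.2e5)
        assert spec.tau1 == pytest.approx(0.133, rel=0.01)
        assert spec.tau2 == pytest.approx(0.951, rel=0.01)

    def test_ordering_invariant(self, chromosome_7um):
        for q in np.geomspace(1e2, 1e8, 25):
            spec = fx.relaxation_times(chromosome_7um, q)
            assert 0 < spec.tau1 <= spec.tau2

    def test_drag_only_reduces_to_single_time(self, chromosome):
        q = 1e5
        spec = fx.relaxation_times(chromosome, q)
        tau_d = fx.relaxation_time_drag(chromosome, q)
        assert spec.tau1 == pytest.approx(tau_d, rel=1e-12)
        assert spec.tau2 == pytest.approx(tau_d, rel=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_generalized_eigenvalue_oracle(self, seed):
        """Stable closed-form route matches the eigen-solver on (K, C)."""
        rng = np.random.default_rng(1000 + seed)
        props = random_props(rng)
        q = float(np.exp(rng.uniform(np.log(1e2), np.log(1e8))))
        spec = fx.relaxation_times(props, q)
        lam = general_eigen_rates(props, q)
        assert 1.0 / spec.tau2 == pytest.approx(lam[0], rel=1e-10)
        assert 1.0 / spec.tau1 == pytest.approx(lam[1], rel=1e-10)

    def test_lapack_qz_cross_check(self, chromosome_7um):
        """Double-precision QZ agrees where the pencil is well conditioned."""
        for q in (2.2e5, 9e4, 8e4):
            C, K = fx.overdamped_matrices(chromosome_7um, q)
            lam = np.sort(np.real(eig(K, C, right=False)))
            spec = fx.relaxation_times(chromosome_7um, q)
            assert 1.0 / spec.tau2 == pytest.approx(lam[0], rel=1e-6)
            assert 1.0 / spec.tau1 == pytest.approx(lam[1], rel=1e-6)

    def test_tau2_nonincreasing_in_q(self, chromosome_7um):
        qs = np.geomspace(1e2, 1e8, 200)
        tau2 = [fx.relaxation_times(chromosome_7um, q).tau2 for q in qs]
        assert np.all(np.diff(tau2) <= 1e-12 * np.array(tau2[:-1]))


class TestLimits:
    def test_eb_time_formula(self):
        props = fx.FilamentProperties(E=500, G=227, r=1e-6, eta=1e-3)
        assert fx.relaxation_time_eb(props, 1e5) == pytest.approx(
            0.02546, rel=1e-3
        )

    def test_eb_large_q_plateau(self, chromosome_7um):
        plateau = chromosome_7um.eta_b * chromosome_7um.I / chromosome_7um.B
        assert fx.relaxation_time_eb(chromosome_7um, 1e9) == pytest.approx(
            plateau, rel=1e-4
        )

    def test_drag_time_value(self, chromosome):
        assert fx.relaxation_time_drag(chromosome, 1e7) == pytest.approx(
            1.895e-8, rel=1e-3
        )

    def test_drag_time_small_q_is_eb(self, chromosome):
        q = 1e3
        assert fx.relaxation_time_drag(chromosome, q) == pytest.approx(
            chromosome.eta / (chromosome.B * q**4), rel=1e-3
        )

    def test_drag_time_strictly_decreasing(self, chromosome):
        qs = np.geomspace(1e2, 1e8, 300)
        taus = [fx.relaxation_time_drag(chromosome, q) for q in qs]
        assert np.all(np.diff(taus) < 0)

    def test_large_q_limit_values(self, chromosome):
        props = chromosome.with_internal_friction(65.0, 162.0)
        t1, t2 = fx.large_q_limits(props)
        assert t1 == pytest.approx(0.13, rel=1e-9)
        assert t2 == pytest.approx(0.9515, rel=1e-3)

    def test_large_q_limit_zero_friction(self, chromosome):
        assert fx.large_q_limits(chromosome) == (0.0, 0.0)

    def test_small_q_limit_values(self, chromosome):
        props = chromosome.with_internal_friction(65.0, 162.0)
        q = 1e3
        t1, t2 = fx.small_q_limits(props, q)
        assert t1 == pytest.approx(0.9515, rel=1e-3)
        assert t2 == pytest.approx(props.eta / (props.B * q**4), rel=1e-9)

    def test_small_q_limit_reached(self, chromosome_7um):
        """Both branches converge to the q -> 0 forms (sub-1% at q = 1e2)."""
        q = 1e2
        spec = fx.relaxation_times(chromosome_7um, q)
        t1_lim, t2_lim = fx.small_q_limits(chromosome_7um, q)
        assert spec.tau1 == pytest.approx(t1_lim, rel=0.01)
        assert spec.tau2 == pytest.approx(t2_lim, rel=0.01)

    def test_large_q_plateau_thresholds(self, chromosome):
        """Plateaus hold beyond the quoted wavenumber thresholds.

        The q > 0.06 um^-1 (tau1, bending plateau) and q > 0.007 um^-1
        (tau2, shear plateau) thresholds describe the stiff end of the
        coefficient ranges the plateaus were surveyed over (internal
        viscosities up to 1e4 and 1e6 kg/(m.s) respectively); the entry
        wavenumber moves up as the coefficients shrink.
        """
        stiff1 = chromosome.with_internal_friction(1e4, 1e4)
        t1_lim, _ = fx.large_q_limits(stiff1)
        for q in np.geomspace(0.061e6, 1e8, 40):
            assert abs(
                fx.relaxation_times(stiff1, q).tau1 / t1_lim - 1
            ) < 0.05
        stiff2 = chromosome.with_internal_friction(1e6, 1e6)
        _, t2_lim = fx.large_q_limits(stiff2)
        for q in np.geomspace(0.0071e6, 1e8, 40):
            assert abs(
                fx.relaxation_times(stiff2, q).tau2 / t2_lim - 1
            ) < 0.05

    def test_dominant_wavenumbers_in_plateau_regime(self, chromosome_7um):
        """At the shortest arm's dominant wavenumber (0.22 um^-1) both
        times sit within 5% of their large-q plateaus, which is what
        licenses reading coefficients off the limit relations."""
        t1_lim, t2_lim = fx.large_q_limits(chromosome_7um)
        spec = fx.relaxation_times(chromosome_7um, 0.22e6)
        assert spec.tau1 == pytest.approx(t1_lim, rel=0.05)
        assert spec.tau2 == pytest.approx(t2_lim, rel=0.05)

    def test_divergent_branch_matches_drag(self, chromosome_7um):
        """tau2 * B q^4 / eta -> 1 as q -> 0."""
        for q in (30.0, 10.0, 3.0):
            spec = fx.relaxation_times(chromosome_7um, q)
            ratio = spec.tau2 * chromosome_7um.B * q**4 / chromosome_7um.eta
            assert ratio == pytest.approx(1.0, rel=0.01)

    def test_stiff_shear_recovers_bending_only_model(self, chromosome_7um):
        """G -> infinity collapses the slow physical branch onto the
        bending-only relaxation time."""
        from dataclasses import replace

        stiff = replace(chromosome_7um, G=chromosome_7um.G * 1e6)
        for q in np.geomspace(1e4, 1e7, 15):
            spec = fx.relaxation_times(stiff, q)
            tau_eb = fx.relaxation_time_eb(stiff, q)
            closest = min(
                abs(spec.tau1 / tau_eb - 1), abs(spec.tau2 / tau_eb - 1)
            )
            assert closest < 1e-3


class TestACFModel:
    def test_drag_only_single_term(self, chromosome):
        q = 1e5
        m = fx.acf_model(chromosome, q)
        assert m.R2 == 0.0
        assert m.tau1 == pytest.approx(
            fx.relaxation_time_drag(chromosome, q), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_variance_matches_quadrature(self, seed):
        """R1 + R2 equals the frequency integral of the power spectrum.

        The two Lorentzian poles can sit 15+ decades apart, which
        defeats adaptive double-precision quadrature; mpmath quadrature
        with the poles as split points is the reliable oracle.
        """
        rng = np.random.default_rng(7 + seed)
        props = random_props(rng)
        q = float(np.exp(rng.uniform(np.log(1e3), np.log(1e7))))
        m = fx.acf_model(props, q)
        C, K = fx.overdamped_matrices(props, q)
        lam_slow, lam_fast = fx.decay_rates(props, q)
        detC = np.linalg.det(C)
        c11, k11 = C[0, 0], K[0, 0]

        def S_u(w):
            return (k11**2 + w**2 * c11**2) / (
                detC**2 * (w**2 + lam_slow**2) * (w**2 + lam_fast**2)
            )

        with mp.workdps(30):
            val = mp.quad(S_u, [0, lam_slow, lam_fast, mp.inf])
        assert m.variance == pytest.approx(float(val) / np.pi, rel=1e-6)

    def test_matches_fft_of_spectrum(self, chromosome_7um):
        """Inverse FFT of the displacement spectrum equals the model ACF."""
        q = 2.2e5
        m = fx.acf_model(chromosome_7um, q)
        C, K = fx.overdamped_matrices(chromosome_7um, q)
        lam_slow, lam_fast = fx.decay_rates(chromosome_7um, q)
        detC = np.linalg.det(C)
        n = 2**21
        dw = lam_fast / 100.0
        w = np.fft.fftfreq(n) * n * dw
        S = (K[0, 0] ** 2 + w**2 * C[0, 0] ** 2) / (
            detC**2 * (w**2 + lam_slow**2) * (w**2 + lam_fast**2)
        )
        acf = np.fft.ifft(S).real * (n * dw) / (2 * np.pi)
        T = np.arange(n) * (2 * np.pi / (n * dw))
        keep = T < 4.0 / lam_slow
        model = m(T[keep])
        assert np.allclose(acf[keep], model, rtol=1e-4, atol=1e-4 * m.variance)

    def test_zero_lag_is_sum_of_amplitudes(self, chromosome_7um):
        m = fx.acf_model(chromosome_7um, 2.2e5)
        assert m(0.0) == pytest.approx(m.R1 + m.R2, rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    logE=st.floats(1, 10),
    logG=st.floats(1, 10),
    logr=st.floats(-9, -5),
    logq=st.floats(2, 8),
    loge=st.floats(-6, -1),
    logeb=st.floats(-2, 4),
    loges=st.floats(-2, 4),
)
def test_rate_quadratic_consistency(logE, logG, logr, logq, loge, logeb, loges):
    """Across the parameter space the two reported rates solve the
    invariant quadratic and keep their ordering."""
    props = fx.FilamentProperties(
        E=10.0**logE, G=10.0**logG, r=10.0**logr,
        eta=10.0**loge, eta_b=10.0**logeb, eta_s=10.0**loges,
    )
    q = 10.0**logq
    spec = fx.relaxation_times(props, q)
    assert 0 < spec.tau1 <= spec.tau2
    lam = general_eigen_rates(props, q)
    assert 1.0 / spec.tau1 == pytest.approx(lam[1], rel=1e-9)
    assert 1.0 / spec.tau2 == pytest.approx(lam[0], rel=1e-9)
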