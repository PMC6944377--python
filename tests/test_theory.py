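import numpy as np
import pytest
from scipy import integrate

from relsim import theory as th


GRID = [(1, 5.0, 0.06), (2, 5.833, 0.05), (4, 2.0, 0.2), (6, 8.0, 0.0)]


def _quad(f, a, b):
    val, _ = integrate.quad(f, a, b, limit=400)
    return val


class TestRegulatedDensities:
    @pytest.mark.parametrize("T,nu,p", GRID)
    def test_normalizations(self, T, nu, p):
        spec = th.TheorySpec(T=T, nu=nu, p=p)
        hi = 60.0
        assert _quad(lambda x: th.f_reg(x, spec), 0, hi) == pytest.approx(1.0, abs=1e-6)
        assert _quad(lambda x: th.g_reg(x, spec), 0, hi) == pytest.approx(1.0, abs=1e-6)
        assert _quad(lambda x: th.h(x, spec), 0, hi) == pytest.approx(1.0, abs=1e-6)
        assert _quad(lambda x: th.phi(x, spec), 0, hi) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("T,nu,p", GRID)
    def test_means(self, T, nu, p):
        spec = th.TheorySpec(T=T, nu=nu, p=p)
        mean_f = _quad(lambda x: x * th.f_reg(x, spec), 0, 80)
        assert mean_f == pytest.approx(1.0 / (1.0 - p), abs=1e-6)
        mean_phi = _quad(lambda x: x * th.phi(x, spec), 0, 60)
        assert mean_phi == pytest.approx(1.0 / (2 * T), abs=1e-6)

    def test_g_reg_at_zero_is_one_minus_p(self):
        for _, nu, p in GRID:
            spec = th.TheorySpec(T=1, nu=nu, p=p)
            assert th.g_reg(0.0, spec) == pytest.approx(1.0 - p, abs=1e-9)

    def test_g_reg_equals_scaled_survival_of_f_reg(self):
        spec = th.TheorySpec(T=1, nu=5.0, p=0.06)
        for x in (0.1, 0.5, 1.0, 2.0):
            tail = _quad(lambda y: th.f_reg(y, spec), x, 80)
            assert th.g_reg(x, spec) == pytest.approx((1 - spec.p) * tail, abs=1e-8)

    def test_h_at_zero_is_2T(self):
        for T, nu, p in GRID:
            spec = th.TheorySpec(T=T, nu=nu, p=p)
            assert th.h(0.0, spec) == pytest.approx(2 * T, abs=1e-9)

    def test_p_one_is_domain_error(self):
        spec = th.TheorySpec(T=1, nu=2.0, p=1.0)
        with pytest.raises(ValueError):
            th.f_reg(0.5, spec)

    def test_series_truncation_stable(self):
        xs = np.linspace(0, 10, 200)
        for k in (50, 100):
            spec = th.TheorySpec(T=2, nu=5.0, p=0.06, k_max=k)
            if k == 50:
                f50, g50 = th.f_reg(xs, spec), th.g_reg(xs, spec)
            else:
                assert np.max(np.abs(th.f_reg(xs, spec) - f50)) < 1e-10
                assert np.max(np.abs(th.g_reg(xs, spec) - g50)) < 1e-10


class TestPoissonReduction:
    def test_f_reg_nu_one_is_exponential(self):
        spec = th.TheorySpec(T=1, nu=1.0, p=0.2)
        xs = np.linspace(0.0, 6, 300)
        expect = (1 - spec.p) * np.exp(-(1 - spec.p) * xs)
        assert np.max(np.abs(th.f_reg(xs, spec) - expect)) < 1e-8

    def test_g_reg_nu_one_is_exponential_survival(self):
        spec = th.TheorySpec(T=1, nu=1.0, p=0.2)
        xs = np.linspace(0.0, 6, 300)
        expect = (1 - spec.p) * np.exp(-(1 - spec.p) * xs)
        assert np.max(np.abs(th.g_reg(xs, spec) - expect)) < 1e-8

    @pytest.mark.parametrize("T", [1, 3, 6])
    def test_h_and_phi_nu_one_reduce_to_poisson(self, T):
        spec = th.TheorySpec(T=T, nu=1.0, p=0.15)
        xs = np.linspace(0.0, 3.0 / T, 200)
        assert np.max(np.abs(th.h(xs, spec) - 2 * T * np.exp(-2 * T * xs))) < 1e-8
        assert np.max(np.abs(th.phi(xs, spec) - th.phi_poisson(xs, T))) < 1e-8

    def test_phi_matches_negative_h_derivative(self):
        spec = th.TheorySpec(T=2, nu=5.0, p=0.06)
        eps = 1e-6
        for x in (0.05, 0.2, 0.5, 1.0):
            fd = -(th.h(x + eps, spec) - th.h(x - eps, spec)) / (2 * eps) / (2 * spec.T)
            assert th.phi(x, spec) == pytest.approx(fd, abs=1e-6)


class TestFiniteChromosome:
    def test_total_mass_is_one(self):
        spec = th.TheorySpec(T=2, nu=5.0, p=0.06, L=2.8)
        cont = _quad(lambda x: th.phi_finite(x, spec), 0, spec.L)
        assert cont + th.phi_finite_atom(spec) == pytest.approx(1.0, abs=1e-6)

    def test_poisson_closed_form_total_mass_exact(self):
        T, L = 2, 2.8
        cont = _quad(lambda x: th.phi_finite_poisson(x, T, L), 0, L)
        assert cont + th.phi_finite_poisson_atom(T, L) == pytest.approx(1.0, abs=1e-9)

    def test_nu_one_matches_poisson_closed_form(self):
        T, L = 3, 2.0
        spec = th.TheorySpec(T=T, nu=1.0, p=0.0, L=L)
        xs = np.linspace(0, L, 100)
        assert np.max(np.abs(th.phi_finite(xs, spec) - th.phi_finite_poisson(xs, T, L))) < 1e-7
        assert th.phi_finite_atom(spec) == pytest.approx(
            th.phi_finite_poisson_atom(T, L), abs=1e-9
        )

    def test_atom_nu_one_closed_form(self):
        T, L = 2, 1.5
        assert th.phi_finite_poisson_atom(T, L) == pytest.approx(
            np.exp(-2 * T * L) / (2 * T * L + 1)
        )

    def test_long_chromosome_converges_to_infinite_form(self):
        # L = 50 Morgans, T = 6, nu = 1: the finite correction is small for
        # short segments; the exact ratio is (2 + 2T(L-x))/(2TL + 1), i.e. a
        # deviation of about 2Tx/(2TL+1) -- under 1% for x <= 0.5 Morgans
        spec = th.TheorySpec(T=6, nu=1.0, p=0.0, L=50.0)
        xs = np.linspace(0.001, 0.5, 50)
        rel = np.abs(th.phi_finite(xs, spec) / th.phi_poisson(xs, 6) - 1.0)
        assert np.max(rel) < 0.01
        xs = np.linspace(0.5, 1.0, 50)
        rel = np.abs(th.phi_finite(xs, spec) / th.phi_poisson(xs, 6) - 1.0)
        assert np.max(rel) < 0.02

    def test_domain_checks(self):
        spec = th.TheorySpec(T=2, nu=5.0, p=0.06, L=1.0)
        with pytest.raises(ValueError):
            th.phi_finite(1.5, spec)
        with pytest.raises(ValueError):
            th.phi_finite(0.5, th.TheorySpec(T=2, nu=5.0, p=0.06))


class TestInterferenceEffect:
    def test_short_segments_suppressed_relative_to_poisson(self):
        """phi(0) < 2T for nu > 1 and small p: interference removes short
        inter-crossover intervals."""
        for T in (1, 2, 4):
            for nu in (3.0, 5.0, 8.0):
                spec = th.TheorySpec(T=T, nu=nu, p=0.05)
                assert th.phi(0.0, spec) / (2 * T) < 1.0


class TestSSPoisson:
    def test_constant_rate_closed_form(self):
        c = 1e-8  # Morgans per bp
        n = 500
        step = 1e4
        L = n * step
        spec = th.SSPoissonSpec(lam_f=np.full(n, c), lam_m=np.full(n, c), step_bp=step, T=1)
        xs = (np.arange(n) + 0.5) * step
        dens = th.ss_poisson_interdensity(xs, spec, n_f=1)
        lam = 2 * c  # n_f + n_m = 2 transmissions
        expect = lam * (L - xs) * np.exp(-lam * xs) / L + np.exp(-lam * xs) / L
        assert np.max(np.abs(dens / expect - 1.0)) < 0.01

    def test_normalization_discretized(self):
        rng = np.random.default_rng(3)
        n, step = 400, 1e4
        lam_f = rng.uniform(0.5e-8, 3e-8, n)
        lam_m = rng.uniform(0.2e-8, 2e-8, n)
        spec = th.SSPoissonSpec(lam_f=lam_f, lam_m=lam_m, step_bp=step, T=2)
        xs = (np.arange(n) + 0.5) * step
        total = np.sum(th.ss_poisson_mixture(xs, spec)) * step
        assert total == pytest.approx(1.0, abs=1e-2)

    def test_equal_sex_rates_collapse_mixture(self):
        n, step = 300, 1e4
        lam = np.linspace(1e-8, 2e-8, n)
        spec = th.SSPoissonSpec(lam_f=lam, lam_m=lam, step_bp=step, T=2)
        xs = (np.arange(0, n, 7) + 0.5) * step
        base = th.ss_poisson_interdensity(xs, spec, n_f=0)
        for n_f in (1, 2, 4):
            np.testing.assert_allclose(
                th.ss_poisson_interdensity(xs, spec, n_f=n_f), base, rtol=1e-12
            )
        np.testing.assert_allclose(th.ss_poisson_mixture(xs, spec), base, rtol=1e-12)

    def test_meiosis_count_weights(self):
        for T in (1, 2, 4):
            w = th.meiosis_count_weights(T)
            assert w.size == 2 * T + 1
            assert w.sum() == pytest.approx(1.0)
        # T=1: the two meioses come from the single shared ancestor, female
        # with probability 1/2 -> n_f in {0, 2}
        np.testing.assert_allclose(th.meiosis_count_weights(1), [0.5, 0.0, 0.5])

    def test_all_zero_rate_is_domain_error(self):
        spec = th.SSPoissonSpec(lam_f=np.zeros(10), lam_m=np.zeros(10), step_bp=1e4, T=1)
        with pytest.raises(ValueError):
            th.ss_poisson_interdensity(1e4, spec, n_f=1)
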