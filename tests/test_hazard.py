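"""Analytic two-stage kernel and field-defect convolution hazard."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from msceapc import (
    BiologicalParams,
    DegenerateRootsError,
    ParameterDomainError,
    TrendParams,
    convolved_hazard,
    fd_density,
    hazard_curve,
    two_hit_hazard,
    two_stage_hazard,
    two_stage_roots,
    two_stage_survival,
)
from msceapc.trends import fd_rate, promotion_g

from conftest import random_valid_rates


class TestTwoStageRoots:
    def test_double_root_when_mu2_zero_and_alpha_equals_beta(self):
        r = two_stage_roots(17.4, 17.4, 0.0)
        assert r.p == pytest.approx(0.0, abs=1e-12)
        assert r.q == pytest.approx(0.0, abs=1e-12)

    def test_mu2_zero_gives_q_zero_and_p_beta_minus_alpha(self):
        r = two_stage_roots(17.4, 10.0, 0.0)
        assert r.p == pytest.approx(-7.4, rel=1e-12)
        assert r.q == 0.0

    def test_against_polynomial_root_oracle(self):
        # white-male posterior medians: alpha=17.4, g=0.1836, mu2=1.3273e-7
        alpha, mu2, g = 17.4, 1.3273e-7, 0.1836
        beta = alpha - g - mu2
        r = two_stage_roots(alpha, beta, mu2)
        # roots of x^2 - (p+q) x + pq = x^2 + (alpha-beta-mu2) x - alpha*mu2
        oracle = np.sort(np.roots([1.0, alpha - beta - mu2, -alpha * mu2]))
        assert r.p == pytest.approx(oracle[0], rel=1e-9)
        assert r.q == pytest.approx(oracle[1], rel=1e-6)
        assert r.p * r.q == pytest.approx(-alpha * mu2, rel=1e-10)

    def test_identities_over_random_draws(self):
        rng = np.random.default_rng(42)
        alpha, beta, mu2 = random_valid_rates(rng, 1000)
        for a, b, m2 in zip(alpha, beta, mu2):
            r = two_stage_roots(a, b, m2)
            # sum identity at the scale of the roots themselves (the sum
            # nearly cancels when mu2 dominates the net proliferation)
            scale = abs(r.p) + abs(r.q)
            assert abs((r.p + r.q) - (-a + b + m2)) <= 1e-10 * scale
            assert r.p * r.q == pytest.approx(-a * m2, rel=1e-10)
            assert r.p <= 0.0 <= r.q

    def test_negative_rates_rejected(self):
        with pytest.raises(ParameterDomainError):
            two_stage_roots(-1.0, 1.0, 1e-7)
        with pytest.raises(ParameterDomainError):
            two_stage_roots(17.4, -0.1, 1e-7)


class TestTwoStageHazard:
    bp = BiologicalParams(nu0=9.54e-5, mu1=39.4632, mu2=0.0345e-7, g0=0.0249)

    def test_zero_at_origin(self):
        assert two_stage_hazard(0.0, self.bp, g=0.0249) == 0.0

    def test_nonnegative_and_increasing_to_plateau(self):
        u = np.linspace(0.0, 200.0, 500)
        h = two_stage_hazard(u, self.bp, g=0.0249)
        assert np.all(h >= 0.0)
        assert np.all(np.diff(h) >= -1e-15)

    def test_against_backward_kolmogorov_ode(self):
        """h2(u) = mu1 (1 - phi(u)) where phi solves the clone-level
        backward equation phi' = -(a+b+m) phi + b + a phi^2, phi(0)=1."""
        g = 0.0249
        a, m2, mu1 = self.bp.alpha, self.bp.mu2, self.bp.mu1
        b = a - g - m2
        sol = solve_ivp(
            lambda t, y: [-(a + b + m2) * y[0] + b + a * y[0] ** 2],
            (0.0, 60.0), [1.0], method="Radau", rtol=1e-12, atol=1e-16,
        )
        h_ode = mu1 * (1.0 - sol.y[0, -1])
        h = two_stage_hazard(60.0, self.bp, g=g)
        assert h == pytest.approx(h_ode, rel=1e-6)

    def test_plateau_is_minus_mu1_p_over_alpha(self):
        g = 0.0249
        r = two_stage_roots(self.bp.alpha, self.bp.beta(g), self.bp.mu2)
        u_large = 60.0 / r.q  # q*u > 50
        plateau = -self.bp.mu1 * r.p / self.bp.alpha
        h = two_stage_hazard(u_large, self.bp, g=g)
        assert abs(h - plateau) / plateau < 1e-4

    def test_overflow_safe_at_old_ages(self):
        bp = BiologicalParams(nu0=1e-4, mu1=5.0, mu2=1e-6, g0=0.3)
        h = two_stage_hazard(5000.0, bp, g=0.3)
        assert np.isfinite(h) and h > 0.0

    def test_degenerate_roots_raise(self):
        bp = BiologicalParams(nu0=1e-4, mu1=1.0, mu2=0.0, g0=0.0)
        with pytest.raises(DegenerateRootsError):
            two_stage_hazard(10.0, bp, g=0.0)


class TestTwoStageSurvival:
    bp = BiologicalParams(nu0=9.54e-5, mu1=39.4632, mu2=0.0345e-7, g0=0.0249)

    def test_one_at_origin(self):
        assert two_stage_survival(0.0, self.bp, g=0.0249) == 1.0

    def test_one_when_mu1_zero(self):
        bp = self.bp.replace(mu1=0.0)
        u = np.array([0.0, 10.0, 50.0, 100.0])
        assert np.allclose(two_stage_survival(u, bp, g=0.0249), 1.0)

    def test_matches_exp_minus_integrated_hazard(self):
        g = 0.0249
        s70 = two_stage_survival(70.0, self.bp, g=g)
        integral, _ = quad(
            lambda u: two_stage_hazard(u, self.bp, g=g), 0.0, 70.0,
            epsabs=1e-14, epsrel=1e-11, limit=300,
        )
        assert s70 == pytest.approx(np.exp(-integral), rel=1e-8)

    def test_quadrature_consistency_over_random_draws(self):
        rng = np.random.default_rng(7)
        alpha, beta, mu2 = random_valid_rates(rng, 20)
        for a, b, m2 in zip(alpha, beta, mu2):
            g = a - b - m2
            bp = BiologicalParams(nu0=1e-4, mu1=rng.uniform(0.1, 20.0),
                                  mu2=m2, g0=max(g, 0.0), alpha=a)
            u_end = rng.uniform(10.0, 80.0)
            s = two_stage_survival(u_end, bp, g=g)
            integral, _ = quad(lambda u: two_stage_hazard(u, bp, g=g),
                               0.0, u_end, epsabs=1e-14, epsrel=1e-10,
                               limit=300)
            assert s == pytest.approx(np.exp(-integral), rel=1e-6)


class TestFdDensity:
    def test_constant_rate_is_exponential(self):
        nu0 = 3.7e-4
        for s in (0.0, 1.0, 10.0, 80.0):
            assert fd_density(s, lambda x: nu0) == pytest.approx(
                nu0 * np.exp(-nu0 * s), rel=1e-9
            )

    def test_zero_rate_gives_zero_density(self):
        assert fd_density(12.0, lambda s: 0.0) == 0.0

    def test_piecewise_onset_is_shifted_exponential(self):
        nu0, s0 = 2e-3, 5.0
        nu = lambda s: nu0 if s >= s0 else 0.0
        s = 20.0
        assert fd_density(s, nu) == pytest.approx(
            nu0 * np.exp(-nu0 * (s - s0)), rel=1e-7
        )

    def test_improper_mass_never_renormalized(self):
        # rate vanishes after age 10: total mass stays below 1
        nu = lambda s: 0.05 if s < 10.0 else 0.0
        mass, _ = quad(lambda s: fd_density(s, nu), 0.0, 200.0,
                       points=[10.0], limit=200)
        assert mass == pytest.approx(1.0 - np.exp(-0.5), rel=1e-6)


class TestConvolvedHazard:
    def test_zero_before_clinical_lag(self, flat_params):
        bp, _ = flat_params
        nu = lambda s: bp.nu0
        for a in (0.0, 2.5, 5.0):
            assert convolved_hazard(a, nu, bp) == 0.0

    def test_point_mass_onset_recovers_two_stage_hazard(self, flat_params):
        """A near-certain immediate FD reduces the convolution to the bare
        TSCE kernel shifted by the lag."""
        bp, _ = flat_params
        bp = bp.replace(nu0=1e4)
        a = 40.0
        # split points guide the quadrature into the sharp onset spike
        h = convolved_hazard(a, lambda s: bp.nu0, bp,
                             breakpoints=(1e-4, 1e-3, 1e-2))
        assert h == pytest.approx(
            two_stage_hazard(a - bp.lag, bp, g=bp.g0), rel=1e-3
        )

    def test_rate_product_invariance_at_young_ages(self, flat_params):
        """At first order the hazard depends on nu*mu1 only: scaling nu by
        10 and mu1 by 1/10 leaves young-age hazard nearly unchanged."""
        bp, _ = flat_params
        bp_small = bp.replace(nu0=1e-5, mu1=0.05)
        bp_swap = bp.replace(nu0=1e-4, mu1=0.005)
        a = 30.0
        h1 = convolved_hazard(a, lambda s: bp_small.nu0, bp_small)
        h2 = convolved_hazard(a, lambda s: bp_swap.nu0, bp_swap)
        assert h1 == pytest.approx(h2, rel=1e-2)

    def test_grid_evaluator_matches_quadrature(self, black_males):
        bp, tp = black_males
        B = 1950.0
        nu = lambda s: fd_rate(s, B, bp.nu0, tp)
        g_fn = lambda b: promotion_g(b, bp.g0, tp)
        for a in (40.5, 60.5):
            ref = convolved_hazard(a, nu, bp, g_fn, B,
                                   breakpoints=(tp.s0, tp.y0 - B))
            crv = hazard_curve([a], bp, tp, B, step=0.25)
            assert crv.hazard[0] == pytest.approx(ref, rel=5e-3)

    def test_curve_invariants(self, black_males):
        bp, tp = black_males
        crv = hazard_curve(np.linspace(0.0, 85.0, 171), bp, tp, B=1950.0)
        assert np.all(crv.hazard >= 0.0)
        assert crv.survival[0] == 1.0
        assert np.all(np.diff(crv.survival) <= 1e-12)


class TestTwoHitModel:
    def test_zero_mutation_rate_gives_zero_hazard(self, flat_params):
        bp, _ = flat_params
        assert two_hit_hazard(65.0, 0.0, 1e6, bp) == 0.0

    def test_structural_equivalence_with_fd_model(self, flat_params):
        bp, _ = flat_params
        a = 60.0
        h_fd = convolved_hazard(a, lambda s: bp.nu0, bp)
        h_2h = two_hit_hazard(a, mu0=bp.nu0 / 1e6, n_stem=1e6, params=bp)
        assert h_2h == pytest.approx(h_fd, rel=1e-10)

    def test_published_range_first_hit_rate_gives_finite_hazard(self):
        """mu0 in the estimated 4.5e-11..8.7e-11 per-cell range with ~1e6
        stem cells yields a finite positive mid-life hazard."""
        bp = BiologicalParams(nu0=0.0, mu1=10.0, mu2=1e-7, g0=0.15)
        h = two_hit_hazard(65.0, mu0=6e-11, n_stem=1e6, params=bp)
        assert np.isfinite(h) and h > 0.0
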