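import math
import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from telokin import (
    InputSpec,
    LengthDistribution,
    LengthGrid,
    analytic_gaussian_solution,
    check_balance,
    exit_distribution,
    exit_mean_closed_form,
    exit_mean_length,
    generation_step,
    input_density,
    iterate_generations,
    solve_bound_density,
)
from telokin.open_model import drug_locking_rate

from conftest import rel_l2


def _solve(p_in, T0, R0, params, **kw):
    return solve_bound_density(p_in, T0, R0, params, p_in.grid, **kw)


class TestSolveBoundDensity:
    def test_no_telomerase_means_no_bound_state(self, gaussian_input, params):
        st_ = _solve(gaussian_input, 0.0, 0.0, params)
        assert np.all(st_.B == 0.0)
        # with T0 = 0 and no drug, the steady exit flux k_c U equals the
        # influx k_e p pointwise (U = k_e p / k_c)
        flux = exit_distribution(st_, params, normalize=True)
        np.testing.assert_allclose(flux.pdf, gaussian_input.pdf,
                                   rtol=1e-8, atol=1e-12)

    def test_control_cells_U_independent_of_g4_rates(self, gaussian_input, params):
        """Without drug, G4 folding/unfolding only shuffles U <-> G, so the
        open-state density is unchanged when k_f and k_u are rescaled."""
        base = _solve(gaussian_input, 25, 0.0, params)
        for factor in (0.5, 2.0):
            mod = params.replace(k_f=params.k_f * factor,
                                 k_u=params.k_u * factor)
            other = _solve(gaussian_input, 25, 0.0, mod)
            np.testing.assert_allclose(other.U, base.U, rtol=1e-10)

    @pytest.mark.parametrize("R0_nM", [0.0, 100.0])
    def test_numeric_matches_analytic_for_step_kernel(self, params, R0_nM):
        grid = LengthGrid(-2000, 20000, 5.0)
        spec = InputSpec(kind="gaussian", L=params.L0, sigma=params.sigma0)
        p_in = LengthDistribution(grid, input_density(grid.x, spec))
        R0 = R0_nM * 1e-9 * params.N_A * params.V_n
        num = _solve(p_in, 25, R0, params, step_kernel=True)
        ana, _ = analytic_gaussian_solution(params.L0, params.sigma0, 25, R0,
                                            params, grid)
        assert rel_l2(num.B, ana.B, grid.x) < 1e-2
        assert rel_l2(num.U, ana.U, grid.x) < 1e-2

    def test_balance_residual_small_and_improves_with_dx(self, params):
        spec = InputSpec(kind="gaussian", L=params.L0 - params.mu,
                         sigma=params.sigma0)
        residuals = []
        for dx in (40.0, 20.0, 10.0):
            grid = LengthGrid(-2000, 30000, dx)
            p_in = LengthDistribution(grid, input_density(grid.x, spec),
                                      normalize=True)
            st_ = _solve(p_in, 25, 0.0, params)
            residuals.append(check_balance(st_, params))
        assert residuals[-1] < 1e-3
        # halving dx should at least halve the residual (observed: ~4x)
        assert residuals[1] <= 0.55 * residuals[0]
        assert residuals[2] <= 0.55 * residuals[1]

    def test_zero_densities_residual_is_one(self, open_grid, params):
        from telokin import StateDensities
        z = np.zeros(open_grid.n)
        st_ = StateDensities(grid=open_grid, U=z, B=z, G=z, C=z)
        assert check_balance(st_, params) == pytest.approx(1.0)


class TestAnalyticConstants:
    def test_drug_free_limits(self, params):
        _, c = analytic_gaussian_solution(3440, 800, 25, 0.0, params)
        assert c.c1 == pytest.approx(params.k_on * 25, rel=1e-14)
        assert c.a2 == 0.0

    def test_g4_to_open_ratio_without_drug(self, params):
        st_, _ = analytic_gaussian_solution(3440, 800, 25, 0.0, params)
        np.testing.assert_allclose(st_.G / st_.U, params.k_f / params.k_u,
                                   rtol=1e-12)

    def test_locked_to_open_ratio_saturates_at_kf_over_kr(self, params):
        # C/U -> k_f/k_r as R0 -> infinity; convergence rate is set by
        # k_u (k_d + k_r)/(k_r k_s R0), so 1e-3 agreement needs R0 ~ 1e12
        st_, _ = analytic_gaussian_solution(3440, 800, 25, 1e12, params)
        ratio = st_.C[100] / st_.U[100]
        assert ratio == pytest.approx(params.k_f / params.k_r, rel=1e-3)

    def test_requires_positive_telomerase(self, params):
        with pytest.raises(ValueError):
            analytic_gaussian_solution(3440, 800, 0.0, 0.0, params)


class TestExitDistribution:
    def test_integrates_to_one_within_residual(self, gaussian_input, params):
        st_ = _solve(gaussian_input, 25, 0.0, params)
        p_exit = exit_distribution(st_, params)  # divided by k_e
        assert p_exit.total_mass() == pytest.approx(1.0, abs=1e-3)

    def test_invariant_under_influx_rate(self, gaussian_input, params):
        a = exit_distribution(_solve(gaussian_input, 25, 0.0, params),
                              params, normalize=True)
        doubled = params.replace(k_e=2 * params.k_e)
        b = exit_distribution(_solve(gaussian_input, 25, 0.0, doubled),
                              doubled, normalize=True)
        np.testing.assert_allclose(a.pdf, b.pdf, rtol=1e-12)

    def test_drug_free_exit_proportional_to_capping_flux(self, gaussian_input,
                                                         params):
        from telokin import capping_rate
        st_ = _solve(gaussian_input, 25, 0.0, params)
        p_exit = exit_distribution(st_, params, normalize=True)
        flux = capping_rate(st_.x, params) * st_.U
        np.testing.assert_allclose(p_exit.pdf,
                                   flux / st_.grid.integrate(flux), rtol=1e-12)

    def test_mean_exit_length_increases_with_telomerase(self, gaussian_input,
                                                        params):
        means = [exit_mean_length(_solve(gaussian_input, T0, 0.0, params),
                                  params) for T0 in (10, 20, 30)]
        assert means[0] < means[1] < means[2]

    def test_bound_density_skewness_increases_with_telomerase(
            self, gaussian_input, params):
        def b_skew(T0):
            st_ = _solve(gaussian_input, T0, 0.0, params)
            d = LengthDistribution(st_.grid, st_.B, normalize=True)
            return d.skewness()
        skews = [b_skew(T0) for T0 in (10, 25, 40)]
        assert skews[0] < skews[1] < skews[2]


class TestExitMeanClosedForm:
    def test_telomerase_term_and_linearity(self, params):
        _, (_, _, t3) = exit_mean_closed_form(3395, 800, 25, params)
        assert t3 == pytest.approx(37.15, abs=0.01)  # "~37 nt" at T0=25
        _, (_, _, t3b) = exit_mean_closed_form(3395, 800, 50, params)
        assert t3b == pytest.approx(2 * t3, rel=1e-12)

    def test_short_telomere_dwell_term_regression(self, params):
        # (rho/2 k_off) erfc((L-alpha)/(sigma sqrt2)) at L = L0 - mu:
        # pinned from this implementation's own evaluation
        _, (_, t2, _) = exit_mean_closed_form(3395, 800, 25, params)
        assert t2 == pytest.approx(6.1252, abs=1e-3)

    def test_agrees_with_numeric_step_kernel_solve(self, params):
        grid = LengthGrid(-2000, 20000, 5.0)
        spec = InputSpec(kind="gaussian", L=params.L0 - params.mu,
                         sigma=params.sigma0)
        p_in = LengthDistribution(grid, input_density(grid.x, spec))
        st_ = _solve(p_in, 25, 0.0, params, step_kernel=True)
        numeric = exit_mean_length(st_, params, step_kernel=True)
        closed, _ = exit_mean_closed_form(params.L0 - params.mu,
                                          params.sigma0, 25, params)
        assert numeric == pytest.approx(closed, rel=1e-2)

    def test_domain_errors(self, params):
        with pytest.raises(ValueError):
            exit_mean_closed_form(3395, 800, 0.0, params)
        with pytest.raises(ValueError):
            exit_mean_closed_form(1000, 800, 25, params)


class TestGammaShapeShift:
    def test_output_shape_exceeds_input_by_one(self, params):
        """With a constant capping rate delta (lengths above the threshold)
        and input gamma scale matched to nu/Lambda = 1/b2, the bound density
        is gamma with shape increased by one."""
        T0 = 25.0
        c1 = params.k_on * T0
        b2 = (params.k_off / params.rho) * (
            1 - params.k_on * T0 / (params.delta + c1))
        theta = 1.0 / b2
        gshape = 18.49
        grid = LengthGrid(params.alpha, params.alpha + 25000.0, 1.0)
        xhat = grid.x - params.alpha
        pdf = stats.gamma(gshape - 1, scale=theta).pdf(xhat)
        p_in = LengthDistribution(grid, pdf)
        st_ = solve_bound_density(p_in, T0, 0.0, params, grid,
                                  step_kernel=True)
        B = LengthDistribution(grid, st_.B, normalize=True)
        mean = B.mean() - params.alpha
        fitted_shape = mean ** 2 / B.var()
        assert fitted_shape == pytest.approx(gshape, rel=1e-2)
        assert mean == pytest.approx(gshape * theta, rel=1e-2)


class TestGenerations:
    def test_zero_generations_returns_initial(self, gaussian_input, params):
        trace = iterate_generations(gaussian_input, 0, 25, 0.0, params)
        assert trace.n_generations == 0
        assert trace.means[0] == pytest.approx(params.L0, abs=0.1)

    def test_each_generation_is_normalised(self, gaussian_input, params):
        trace = iterate_generations(gaussian_input, 3, 25, 0.0, params)
        for d in trace.distributions:
            assert d.total_mass() == pytest.approx(1.0, abs=1e-4)

    def test_no_telomerase_loses_exactly_mu_per_generation(self, gaussian_input,
                                                           params):
        """With T0 = 0 the steady-state exit flux reproduces the entering
        density exactly, so the only change per generation is the mu-shift."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1, _ = generation_step(gaussian_input, 0.0, 0.0, params)
        assert gaussian_input.mean() - p1.mean() == pytest.approx(params.mu,
                                                                  abs=0.01)

    def test_tuned_telomerase_fixes_the_mean(self, gaussian_input, params):
        """A T0 exists at which elongation balances the mu-loss; after tuning
        on one step, subsequent generations move the mean < 1 bp each."""
        def drift(T0):
            p1, _ = generation_step(gaussian_input, T0, 0.0, params)
            return p1.mean() - gaussian_input.mean()

        T0_star = brentq(drift, 20.0, 35.0, xtol=1e-3)
        trace = iterate_generations(gaussian_input, 3, T0_star, 0.0, params,
                                    shift_initial=True)
        steps = np.abs(np.diff(trace.means[1:]))
        assert np.all(steps < 1.0)

    def test_drug_lowers_late_generation_mean(self, params):
        """Raising R0 monotonically lowers the generation mean (coarse grid,
        few generations for speed)."""
        grid = LengthGrid(-2000, 12000, 20.0)
        spec = InputSpec(kind="gaussian", L=params.L0, sigma=params.sigma0)
        p0 = LengthDistribution(grid, input_density(grid.x, spec))
        per_nM = 1e-9 * params.N_A * params.V_n
        means = []
        for R0_nM in (0.0, 100.0, 1000.0):
            trace = iterate_generations(p0, 8, 25, R0_nM * per_nM, params)
            means.append(trace.means[-1])
        assert means[0] > means[1] > means[2]
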