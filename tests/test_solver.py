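"""IMEX solver: stencil identities, fixed points, consistency, steady states."""

import numpy as np
import pytest

from turingbayes.growth import GrowthFunction, constant_growth, exponential_growth
from turingbayes.kinetics import ModelParameters, homogeneous_steady_state
from turingbayes.solver import (
    FieldPair,
    Grid,
    SolverConfig,
    SteadyStateError,
    discrete_laplacian,
    imex_step,
    initial_condition_1d,
    initial_condition_2d,
    laplacian_matrix,
    solve_forward,
    solve_to_steady_state,
)


class TestDiscreteLaplacian:
    def test_constant_field_maps_to_zero(self):
        grid = Grid(1, 1 / 64)
        np.testing.assert_allclose(discrete_laplacian(np.full(grid.n, 3.7), grid), 0.0, atol=1e-9)
        grid2 = Grid(2, 1 / 16)
        np.testing.assert_allclose(
            discrete_laplacian(np.full(grid2.shape, -1.2), grid2), 0.0, atol=1e-9
        )

    @pytest.mark.parametrize("k", [1, 2, 5, 11])
    def test_cosine_eigenvectors(self, k):
        grid = Grid(1, 1 / 64)
        x = grid.coords
        f = np.cos(k * np.pi * x)
        lam = -(2.0 / grid.h**2) * (1.0 - np.cos(k * np.pi * grid.h))
        np.testing.assert_allclose(discrete_laplacian(f, grid), lam * f, atol=1e-12 / grid.h**2 * 1e-2, rtol=1e-10)

    def test_2d_separability(self):
        grid = Grid(2, 1 / 20)
        g1 = Grid(1, 1 / 20)
        x = grid.coords
        fx = np.sin(3 * x) + x**2
        gy = np.cos(2 * x)
        F = fx[:, None] + gy[None, :]
        expected = discrete_laplacian(fx, g1)[:, None] + discrete_laplacian(gy, g1)[None, :]
        np.testing.assert_allclose(discrete_laplacian(F, grid), expected, rtol=1e-12, atol=1e-9)

    def test_weighted_matrix_symmetric_negative_semidefinite(self):
        for grid in (Grid(1, 1 / 32), Grid(2, 1 / 8)):
            L = laplacian_matrix(grid, weighted=True).toarray()
            np.testing.assert_allclose(L, L.T, atol=1e-12)
            eig = np.linalg.eigvalsh(L)
            assert eig.max() < 1e-8
        # raw stencil rows sum to zero (constants in the kernel)
        raw = laplacian_matrix(Grid(2, 1 / 8), weighted=False)
        np.testing.assert_allclose(np.asarray(raw.sum(axis=1)).ravel(), 0.0, atol=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            discrete_laplacian(np.zeros(7), Grid(1, 1 / 32))


class TestImexStep:
    def test_homogeneous_steady_state_is_fixed_point(self):
        params = ModelParameters(0.1, 0.9, 10.0, 1000.0, m=1)
        grid = Grid(1, 1 / 100)
        u, v = homogeneous_steady_state(params.a, params.b)
        state = FieldPair(np.full(grid.n, u), np.full(grid.n, v))
        for _ in range(1000):
            state = imex_step(state, params, 1.0, 0.0, 1e-4, grid)
        assert np.max(np.abs(state.u - u)) < 1e-8
        assert np.max(np.abs(state.v - v)) < 1e-8

    def test_pure_dilution_closed_form(self):
        # negligible reaction, spatially constant: one step divides by (1 + tau*m*rho_dot/rho)
        params = ModelParameters(0.1, 0.9, 10.0, 1e-12, m=1)
        grid = Grid(1, 1 / 16)
        tau = 1e-3
        state = FieldPair(np.full(grid.n, 2.0), np.full(grid.n, 3.0))
        out = imex_step(state, params, 1.5, 0.3, tau, grid)
        factor = 1.0 + tau * 0.3 / 1.5
        np.testing.assert_allclose(out.u, 2.0 / factor, rtol=1e-9)
        np.testing.assert_allclose(out.v, 3.0 / factor, rtol=1e-9)

    def test_pure_dilution_first_order_in_tau(self):
        # against the exact solution u(t) = u0 * rho(t)^{-m} on a growing domain
        r, T = 0.5, 1.0
        growth = exponential_growth(r)
        params = ModelParameters(0.1, 0.9, 10.0, 1e-12, m=1)
        grid = Grid(1, 1 / 8)
        exact = 2.0 * np.exp(-r * T)
        errors = []
        for tau in (1e-2, 5e-3):
            cfg = SolverConfig(h=grid.h, tau=tau, T=T)
            ic = FieldPair(np.full(grid.n, 2.0), np.full(grid.n, 2.0))
            out = solve_forward(params, growth, ic, cfg)
            errors.append(abs(out.u[0] - exact))
        ratio = errors[0] / errors[1]
        assert 1.7 < ratio < 2.3

    def test_two_half_steps_vs_one_step_consistency(self):
        params = ModelParameters(0.1, 0.9, 10.0, 100.0, m=1)
        grid = Grid(1, 1 / 32)
        x = grid.coords
        base = FieldPair(1.0 + 0.1 * np.cos(np.pi * x), 0.9 - 0.1 * np.cos(np.pi * x))
        diffs = []
        for tau in (2e-4, 1e-4):
            one = imex_step(base.copy(), params, 1.0, 0.0, 2 * tau, grid)
            half = imex_step(base.copy(), params, 1.0, 0.0, tau, grid)
            two = imex_step(half, params, 1.0, 0.0, tau, grid)
            diffs.append(np.max(np.abs(two.u - one.u)))
        # halving tau should shrink the defect by ~4 (second-order local error)
        assert 2.5 < diffs[0] / diffs[1] < 6.0


class TestSolveForward:
    def test_steady_state_preserved_over_horizon(self):
        params = ModelParameters(0.1, 0.9, 10.0, 1000.0, m=1)
        cfg = SolverConfig(h=1 / 50, tau=1e-4, T=0.05)
        grid = cfg.grid(1)
        u, v = homogeneous_steady_state(params.a, params.b)
        ic = FieldPair(np.full(grid.n, u), np.full(grid.n, v))
        out = solve_forward(params, constant_growth(), ic, cfg)
        assert np.max(np.abs(out.u - u)) < 1e-8
        assert out.t == pytest.approx(cfg.T)

    def test_diffusion_decay_of_single_mode(self):
        # negligible reaction on a stationary domain: implicit Euler damps a
        # cosine mode by 1/(1+tau*|lambda_k|) per step (d-fold faster for v)
        params = ModelParameters(0.1, 0.9, 10.0, 1e-12, m=1)
        grid = Grid(1, 1 / 32)
        k = 2
        lam = (2.0 / grid.h**2) * (1.0 - np.cos(k * np.pi * grid.h))
        tau, steps = 1e-3, 40
        cfg = SolverConfig(h=grid.h, tau=tau, T=tau * steps)
        mode = 0.01 * np.cos(k * np.pi * grid.coords)
        ic = FieldPair(1.0 + mode, 0.9 + mode)
        out = solve_forward(params, constant_growth(), ic, cfg)
        target_u = 1.0 + mode / (1.0 + tau * lam) ** steps
        target_v = 0.9 + mode / (1.0 + tau * params.d * lam) ** steps
        np.testing.assert_allclose(out.u, target_u, atol=1e-8)
        np.testing.assert_allclose(out.v, target_v, atol=1e-8)

    def test_growing_domain_forms_pattern(self):
        params = ModelParameters(0.1, 0.9, 10.0, 1000.0, m=1)
        cfg = SolverConfig(h=1 / 32, tau=1e-4, T=0.8)
        ic = initial_condition_1d(cfg.grid(1))
        out = solve_forward(params, exponential_growth(0.75), ic, cfg)
        assert np.std(out.v) > 0.05


class TestSolveToSteadyState:
    def test_exact_steady_state_stops_immediately(self):
        params = ModelParameters(0.1, 0.9, 10.0, 1000.0, m=1)
        cfg = SolverConfig(h=1 / 32, tau=1e-4, tol=1e-5)
        grid = cfg.grid(1)
        u, v = homogeneous_steady_state(params.a, params.b)
        ic = FieldPair(np.full(grid.n, u), np.full(grid.n, v))
        state, T = solve_to_steady_state(params, ic, cfg)
        assert T == pytest.approx(cfg.tau)
        assert np.max(np.abs(state.u - u)) < 1e-8

    def test_turing_unstable_parameters_reach_patterned_state(self):
        # reduced reaction scaling (resolvable pattern at a coarse grid)
        params = ModelParameters(0.126779, 0.792366, 10.0, 200.0, m=2)
        cfg = SolverConfig(h=1 / 12, tau=5e-4, tol=1e-5, max_time=100.0)
        ic = initial_condition_2d(cfg.grid(2), params.a, params.b)
        state, T = solve_to_steady_state(params, ic, cfg)
        assert np.max(state.u) - np.min(state.u) > 0.1
        assert T > 0

    def test_stable_parameters_return_to_homogeneity(self):
        # equal diffusivities: no diffusion-driven instability
        params = ModelParameters(0.1, 0.9, 1.0, 200.0, m=1)
        cfg = SolverConfig(h=1 / 32, tau=5e-4, tol=1e-6, max_time=100.0)
        ic = initial_condition_1d(cfg.grid(1))
        state, _ = solve_to_steady_state(params, ic, cfg)
        u_star, v_star = homogeneous_steady_state(params.a, params.b)
        assert np.max(np.abs(state.u - u_star)) < 1e-3
        assert np.max(np.abs(state.v - v_star)) < 1e-3

    def test_non_convergence_raises(self):
        params = ModelParameters(0.126779, 0.792366, 10.0, 200.0, m=2)
        cfg = SolverConfig(h=1 / 12, tau=5e-4, tol=1e-9, max_time=0.05)
        ic = initial_condition_2d(cfg.grid(2), params.a, params.b)
        with pytest.raises(SteadyStateError):
            solve_to_steady_state(params, ic, cfg)


class TestInitialConditions:
    def test_1d_endpoint_and_mean_values(self):
        grid = Grid(1, 1 / 200)
        ic = initial_condition_1d(grid)
        assert ic.u[0] == pytest.approx(1.0) and ic.v[0] == pytest.approx(0.9)
        assert ic.u[-1] == pytest.approx(1.0, abs=1e-12)
        # odd-k sine terms integrate to 2/(k*pi), leaving a ~5.7e-3 residue
        assert abs(np.mean(ic.u) - 1.0) < 1e-2
        assert abs(np.mean(ic.v) - 0.9) < 1e-2

    def test_2d_reference_values(self):
        grid = Grid(2, 1 / 16)
        ic = initial_condition_2d(grid, 0.126779, 0.792366)
        # at the origin every cosine equals one
        assert ic.u[0, 0] == pytest.approx(0.919145 + 0.0016 + 0.08, abs=1e-6)
        u_star, v_star = homogeneous_steady_state(0.126779, 0.792366)
        diff = ic.u - ic.v
        np.testing.assert_allclose(diff, u_star - v_star, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            initial_condition_1d(Grid(2, 1 / 8))
        with pytest.raises(ValueError):
            initial_condition_2d(Grid(1, 1 / 8), 0.1, 0.9)


def test_grid_spacing_validation():
    with pytest.raises(ValueError):
        Grid(1, 0.3)
    assert Grid(2, 1 / 12).n == 13
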