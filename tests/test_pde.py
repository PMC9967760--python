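import numpy as np
import pytest

from allelloscape import (
    ContinuousParameters,
    FieldState,
    GridSpec,
    build_cycle,
    build_from_matrix,
    holling_response,
    init_circular_patches,
    init_homogeneous,
    init_random_patchwork,
    integrate,
    laplacian,
    reaction_terms,
    step,
)
from allelloscape.pde import GeometryError

from conftest import euler_ode_oracle


def single_species_params(**kw):
    mat = np.zeros((1, 1), dtype=int)
    net = build_from_matrix(mat)
    defaults = dict(r=0.3, nu=1.0, mu=0.0, gamma=0.0, beta=0.5, delta=0.1,
                    d=0.0, D=0.0)
    defaults.update(kw)
    return ContinuousParameters.uniform(1, **defaults), net


class TestLaplacian:
    def test_constant_field_periodic_and_neumann(self):
        f = np.full((7, 9), 3.7)
        for bc in ("periodic", "neumann_zero"):
            np.testing.assert_allclose(laplacian(f, 1.0, bc), 0.0, atol=1e-14)

    def test_unit_impulse_stencil(self):
        f = np.zeros((7, 7))
        f[3, 3] = 1.0
        out = laplacian(f, 1.0, "dirichlet_zero")
        assert out[3, 3] == -4.0
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            assert out[3 + dy, 3 + dx] == 1.0
        assert np.count_nonzero(out) == 5

    @pytest.mark.parametrize("bc", ["periodic", "neumann_zero"])
    def test_diffusion_conserves_mass(self, bc):
        """Zero-flux and wrap-around stencils conserve the field sum."""
        rng = np.random.default_rng(0)
        f = rng.random((16, 12))
        out = laplacian(f, 0.7, bc)
        assert abs(out.sum()) / f.sum() <= 1e-10

    def test_unknown_boundary(self):
        with pytest.raises(ValueError, match="boundary"):
            laplacian(np.zeros((4, 4)), 1.0, "reflecting")

    def test_too_small_field(self):
        with pytest.raises(ValueError):
            laplacian(np.zeros((2, 5)), 1.0, "periodic")


class TestHollingResponse:
    def test_kind1_is_free_toxin(self):
        assert holling_response(1, 0.3, 123.0, 9.0) == 0.3

    def test_kind2_uptake_product(self):
        assert holling_response(2, 0.4, 0.25, 0.1) == pytest.approx(0.01)

    def test_kind2_zero_toxin(self):
        assert holling_response(2, 0.0, 0.5, 0.1) == 0.0

    def test_bad_kind(self):
        with pytest.raises(ValueError):
            holling_response(3, 0.1, 0.1, 0.1)


class TestReactionTerms:
    def test_carrying_capacity_fixed_point(self):
        params, net = single_species_params()
        grid = GridSpec(5, 5, 1.0)
        state = init_homogeneous(grid, [1.0])
        dN, _ = reaction_terms(state, params, net)
        np.testing.assert_allclose(dN, 0.0, atol=1e-14)

    def test_pure_toxin_degradation(self):
        params, net = single_species_params(delta=0.1)
        grid = GridSpec(5, 5, 1.0)
        state = init_homogeneous(grid, [0.0])
        state.B[:] = 0.2
        _, dB = reaction_terms(state, params, net)
        np.testing.assert_allclose(dB, -0.02)

    def test_rps_pointwise_against_hand_evaluation(self, rps_net, fig_params):
        """Homogeneous 3-species state matches a scalar evaluation of the
        right-hand side done with plain Python loops."""
        grid = GridSpec(4, 4, 1.0)
        N0 = [0.2, 0.3, 0.1]
        B0 = [0.05, 0.02, 0.1]
        state = init_homogeneous(grid, N0)
        for i, b in enumerate(B0):
            state.B[i] = b
        dN, dB = reaction_terms(state, fig_params, rps_net)
        # one-step oracle: infer the rates from an Euler step of size dt
        dt = 1e-3
        N1, B1, _ = euler_ode_oracle(N0, B0, fig_params, rps_net, dt, 1)
        for i in range(3):
            assert dN[i, 0, 0] == pytest.approx((N1[i] - N0[i]) / dt, rel=1e-9)
            assert dB[i, 0, 0] == pytest.approx((B1[i] - B0[i]) / dt, rel=1e-9)

    def test_shape_mismatch(self, rps_net, fig_params):
        grid = GridSpec(4, 4, 1.0)
        state = init_homogeneous(grid, [0.1, 0.2])  # 2 species vs 3
        with pytest.raises(ValueError):
            reaction_terms(state, fig_params, rps_net)


class TestInitCircularPatches:
    def test_three_disjoint_discs(self):
        grid = GridSpec(100, 100, 1.0)
        state = init_circular_patches(grid, 3, radius=8.0, density0=0.25)
        present = (state.N > 0).sum(axis=0)
        assert present.max() == 1  # pairwise disjoint
        for i in range(3):
            vals = state.N[i][state.N[i] > 0]
            assert vals.size > 0
            assert np.all(vals == 0.25)
        assert np.all(state.B == 0)

    def test_single_centered_disc(self):
        grid = GridSpec(40, 40, 1.0)
        state = init_circular_patches(grid, 1, radius=5.0)
        c = (grid.nx - 1) // 2
        assert state.N[0, c, c] == 0.25

    def test_overlap_geometry_error(self):
        grid = GridSpec(20, 20, 1.0)
        with pytest.raises(GeometryError):
            init_circular_patches(grid, 9, radius=8.0)


class TestInitRandomPatchwork:
    def test_one_species_per_node_in_range(self):
        grid = GridSpec(60, 60, 1.0)
        state = init_random_patchwork(grid, 4, a=5.0, seed=11)
        nonzero = (state.N > 0).sum(axis=0)
        assert nonzero.max() == 1
        occupied = state.N.max(axis=0)
        assert occupied.min() >= 0.01 and occupied.max() <= 1.0
        assert np.all(state.B == 0)

    def test_determinism(self):
        grid = GridSpec(32, 32, 1.0)
        a = init_random_patchwork(grid, 3, a=4.0, seed=5)
        b = init_random_patchwork(grid, 3, a=4.0, seed=5)
        np.testing.assert_array_equal(a.N, b.N)

    def test_single_species(self):
        grid = GridSpec(16, 16, 1.0)
        state = init_random_patchwork(grid, 1, a=4.0, seed=0)
        assert np.all(state.N[0] >= 0.01) and np.all(state.N[0] <= 1.0)

    def test_bad_patch_size(self):
        grid = GridSpec(16, 16, 1.0)
        with pytest.raises(ValueError):
            init_random_patchwork(grid, 2, a=0.0, seed=0)
        with pytest.raises(ValueError):
            init_random_patchwork(grid, 2, a=20.0, seed=0)


class TestStep:
    def test_nonpositive_dt_rejected(self, rps_net, fig_params):
        grid = GridSpec(8, 8, 1.0)
        state = init_homogeneous(grid, [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            step(state, fig_params, rps_net, 0.0)

    def test_homogeneous_matches_scalar_euler(self, rps_net):
        params = ContinuousParameters.uniform(3, d=0.0, D=0.0)
        grid = GridSpec(6, 6, 1.0)
        N0, B0 = [0.2, 0.25, 0.15], [0.0, 0.0, 0.0]
        state = init_homogeneous(grid, N0)
        out = step(state, params, rps_net, 0.05)
        N1, B1, _ = euler_ode_oracle(N0, B0, params, rps_net, 0.05, 1)
        for i in range(3):
            np.testing.assert_allclose(out.N[i], N1[i], rtol=0, atol=1e-14)
            np.testing.assert_allclose(out.B[i], B1[i], rtol=0, atol=1e-14)

    def test_nonnegativity_over_random_states(self, rps_net):
        """One admissible Euler step from a random nonnegative state never
        produces negative densities or concentrations (1000 trials)."""
        rng = np.random.default_rng(42)
        grid = GridSpec(8, 8, 1.0)
        for _ in range(1000):
            params = ContinuousParameters.uniform(
                3,
                r=rng.uniform(0, 0.6),
                nu=rng.uniform(0, 1),
                mu=rng.uniform(0, 0.5),
                gamma=rng.uniform(0, 0.3),
                beta=rng.uniform(0, 1),
                delta=rng.uniform(0.01, 0.3),
                d=rng.uniform(0, 0.05),
                D=rng.uniform(0, 0.05),
                response_kind=int(rng.integers(1, 3)),
            )
            N = rng.uniform(0, 1.2, size=(3, 8, 8))
            B = rng.uniform(0, 2.0, size=(3, 8, 8))
            state = FieldState(N, B, 0.0, grid)
            # admissible dt: diffusive bound and per-capita reaction bound
            rate = max(
                params.r.max() * (1 + params.nu.sum(axis=1).max() * 1.2)
                + params.mu * (params.gamma if params.response_kind == 2 else 1)
                * 2.0 * 1.2 * 2,
                params.delta.max() + params.gamma * 2 * 1.2,
            )
            dt = min(0.2 / rate, 0.9 / (4 * max(params.d.max(), params.D.max(), 1e-9)))
            out = step(state, params, rps_net, dt)
            assert out.N.min() >= 0, "negative density after admissible step"
            assert out.B.min() >= 0, "negative concentration after admissible step"


class TestIntegrate:
    def test_logistic_recovery(self):
        """A lone species relaxes to carrying capacity along the closed-form
        logistic curve."""
        params, net = single_species_params(r=0.3)
        grid = GridSpec(8, 8, 1.0)
        state = init_homogeneous(grid, [0.1])
        final, traj = integrate(state, params, net, 80.0, record_dt=5.0, dt=0.01)
        closed = 1.0 / (1.0 + (1.0 / 0.1 - 1.0) * np.exp(-0.3 * traj.times[-1]))
        assert abs(final.spatial_means()[0] - closed) <= 1e-4
        assert abs(final.spatial_means()[0] - 1.0) <= 1e-4
        # the transient follows the closed form to Euler accuracy
        mid = 1.0 / (1.0 + (1.0 / 0.1 - 1.0) * np.exp(-0.3 * traj.times))
        np.testing.assert_allclose(traj.means[:, 0], mid, atol=5e-3)

    def test_ode_limit_node_for_node(self, rps_net):
        """With zero diffusivities every node follows the independently coded
        0-D Euler trajectory to 1e-12."""
        params = ContinuousParameters.uniform(3, d=0.0, D=0.0)
        grid = GridSpec(5, 5, 1.0)
        N0 = [0.2, 0.25, 0.15]
        state = init_homogeneous(grid, N0)
        dt = 0.05
        final, _ = integrate(state, params, rps_net, 10.0, record_dt=1.0, dt=dt)
        Nend, Bend, _ = euler_ode_oracle(N0, [0, 0, 0], params, rps_net, dt, 200)
        for i in range(3):
            np.testing.assert_allclose(final.N[i], Nend[i], rtol=0, atol=1e-12)
            np.testing.assert_allclose(final.B[i], Bend[i], rtol=0, atol=1e-12)

    def test_toxin_steady_state_balance(self):
        """Single species, no uptake: B* = beta N* / delta at equilibrium."""
        params, net = single_species_params(r=0.5, beta=0.5, delta=0.1)
        grid = GridSpec(6, 6, 1.0)
        state = init_homogeneous(grid, [0.3])
        final, _ = integrate(state, params, net, 300.0, record_dt=50.0, dt=0.02)
        Nstar = final.N[0, 0, 0]
        expected = params.beta[0] * Nstar / params.delta[0]
        np.testing.assert_allclose(final.B[0], expected, atol=1e-6)

    def test_permutation_symmetry_exact(self):
        """Rotating species labels of a symmetric cyclic game (with purely
        intraspecific competition) rotates the trajectories exactly."""
        net = build_cycle(3, 1)
        params = ContinuousParameters.uniform(3, nu=0.0, mu=0.4, d=0.005, D=0.005)
        grid = GridSpec(48, 48, 1.0)
        base = init_circular_patches(grid, 3)
        rotated = FieldState(base.N[[1, 2, 0]].copy(), base.B[[1, 2, 0]].copy(),
                             0.0, grid)
        fin_a, traj_a = integrate(base, params, net, 60.0, record_dt=10.0)
        fin_b, traj_b = integrate(rotated, params, net, 60.0, record_dt=10.0)
        for i in range(3):
            np.testing.assert_array_equal(fin_b.N[i], fin_a.N[[1, 2, 0][i]])
            np.testing.assert_array_equal(
                traj_b.means[:, i], traj_a.means[:, [1, 2, 0][i]]
            )

    def test_blowup_reports_time(self, rps_net):
        from allelloscape.pde import NumericalBlowupError

        params = ContinuousParameters.uniform(3, r=1e8, d=0.0, D=0.0)
        grid = GridSpec(4, 4, 1.0)
        state = init_homogeneous(grid, [0.5, 0.5, 0.5])
        import warnings

        with pytest.raises(NumericalBlowupError) as exc:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                integrate(state, params, rps_net, 5.0, record_dt=0.1, dt=0.05)
        assert exc.value.t > 0

    def test_t_end_must_advance(self, rps_net, fig_params):
        grid = GridSpec(4, 4, 1.0)
        state = init_homogeneous(grid, [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            integrate(state, fig_params, rps_net, 0.0)
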