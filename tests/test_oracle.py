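"""Analytic 1-D multilayer oracle and 3-D solver verification against it."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from thermosole import (
    DEFAULT_BLOOD,
    TISSUE,
    BoundarySpec,
    GridResolution,
    LayerSpec,
    MaterialProps,
    build_domain,
    compare_to_oracle,
    foot_tissue_layers,
    insole_shoe_layers,
    solve_1d,
    solve_steady,
)


def brute_force_1d(layers, blood, bc, n_per_layer=1000, sock_after=None):
    """Independent cell-centered finite-volume solve of the 1-D stack.

    Deliberately separate from both the analytic oracle and the 3-D
    solver: a plain tridiagonal assembly at very fine uniform-per-layer
    resolution.
    """
    zs, mats = [0.0], []
    for sp_ in layers:
        for _ in range(n_per_layer):
            zs.append(zs[-1] + sp_.thickness / n_per_layer)
            mats.append(sp_.material)
    z = np.array(zs)
    zc = 0.5 * (z[:-1] + z[1:])
    dz = np.diff(z)
    n = len(zc)
    k = np.array([m.thermal_conductivity for m in mats])
    w = np.array([m.perfusion_rate for m in mats])
    q = np.array([m.metabolic_heat for m in mats])
    tb = np.array([m.blood_temperature for m in mats])
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    rhs = np.zeros(n)
    sock_face = None if sock_after is None else (sock_after + 1) * n_per_layer
    for f in range(1, n):
        r = dz[f - 1] / (2 * k[f - 1]) + dz[f] / (2 * k[f])
        if sock_face is not None and f == sock_face:
            r += bc.sock_resistance
        g = 1.0 / r
        main[f - 1] += g
        main[f] += g
        lower[f - 1] -= g
        upper[f - 1] -= g
    if bc.top == "fixed":
        g = k[0] / (dz[0] / 2)
        main[0] += g
        rhs[0] += g * bc.top_T
    if bc.floor_h > 0:
        g = 1.0 / (1.0 / bc.floor_h + dz[-1] / (2 * k[-1]))
        main[-1] += g
        rhs[-1] += g * bc.floor_T_env
    perf = blood.volumetric_heat_capacity * w * dz
    main += perf
    rhs += perf * tb + q * dz
    a = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    return zc, spla.spsolve(a, rhs)


class TestClosedForm:
    def test_single_layer_dirichlet_linear(self, slab_material):
        sol = solve_1d(
            [LayerSpec(slab_material, 0.01)],
            DEFAULT_BLOOD,
            BoundarySpec(floor_h=1e12, floor_T_env=20.0, top="fixed", top_T=37.0),
        )
        z = np.linspace(0, 0.01, 11)
        np.testing.assert_allclose(sol(z), 37.0 - 17.0 * z / 0.01, atol=1e-6)

    def test_thick_perfused_slab_reaches_equilibrium_at_depth(self):
        """With an adiabatic deep end, a thick muscle slab approaches the
        perfusion equilibrium ~37.07 degC away from the cooled face."""
        sol = solve_1d(
            [LayerSpec(TISSUE["muscle"], 0.06)], DEFAULT_BLOOD, BoundarySpec()
        )
        assert float(sol(0.0)) == pytest.approx(37.0667, abs=5e-3)

    def test_full_stack_matches_brute_force(self, full_stack, standard_bc):
        """Analytic coefficients vs an independent 10^4-node finite-volume
        solve of the same stack: agreement to < 1e-4 degC."""
        sol = solve_1d(full_stack, DEFAULT_BLOOD, standard_bc, sock_after_layer=4)
        zc, t_fd = brute_force_1d(
            full_stack, DEFAULT_BLOOD, standard_bc, sock_after=4
        )
        assert np.max(np.abs(sol(zc) - t_fd)) < 1e-4

    def test_interface_continuity_and_sock_jump(self, full_stack, standard_bc):
        """Temperature and flux are continuous at every interface except the
        sock plane, where the jump equals R_sock times the flux."""
        sol = solve_1d(full_stack, DEFAULT_BLOOD, standard_bc, sock_after_layer=4)
        for i in range(len(full_stack) - 1):
            t_above, t_below, q_above, q_below = sol.interface_values(i)
            assert q_above == pytest.approx(q_below, rel=1e-9, abs=1e-9)
            if i == 4:  # skin-insole interface carries the sock
                expected_jump = standard_bc.sock_resistance * q_above
                assert t_above - t_below == pytest.approx(expected_jump, rel=1e-6)
            else:
                assert t_above == pytest.approx(t_below, rel=0, abs=1e-9)

    def test_ode_residual_spot_check(self, full_stack, standard_bc):
        """Numerical second differences of the closed form satisfy the
        steady equation at random interior points (tolerance limited by
        finite-difference round-off, not by the solution)."""
        sol = solve_1d(full_stack, DEFAULT_BLOOD, standard_bc, sock_after_layer=4)
        rng = np.random.default_rng(42)
        h = 1e-4  # balances truncation against round-off in the 2nd difference
        for _ in range(20):
            i = rng.integers(0, len(sol.layers))
            z0, z1 = sol.z_interfaces[i], sol.z_interfaces[i + 1]
            if z1 - z0 < 12 * h:
                continue  # layer too thin for the finite-difference stencil
            z = rng.uniform(z0 + 5 * h, z1 - 5 * h)
            mat = sol.layers[i].material
            k = mat.thermal_conductivity
            t = float(sol(z))
            d2 = (float(sol(z + h)) - 2 * t + float(sol(z - h))) / h**2
            perf = DEFAULT_BLOOD.volumetric_heat_capacity * mat.perfusion_rate
            residual = k * d2 + perf * (mat.blood_temperature - t) + mat.metabolic_heat
            scale = max(abs(mat.metabolic_heat), perf * 2.0, 1.0)
            assert abs(residual) / scale < 1e-3

    def test_degenerate_all_adiabatic_rejected(self, slab_material):
        with pytest.raises(ValueError, match="singular|adiabatic"):
            solve_1d(
                [LayerSpec(slab_material, 0.01)], DEFAULT_BLOOD,
                BoundarySpec(floor_h=0.0),
            )


class TestSolverVsOracle:
    def solve_3d(self, res=None):
        layers = foot_tissue_layers() + insole_shoe_layers()
        res = res or GridResolution(dx=0.065, dy=0.0225)
        grid = build_domain(
            layers[:5], layers[5:], footprint=(0.26, 0.09), resolution=res
        )
        bc = BoundarySpec(sock_resistance=0.02)
        fld = solve_steady(grid, DEFAULT_BLOOD, bc)
        oracle = solve_1d(layers, DEFAULT_BLOOD, bc, sock_after_layer=4)
        return fld, grid, oracle

    def test_default_resolution_within_hundredth_degree(self):
        fld, grid, oracle = self.solve_3d()
        assert compare_to_oracle(fld, grid, oracle) < 0.01

    def test_second_order_z_convergence(self):
        """Halving the vertical spacing cuts the oracle deviation by about
        4x (second-order scheme)."""
        coarse = GridResolution(dx=0.065, dy=0.0225, dz_fine=1.0e-3,
                                dz_coarse=5.0e-3)
        fine = GridResolution(dx=0.065, dy=0.0225, dz_fine=0.5e-3,
                              dz_coarse=2.5e-3)
        fld_c, grid_c, oracle_c = self.solve_3d(coarse)
        e_coarse = compare_to_oracle(fld_c, grid_c, oracle_c)
        fld_f, grid_f, oracle_f = self.solve_3d(fine)
        e_fine = compare_to_oracle(fld_f, grid_f, oracle_f)
        assert e_fine < e_coarse / 2.5
        assert e_coarse < 0.05

    def test_self_comparison_is_zero(self, full_stack, standard_bc):
        oracle = solve_1d(full_stack, DEFAULT_BLOOD, standard_bc,
                          sock_after_layer=4)
        dev = np.max(np.abs(oracle(np.linspace(0, oracle.z_interfaces[-1], 50))
                            - oracle(np.linspace(0, oracle.z_interfaces[-1], 50))))
        assert dev == 0.0

    def test_stack_mismatch_rejected(self, standard_bc):
        fld, grid, _ = self.solve_3d()
        wrong = solve_1d(foot_tissue_layers(), DEFAULT_BLOOD, BoundarySpec())
        with pytest.raises(ValueError, match="match"):
            compare_to_oracle(fld, grid, wrong)
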