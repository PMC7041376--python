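"""Biot poroelastic solver verification against closed forms.

Benchmarks: single-element stiffness vs. an exact symbolic oracle, drained
confined compression (oedometer), Terzaghi 1-D consolidation, steady Darcy
flow, and the linearity / equilibrium invariants of the discrete model.
"""

import numpy as np
import pytest

import oracles
from scaffopt import mocks
from scaffopt.fem import (
    GRANULATION_TISSUE,
    SCAFFOLD_PLA,
    BoundaryConditions,
    LoadCase,
    MaterialProperties,
    assemble_biot,
    hex_element_matrices,
    hex_stiffness,
    solve_compression,
)
from scaffopt.geometry import DomainSpec, ScaffoldSpec, build_scaffold

# nearly incompressible constituents: alpha -> 1, storage -> 0, so the
# classic Terzaghi solution (c_v = k * (lambda + 2G)) applies
TERZAGHI_MAT = MaterialProperties(
    E_MPa=1.0, nu=0.0, k_m4_Ns=1e-12, n_poro=0.5,
    K_grain_MPa=1e9, K_fluid_MPa=1e9,
)


def small_scaffold_system(d_fil=800.0, res=100.0, layers=4):
    model = build_scaffold(
        ScaffoldSpec(D_um=400.0, d_fil_um=d_fil),
        DomainSpec(resolution_um=res, n_layers=layers),
    )
    return model, assemble_biot(model)


class TestMaterialProperties:
    def test_biot_coefficient_incompressible_grain_limit(self):
        mat = MaterialProperties(
            E_MPa=1.0, nu=0.3, k_m4_Ns=1e-14, n_poro=0.5,
            K_grain_MPa=1e15, K_fluid_MPa=2300.0,
        )
        assert mat.alpha == pytest.approx(1.0, abs=1e-12)

    def test_table_values_derived_constants(self):
        # scaffold: K_drained = 2300 / (3 * 0.4); granulation nearly alpha=1
        assert SCAFFOLD_PLA.K_drained == pytest.approx(2300.0 / 1.2)
        assert 0.85 < SCAFFOLD_PLA.alpha < 0.87
        assert GRANULATION_TISSUE.alpha == pytest.approx(1.0, abs=1e-3)
        assert SCAFFOLD_PLA.k_mm == pytest.approx(1e-2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(E_MPa=-1.0), dict(nu=0.5), dict(k_m4_Ns=0.0),
            dict(n_poro=1.0), dict(K_grain_MPa=-1.0),
        ],
    )
    def test_invalid_materials_rejected(self, kwargs):
        base = dict(E_MPa=1.0, nu=0.3, k_m4_Ns=1e-14, n_poro=0.5,
                    K_grain_MPa=100.0, K_fluid_MPa=100.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            MaterialProperties(**base)


class TestElementMatrices:
    def test_stiffness_matches_symbolic_oracle(self):
        import sympy as sym

        K_ref = oracles.sympy_hex_stiffness(1, 12, sym.Rational(1, 4))
        K = hex_stiffness(1.0, 12.0, 0.25)
        np.testing.assert_allclose(K, K_ref, rtol=0, atol=1e-12)

    def test_stiffness_scales_linearly_in_E_and_h(self):
        K1 = hex_stiffness(1.0, 1.0, 0.3)
        np.testing.assert_allclose(hex_stiffness(0.05, 230.0, 0.3),
                                   230.0 * 0.05 * K1, rtol=1e-12)

    def test_rigid_body_modes_are_null(self):
        K = hex_stiffness(0.1, 2300.0, 0.3)
        w = np.linalg.eigvalsh(K)
        assert np.all(np.abs(w[:6]) < 1e-9 * w[-1])  # 3 translations + 3 rotations
        assert w[6] > 0

    def test_blocks_are_symmetric(self):
        m = hex_element_matrices(0.1, GRANULATION_TISSUE)
        for name in ("K", "S", "H", "Lstab"):
            np.testing.assert_allclose(m[name], m[name].T, atol=1e-15)


class TestAssembly:
    def test_homogeneous_elasticity_block_equals_single_hex(self):
        model = mocks.homogeneous_column(n_xy=1, n_z=1, voxel_mm=0.1)
        system = assemble_biot(model, GRANULATION_TISSUE, GRANULATION_TISSUE)
        K_elem = hex_element_matrices(0.1, GRANULATION_TISSUE)["K"]
        conn = system.conn[0]
        dofs = (3 * conn[:, None] + np.arange(3)).ravel()
        np.testing.assert_allclose(
            system.K.toarray()[np.ix_(dofs, dofs)], K_elem, rtol=1e-12
        )

    def test_mixed_phase_blocks_symmetric(self):
        _, system = small_scaffold_system()
        assert (system.K - system.K.T).nnz == 0 or \
            abs(system.K - system.K.T).max() < 1e-9
        assert abs(system.H - system.H.T).max() < 1e-15


class TestSolveCompression:
    def test_drained_oedometer_matches_confined_closed_form(self):
        # long-time drained solve: uniform strain -p / (lambda + 2G)
        mat = GRANULATION_TISSUE
        model = mocks.homogeneous_column(n_xy=2, n_z=10, voxel_mm=0.1)
        system = assemble_biot(model, mat, mat)
        load = LoadCase(p_MPa=0.01, ramp_time_s=1.0, eval_time_s=5000.0,
                        dt_s=250.0)
        sol = solve_compression(system, load)
        eps_zz = -sol.settlement_mm() / 1.0
        assert eps_zz == pytest.approx(-0.01 / mat.M_constrained, rel=0.01)
        np.testing.assert_allclose(
            sol.states.eps_III, -0.01 / mat.M_constrained, rtol=0.01
        )

    def test_terzaghi_consolidation(self):
        n_z, L, p0, T = 40, 1.0, 0.1, 0.5
        model = mocks.homogeneous_column(n_xy=1, n_z=n_z, voxel_mm=L / n_z)
        system = assemble_biot(model, TERZAGHI_MAT, TERZAGHI_MAT)
        cv = TERZAGHI_MAT.k_mm * TERZAGHI_MAT.M_constrained
        t_end = T * L**2 / cv
        times = np.geomspace(1e-5, t_end, 400)
        load = LoadCase(p_MPa=p0, ramp_time_s=times[0], eval_time_s=t_end)
        sol = solve_compression(system, load, times=times)

        p_fe = sol.p.reshape(2, 2, n_z + 1).mean(axis=(0, 1))
        z = np.arange(n_z + 1) * (L / n_z)
        p_ref = oracles.terzaghi_pressure(L - z, L, cv, t_end, p0)
        err = np.linalg.norm(p_fe - p_ref) / np.linalg.norm(p_ref)
        assert err < 0.02

        s_ref = oracles.terzaghi_settlement(
            L, cv, t_end, p0, TERZAGHI_MAT.M_constrained
        )
        assert sol.settlement_mm() == pytest.approx(s_ref, rel=0.02)

    def test_zero_load_gives_zero_response(self):
        model = mocks.homogeneous_column(n_xy=1, n_z=4, voxel_mm=0.1)
        system = assemble_biot(model)
        sol = solve_compression(system, LoadCase(p_MPa=0.0))
        assert np.allclose(sol.u, 0) and np.allclose(sol.p, 0)
        assert np.all(sol.states.v_um_s == 0)

    def test_load_reaction_balance(self):
        _, system = small_scaffold_system()
        sol = solve_compression(system, LoadCase(p_MPa=0.5))
        assert abs(sol.reaction_bottom_N) == pytest.approx(
            sol.applied_force_N, rel=0.005
        )

    def test_response_is_linear_in_load(self):
        _, system = small_scaffold_system()
        s1 = solve_compression(system, LoadCase(p_MPa=0.5)).states
        s2 = solve_compression(system, LoadCase(p_MPa=1.0)).states
        np.testing.assert_allclose(s2.eps_III, 2 * s1.eps_III, rtol=1e-8,
                                   atol=1e-14)
        np.testing.assert_allclose(s2.v_um_s, 2 * s1.v_um_s, rtol=1e-8,
                                   atol=1e-14)

    def test_principal_strain_ordering(self):
        _, system = small_scaffold_system()
        st = solve_compression(system, LoadCase(p_MPa=0.5)).states
        assert np.all(st.eps_I >= st.eps_II) and np.all(st.eps_II >= st.eps_III)
        assert np.all(st.v_um_s >= 0)

    def test_eval_before_ramp_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(p_MPa=0.5, ramp_time_s=1.0, eval_time_s=0.5)


class TestFluidVelocity:
    def test_steady_darcy_flow_closed_form(self):
        # both ends drained, pressure drop dp over length L: v = k dp / L
        mat = GRANULATION_TISSUE
        model = mocks.homogeneous_column(n_xy=1, n_z=10, voxel_mm=0.1)
        system = assemble_biot(model, mat, mat)
        load = LoadCase(p_MPa=0.01, ramp_time_s=1.0, eval_time_s=1e7, dt_s=5e5)
        bcs = BoundaryConditions(drained_top=True, drained_bottom=True,
                                 p_bottom_MPa=0.05)
        sol = solve_compression(system, load, bcs=bcs)
        v_expect = mat.k_mm * 0.05 / 1.0 * 1e3  # um/s
        np.testing.assert_allclose(sol.states.v_um_s, v_expect, rtol=1e-6)

    def test_uniform_pressure_gives_zero_velocity(self):
        from scaffopt.fem import element_fluid_velocity

        model = mocks.homogeneous_column(n_xy=1, n_z=4, voxel_mm=0.1)
        system = assemble_biot(model)
        sol = solve_compression(system, LoadCase(p_MPa=0.0))
        assert element_fluid_velocity(sol, 0) == 0.0
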