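"""Coupled solver: equilibrium preservation, mechanics, step control, orders."""

import numpy as np
import pytest

from scarsim.geometry import DomainSpec, WoundSpec, initial_state
from scarsim.mesh import generate_mesh
from scarsim.parameters import ParameterSet
from scarsim.solver import (
    SolverOptions,
    StateFields,
    StepControl,
    adapt_timestep,
    assemble_constituent_system,
    defect_correction_step,
    simulate,
    solve_mechanics,
    _mesh_edges,
)


class TestMechanicsSolve:
    def test_no_myofibroblasts_gives_zero_displacement(self, coarse_mesh, params):
        rho = np.full(coarse_mesh.n_nodes, params.rho_bar)
        M = np.zeros(coarse_mesh.n_nodes)
        u, n_it = solve_mechanics(coarse_mesh, M, rho, params)
        assert np.all(u == 0.0)
        assert n_it == 0

    def test_symmetric_load_gives_mirror_symmetric_displacement(self, params):
        mesh = generate_mesh(DomainSpec(), 0.1, seed=0)
        Y = mesh.nodes_ref[:, 0]
        M = 500.0 * np.exp(-((Y / 3.0) ** 2))  # even myofibroblast bump
        rho = np.full(mesh.n_nodes, 0.05)
        u, _ = solve_mechanics(mesh, M, rho, params)
        assert np.abs(u).max() > 1e-6  # the load actually deforms the slab
        # mirror each node across Y=0 and compare (u_y flips, u_z preserved)
        order = np.lexsort((np.round(mesh.nodes_ref[:, 1], 9),
                            np.round(mesh.nodes_ref[:, 0], 9)))
        order_m = np.lexsort((np.round(mesh.nodes_ref[:, 1], 9),
                              np.round(-mesh.nodes_ref[:, 0], 9)))
        scale = np.abs(u).max()
        assert np.allclose(u[order, 0], -u[order_m, 0], atol=1e-6 * scale)
        assert np.allclose(u[order, 1], u[order_m, 1], atol=1e-6 * scale)

    def test_small_load_limit_is_linear_response(self, params):
        """Doubling the traction load doubles the displacement up to an
        O(psi^2) defect: the relative deviation shrinks linearly with the
        load, consistent with convergence to the linearized equations."""
        mesh = generate_mesh(DomainSpec(), 0.1, seed=0)
        rho = np.full(mesh.n_nodes, params.rho_bar)
        base = np.exp(-((mesh.nodes_ref[:, 0] / 3.0) ** 2))
        devs = []
        for M0 in (100.0, 1.0):
            u1, _ = solve_mechanics(mesh, M0 * base, rho, params)
            u2, _ = solve_mechanics(mesh, 2.0 * M0 * base, rho, params)
            assert np.abs(u2).max() > 0
            devs.append(np.abs(u2 - 2.0 * u1).max() / np.abs(u2).max())
        assert devs[0] < 0.02       # already nearly linear at psi ~ 0.2 N/cm^2
        assert devs[1] < 1e-4       # and two orders closer at 1% of that load
        assert devs[0] / devs[1] > 30.0


class TestConstituentAssembly:
    def test_equilibrium_state_is_a_fixed_point_of_the_step(self, coarse_mesh, params):
        f = initial_state(coarse_mesh.nodes_ref[:, 0], params, None)
        state = StateFields(0.0, f["N"], f["M"], f["c"], f["rho"])
        opts = SolverOptions()
        new_state, new_mesh, u, est, rep = defect_correction_step(
            coarse_mesh, state, None, 1.0, 0.0, params, opts,
            _mesh_edges(coarse_mesh.triangles), np.zeros((coarse_mesh.n_nodes, 2)),
        )
        assert rep.fp_iterations == 1
        assert np.allclose(new_state.N, params.N_bar, rtol=1e-12)
        assert np.allclose(new_state.rho, params.rho_bar, rtol=1e-12)
        assert np.all(u == 0.0)

    def test_dirichlet_rows_and_patankar_fields(self, coarse_mesh, params):
        f = initial_state(coarse_mesh.nodes_ref[:, 0], params, WoundSpec())
        guess = StateFields(0.0, f["N"], f["M"], f["c"], f["rho"])
        sysd = assemble_constituent_system(
            coarse_mesh.nodes_ref, coarse_mesh.nodes_ref, coarse_mesh, guess, params, "N"
        )
        assert np.all(sysd["production"] >= 0.0)
        assert np.all(sysd["destruction"] >= 0.0)
        lateral = sysd["dirichlet_idx"]
        assert np.all(np.isin(lateral, coarse_mesh.boundary_nodes()))
        assert np.all(sysd["dirichlet_val"] == params.N_bar)

    def test_one_triangle_diffusion_operator_matches_hand_assembly(self, params):
        """The transport operator of the signal on a single unit triangle is
        minus D_c times the P1 Laplacian of that triangle."""
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        tri = np.array([[0, 1, 2]])
        from scarsim.mesh import TriMesh

        mesh = TriMesh(nodes_ref=pts, triangles=tri,
                       boundary_edges=np.array([[0, 1], [1, 2], [2, 0]]),
                       boundary_tags=np.array(["B.I", "B.II", "B.III"]))
        z = np.array([1.0, 1.0, 1.0])
        guess = StateFields(0.0, z * 1e4, z * 0.0, z * 1e-8, z * 0.1)
        sysd = assemble_constituent_system(pts, pts, mesh, guess, params, "c")
        hand = 0.5 * np.array([[2.0, -1.0, -1.0], [-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
        assert np.allclose(sysd["K"].toarray(), -params.D_c * hand, atol=1e-15)


class TestAdaptTimestep:
    def test_zero_estimate_grows_maximally(self):
        ctrl = StepControl(dt=1.0, tol=1e-3)
        dt_new, accept = adapt_timestep(0.0, ctrl)
        assert accept
        assert dt_new == pytest.approx(ctrl.grow_max * 1.0)

    def test_estimate_at_tolerance_shrinks_by_safety(self):
        ctrl = StepControl(dt=1.0, tol=1e-3)
        dt_new, accept = adapt_timestep(1e-3, ctrl)
        assert accept
        assert dt_new == pytest.approx(ctrl.safety)

    def test_reject_above_tolerance(self):
        ctrl = StepControl(dt=1.0, tol=1e-3)
        dt_new, accept = adapt_timestep(1e-1, ctrl)
        assert not accept
        assert dt_new < 1.0

    def test_clamped_to_bounds(self):
        ctrl = StepControl(dt=1.0, tol=1e-3, dt_max=1.5)
        dt_new, _ = adapt_timestep(0.0, ctrl)
        assert dt_new == 1.5
        ctrl = StepControl(dt=1e-8, tol=1e-3, dt_min=1e-8)
        dt_new, _ = adapt_timestep(10.0, ctrl)
        assert dt_new == 1e-8

    def test_negative_estimate_rejected(self):
        with pytest.raises(ValueError):
            adapt_timestep(-1.0, StepControl(dt=1.0))

    def test_controller_tracks_exact_decay_solution(self):
        """On dz/dt = -z the accepted-step local errors stay below the
        tolerance measured against the exact solution."""
        tol = 1e-4
        ctrl = StepControl(dt=0.01, tol=tol, dt_max=1.0)
        z, z_prev, t = 1.0, None, 0.0
        dt_prev = 0.0
        while t < 5.0:
            dt = ctrl.dt
            z_new = z / (1.0 + dt)  # backward Euler
            if z_prev is None:
                est = 0.0
            else:
                pred = z + dt * (z - z_prev) / dt_prev
                est = dt / (dt + dt_prev) * abs(z_new - pred)
            dt_next, accept = adapt_timestep(est, ctrl)
            if accept:
                exact_step = z * np.exp(-dt)
                assert abs(z_new - exact_step) < 2.0 * max(tol, 1e-12)
                z_prev, dt_prev = z, dt
                z, t = z_new, t + dt
            ctrl.dt = dt_next
        # the global first-order error stays modest (local errors accumulate)
        assert z == pytest.approx(np.exp(-5.0), rel=0.25)


class TestConvergenceOrders:
    """Manufactured heat-equation solutions through the package's P1 operators."""

    def test_first_order_in_time(self, unit_square_mesh):
        from conftest import heat_equation_error

        errs = [heat_equation_error(unit_square_mesh, dt, 0.08)
                for dt in (0.02, 0.01, 0.005)]
        r1 = errs[0] / errs[1]
        r2 = errs[1] / errs[2]
        assert 1.6 < r1 < 2.6  # halving dt halves the error
        assert 1.6 < r2 < 2.6

    def test_second_order_in_space(self):
        from conftest import heat_equation_error

        dom = DomainSpec(y_min=0.0, y_max=1.0, z_min=0.0, z_max=1.0)
        errs = []
        for h in (0.2, 0.1, 0.05):
            mesh = generate_mesh(dom, h, seed=0)
            errs.append(heat_equation_error(mesh, 1e-4, 2e-3))
        assert errs[1] < errs[0] / 3.0  # ~4x per halving
        assert errs[2] < errs[1] / 3.0


class TestCheckpointRestart:
    def test_round_trip_and_resume(self, tmp_path, coarse_mesh, params):
        """A run split across a checkpoint reproduces the single-run state."""
        from scarsim.solver import load_checkpoint, save_checkpoint

        wound = WoundSpec(half_width=4.0)
        full = simulate(coarse_mesh, params, wound, duration=2.0)
        first = simulate(coarse_mesh, params, wound, duration=1.0)
        path = tmp_path / "chk.npz"
        save_checkpoint(path, first.mesh, first.final)
        mesh2, state2 = load_checkpoint(path)
        assert np.array_equal(mesh2.nodes_cur, first.mesh.nodes_cur)
        resumed = simulate(mesh2, params, wound, duration=1.0, initial=state2)
        assert resumed.final.time == pytest.approx(2.0)
        # restart resets the adaptive-step history, so the two trajectories
        # differ by the (first-order) time-discretization error only
        for k in ("N", "M", "c", "rho"):
            a = getattr(resumed.final, k)
            b = getattr(full.final, k)
            scale = max(np.abs(b).max(), 1e-300)
            assert np.abs(a - b).max() / scale < 1e-2


class TestEquilibriumRun:
    def test_unwounded_run_is_stationary(self, nowound_run, params):
        """Twenty days from the unwounded state: all fields stay at their
        equilibria to solver tolerance and the mesh never moves."""
        f = nowound_run.final
        assert f.time == pytest.approx(20.0)
        assert np.abs(f.N / params.N_bar - 1.0).max() < 1e-6
        assert np.abs(f.rho / params.rho_bar - 1.0).max() < 1e-6
        assert np.abs(f.M).max() < 1e-6 * params.N_bar
        assert np.abs(f.c).max() < 1e-6 * params.c_w
        assert np.abs(nowound_run.mesh.displacement).max() == 0.0

    def test_dirichlet_values_hold_at_all_times(self, nowound_run, params):
        lateral = np.concatenate([
            nowound_run.mesh.boundary_nodes("B.II"),
            nowound_run.mesh.boundary_nodes("B.IV"),
        ])
        for st_ in nowound_run.states:
            assert np.allclose(st_.N[lateral], params.N_bar)
            assert np.allclose(st_.M[lateral], 0.0)
            assert np.allclose(st_.c[lateral], 0.0)
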