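import numpy as np
import pytest

from protoadapt.config import CellGeometry, GradientStimulus, ReceptorParams, make_fixture
from protoadapt.gradient2d import (
    apply_laplacian,
    boundary_activity,
    build_disk_mesh,
    dipole_moment,
    dipole_series,
    harmonic_extension,
    polarization,
    simulate_gradient,
)


@pytest.fixture(scope="module")
def fig8_run():
    cfg = make_fixture("fig8_gradient")
    mesh = build_disk_mesh(cfg.geometry.radius, cfg.solver.n_r, cfg.solver.n_theta)
    t_grid = np.arange(0.0, 3.0 + 1e-9, cfg.solver.dt)
    series = simulate_gradient(
        mesh,
        cfg.stimulus,
        cfg.diffusion.D_ligand,
        cfg.diffusion.permeability,
        t_grid,
        bc_mode="dirichlet",
        probe_rho=cfg.geometry.rho,
    )
    return cfg, mesh, series


class TestMesh:
    def test_boundary_nodes_sit_on_the_circle(self):
        mesh = build_disk_mesh(5.0, 20, 64)
        x, y = mesh.node_positions()
        r_bnd = np.hypot(x[mesh.boundary_indices], y[mesh.boundary_indices])
        assert np.allclose(r_bnd, 5.0, atol=1e-12)
        assert len(mesh.boundary_indices) == 64

    def test_node_count_grows_with_resolution(self):
        assert build_disk_mesh(5.0, 40, 96).n_nodes > build_disk_mesh(5.0, 20, 64).n_nodes

    def test_degenerate_resolution_rejected(self):
        with pytest.raises(ValueError):
            build_disk_mesh(5.0, 40, 8)

    def test_discrete_laplacian_annihilates_linear_fields(self):
        mesh = build_disk_mesh(5.0, 40, 96)
        x, y = mesh.node_positions()
        for field in (0.5 + 0.1 * x, 1.0 - 0.07 * y):
            lap = apply_laplacian(mesh, field)
            assert np.max(np.abs(lap)) < 1e-2


class TestSimulation:
    def test_uniform_stimulus_stays_constant_with_zero_dipole(self):
        mesh = build_disk_mesh(5.0, 20, 64)
        stim = GradientStimulus(c_init=0.5, c_rear=0.5, c_front=0.5)
        t = np.arange(0.0, 0.2, 2e-3)
        series = simulate_gradient(mesh, stim, 10.0, 200.0, t, probe_rho=0.9)
        assert np.max(np.abs(series.snapshots[-1].u - 0.5)) < 1e-10
        geom = CellGeometry(5.0, 0.5)
        dip = dipole_series(series, geom, ReceptorParams())
        assert np.max(np.abs(dip.P)) < 1e-12

    def test_steady_field_matches_harmonic_extension(self, fig8_run):
        cfg, mesh, series = fig8_run
        u_ha = harmonic_extension(mesh, cfg.stimulus)
        rel = np.max(np.abs(series.snapshots[-1].u - u_ha)) / np.max(np.abs(u_ha))
        assert rel < 1e-3

    def test_interior_relaxes_monotonically_toward_the_gradient(self, fig8_run):
        cfg, mesh, series = fig8_run
        # front probe concentration rises with time, rear falls
        front = series.probe_u[:, 0]
        rear = series.probe_u[:, mesh.n_theta // 2]
        assert front[-1] > front[0] and rear[-1] < rear[0]

    def test_robin_approaches_dirichlet_for_large_permeability(self):
        cfg = make_fixture("fig8_gradient")
        mesh = build_disk_mesh(5.0, 20, 64)
        t = np.arange(0.0, 3.0, 5e-3)
        dir_run = simulate_gradient(mesh, cfg.stimulus, 10.0, 1.0, t, "dirichlet", 0.9)
        rob_run = simulate_gradient(mesh, cfg.stimulus, 10.0, 1e6, t, "robin", 0.9)
        assert np.max(np.abs(dir_run.snapshots[-1].u - rob_run.snapshots[-1].u)) < 1e-3

    def test_finite_permeability_slows_equilibration(self):
        cfg = make_fixture("fig8_gradient")
        mesh = build_disk_mesh(5.0, 20, 64)
        t = np.arange(0.0, 1.0, 5e-3)
        fast = simulate_gradient(mesh, cfg.stimulus, 10.0, 1e6, t, "robin", 0.9)
        slow = simulate_gradient(mesh, cfg.stimulus, 10.0, 1.0, t, "robin", 0.9)
        # with a less permeable membrane the probe field lags farther behind
        u_ha = harmonic_extension(mesh, cfg.stimulus)
        err_fast = np.max(np.abs(fast.snapshots[-1].u - u_ha))
        err_slow = np.max(np.abs(slow.snapshots[-1].u - u_ha))
        assert err_slow > err_fast


class TestActivityAndDipole:
    def test_uniform_equilibrated_field_gives_adapted_activity(self):
        mesh = build_disk_mesh(5.0, 20, 64)
        stim = GradientStimulus(c_init=0.5, c_rear=0.5, c_front=0.5)
        t = np.arange(0.0, 0.2, 2e-3)
        series = simulate_gradient(mesh, stim, 10.0, 200.0, t, probe_rho=0.9)
        a = boundary_activity(series.snapshots[-1], CellGeometry(5.0, 0.5), ReceptorParams())
        assert np.allclose(a, 0.5, atol=1e-9)

    def test_dipole_of_linear_activity_ring_closed_form(self):
        # a(x) = a* + k x on a fine ring: P -> k R / 2
        n = 4096
        theta = np.arange(n) * 2 * np.pi / n
        R, k, a_star = 5.0, 0.01, 0.5
        x = R * np.cos(theta)
        P = dipole_moment(a_star + k * x, x, R, a_star)
        assert P == pytest.approx(k * R / 2, rel=1e-6)

    def test_empty_boundary_rejected(self):
        with pytest.raises(ValueError):
            dipole_moment(np.array([]), np.array([]), 5.0, 0.5)

    def test_front_rear_asymmetry_right_after_onset(self, fig8_run):
        cfg, mesh, series = fig8_run
        a0 = boundary_activity(series.snapshots[0], cfg.geometry, cfg.receptor)
        assert abs(a0[0] - a0[mesh.n_theta // 2]) > 0.1

    def test_transient_dipole_decays_while_polarization_persists(self, fig8_run):
        cfg, mesh, series = fig8_run
        dip = dipole_series(series, cfg.geometry, cfg.receptor)
        peak = np.max(np.abs(dip.P))
        steady = abs(dip.P[-1])
        assert peak > 10 * steady
        assert steady < 1e-3 * peak
        assert dip.polarization[-1] > 0.1

    def test_polarization_zero_for_uniform_field(self):
        mesh = build_disk_mesh(5.0, 20, 64)
        stim = GradientStimulus(c_init=0.5, c_rear=0.5, c_front=0.5)
        t = np.arange(0.0, 0.1, 2e-3)
        series = simulate_gradient(mesh, stim, 10.0, 200.0, t, probe_rho=0.9)
        assert polarization(series.snapshots[-1], CellGeometry(5.0, 0.5)) == pytest.approx(0.0)

    def test_mesh_refinement_changes_dipole_by_under_two_percent(self):
        cfg = make_fixture("fig8_gradient")
        t = np.arange(0.0, 1.5, 5e-3)
        runs = []
        for n_r, n_th in [(20, 48), (40, 96)]:
            mesh = build_disk_mesh(5.0, n_r, n_th)
            s = simulate_gradient(mesh, cfg.stimulus, 10.0, 200.0, t, "dirichlet", 0.9)
            runs.append(dipole_series(s, CellGeometry(5.0, 0.5), cfg.receptor).P)
        scale = np.max(np.abs(runs[1]))
        assert np.max(np.abs(runs[0] - runs[1])) < 0.02 * scale
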