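"""Assembly, dark steady state, Wilson-theta stepping and SPR runs."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from rodspr.cascade import PhotoisomerizationEvent
from rodspr.geometry import (
    MeshResolution,
    ROSGeometry,
    build_effective_medium,
    build_mesh,
)
from rodspr.params import CascadeParams, ParameterError
from rodspr.solver import (
    SimulationConfig,
    SPRSolver,
    StepSizeError,
    assemble_system,
    dark_current_two_ways,
    dark_steady_state,
    step_wilson_theta,
)


@pytest.fixture(scope="module")
def small_ops(small_geom, small_mesh):
    return assemble_system(small_mesh, build_effective_medium(small_geom))


class TestAssembly:
    def test_stiffness_annihilates_constants(self, small_ops):
        c = np.ones(small_ops.n_nodes)
        assert np.max(np.abs(small_ops.K_geom @ c)) < 1e-10

    def test_stiffness_symmetric_psd(self, small_ops):
        K = small_ops.K_geom
        assert abs(K - K.T).max() < 1e-12
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=K.shape[0])
            assert x @ (K @ x) >= -1e-10

    def test_total_capacity_matches_homogenized_volume(self, small_geom, small_ops):
        """Mass-matrix total = eps0 * (meshed cross-section area) * L plus
        the concentrated shell/incisure capacities; approaches the ideal
        cylinder volume as the polygon fills the circle (within 1% at this
        resolution, after adding the surface capacities)."""
        em = build_effective_medium(small_geom)
        mesh = small_ops.mesh
        area = mesh.disk.triangle_areas().sum()
        L = small_geom.length
        rim_len = len(mesh.disk.rim_nodes) * 2 * small_geom.radius * math.sin(
            math.pi / len(mesh.disk.rim_nodes)
        )
        expect = em.cytosol_volume_fraction * area * L + em.shell_capacity * rim_len * L
        for line, sig in zip(mesh.disk.incisure_node_lines, em.incisure_capacities):
            seg = np.abs(np.diff(mesh.disk.node_r[line]))
            expect += sig * seg.sum() * L
        assert small_ops.total_capacity() == pytest.approx(expect, rel=1e-6)
        ideal = em.cytosol_volume_fraction * math.pi * small_geom.radius**2 * L
        assert small_ops.M_cap.sum() == pytest.approx(ideal, rel=0.06)

    def test_axial_relaxation_matches_analytic_rate(self, small_geom, small_ops):
        """Manufactured solution: a cos(pi z / L) axial mode relaxes at
        rate D_eff (pi/L)^2 where D_eff is the conduit share of the total
        capacity -- the 1-D problem hidden in the 3-D operator."""
        em = build_effective_medium(small_geom)
        mesh = small_ops.mesh
        L = small_geom.length
        nd = mesh.disk.n_nodes
        z = np.repeat(mesh.z_layers, nd)
        y0 = np.cos(math.pi * z / L)
        D = 0.08
        # conduit capacity per unit length (shell + incisures), axially mobile
        rim_len = len(mesh.disk.rim_nodes) * 2 * small_geom.radius * math.sin(
            math.pi / len(mesh.disk.rim_nodes)
        )
        cond = em.shell_capacity * rim_len
        for line, sig in zip(mesh.disk.incisure_node_lines, em.incisure_capacities):
            cond += sig * np.abs(np.diff(mesh.disk.node_r[line])).sum()
        cap_tot = small_ops.total_capacity() / L
        lam = D * (cond / cap_tot) * (math.pi / L) ** 2
        dt = 20.0
        y = y0.copy()
        for _ in range(50):
            y = step_wilson_theta(
                y, dt, 1.0, small_ops.M_cap, D * small_ops.K_geom,
                lambda yy: np.zeros_like(yy), tol=1e-10,
            )
        # amplitude of the mode after 1000 ms
        amp = (y * y0 * small_ops.lumped_cap).sum() / (y0 * y0 * small_ops.lumped_cap).sum()
        assert amp == pytest.approx(math.exp(-lam * 50 * dt), rel=0.04)

    def test_mass_conservation_under_pure_diffusion(self, small_ops):
        rng = np.random.default_rng(1)
        y = 1.0 + 0.3 * rng.random(small_ops.n_nodes)
        total0 = small_ops.lumped_cap @ y
        for _ in range(50):
            y = step_wilson_theta(
                y, 10.0, 1.37, small_ops.M_cap, 0.1 * small_ops.K_geom,
                lambda yy: np.zeros_like(yy), tol=1e-12,
            )
        drift = abs(small_ops.lumped_cap @ y - total0) / abs(total0)
        assert drift < 1e-6


class TestDarkSteadyState:
    def test_two_current_routes_agree(self, salamander):
        _, p = salamander
        a, b = dark_current_two_ways(p)
        assert a == pytest.approx(b, rel=1e-10)

    def test_bicarbonate_like_cyclase_boost_raises_dark_current(self, salamander):
        _, p = salamander
        boosted = p.with_updates(alpha_min=p.alpha_min * 1.13, alpha_max=p.alpha_max * 2)
        assert dark_steady_state(boosted).j_dark > dark_steady_state(p).j_dark

    def test_doubling_hydrolysis_halves_cgmp_at_frozen_synthesis(self, salamander):
        _, p = salamander
        ds = dark_steady_state(p)
        synthesis = p.cyclase_rate(ds.ca0)  # frozen feedback
        assert synthesis / (2 * p.beta_dark) == pytest.approx(ds.cg0 / 2)

    def test_inconsistent_parameters_raise(self, salamander):
        _, p = salamander
        bad = p.with_updates(J_ex_sat=1e-6)  # exchanger cannot balance influx
        with pytest.raises(ParameterError):
            dark_steady_state(bad)

    def test_uniform_dark_state_is_discrete_equilibrium(self, small_geom):
        """Time-stepping from the dark state drifts < 0.1% over 5 s."""
        p = CascadeParams()
        res = MeshResolution(n_radial=4, n_angular=8, n_axial=4)
        geom = ROSGeometry(
            radius=small_geom.radius, length=small_geom.length,
            disk_thickness=small_geom.disk_thickness,
            interdisk_gap=small_geom.interdisk_gap, n_disks=small_geom.n_disks,
            incisures=(), species_tag="drift",
        )
        s = SPRSolver(geom, p, res)
        cfg = SimulationConfig(dt=50.0, t_end=5000.0)
        tr = s.run(cfg, None)
        assert np.max(np.abs(tr.r)) < 1e-3 * s.dark.j_dark


class TestWilsonTheta:
    def test_zero_forcing_uniform_field_unchanged(self, small_ops):
        y = np.full(small_ops.n_nodes, 3.0)
        y1 = step_wilson_theta(
            y, 5.0, 1.37, small_ops.M_cap, 0.1 * small_ops.K_geom,
            lambda yy: np.zeros_like(yy),
        )
        assert np.allclose(y1, y, atol=1e-12)

    @pytest.mark.parametrize("theta", [1.0, 1.37])
    def test_linear_decay_accuracy_improves_with_dt(self, theta):
        """Scalar decay y' = -k y: the scheme is first-order accurate for
        theta >= 1, so halving dt cuts the error at t = 1/k by a factor
        approaching 2 (allow 1.8 at these step sizes), and the per-step
        (local) error is O(dt^2)."""
        k = 1.0
        M = sp.identity(1, format="csr")
        K = k * sp.identity(1, format="csr")
        errs = []
        for dt in (0.2, 0.1, 0.05):
            y = np.array([1.0])
            n = int(round(1.0 / dt))
            for _ in range(n):
                y = step_wilson_theta(y, dt, theta, M, K, lambda yy: np.zeros(1))
            errs.append(abs(y[0] - math.exp(-1.0)))
        assert errs[0] / errs[1] >= 1.8
        assert errs[1] / errs[2] >= 1.8
        # local truncation error after one step is O(dt^2)
        loc = []
        for dt in (0.1, 0.05):
            y = step_wilson_theta(np.array([1.0]), dt, theta, M, K,
                                  lambda yy: np.zeros(1))
            loc.append(abs(y[0] - math.exp(-dt)))
        assert loc[0] / loc[1] >= 3.0

    def test_nonconvergent_picard_raises(self):
        M = sp.identity(1, format="csr")
        K = sp.identity(1, format="csr")
        # violently amplifying forcing cannot reach a fixed point
        with pytest.raises(StepSizeError):
            step_wilson_theta(
                np.array([1.0]), 1.0, 1.0, M, K,
                lambda yy: -50.0 * yy + 100.0 * np.sign(yy - 0.99), max_iters=10,
            )


class TestRunSPR:
    def test_no_photoisomerization_gives_flat_trace(self, small_geom):
        p = CascadeParams()
        s = SPRSolver(small_geom, p, MeshResolution(4, 8, 4))
        tr = s.run(SimulationConfig(dt=20.0, t_end=500.0), None)
        assert np.max(np.abs(tr.r)) < 1e-6 * s.dark.j_dark

    def test_deterministic_mode_bitwise_reproducible(self, small_geom):
        p = CascadeParams()
        cfg = SimulationConfig(dt=20.0, t_end=800.0)
        ev = PhotoisomerizationEvent(small_geom.n_disks // 2, 0.0, 0.3)
        r = []
        for _ in range(2):
            s = SPRSolver(small_geom, p, MeshResolution(4, 8, 4))
            r.append(s.run(cfg, ev).r)
        assert np.array_equal(r[0], r[1])

    def test_stochastic_mode_reproducible_per_seed(self, small_geom):
        from rodspr.solver import run_spr

        p = CascadeParams()
        ev = PhotoisomerizationEvent(small_geom.n_disks // 2, 0.5, 0.3)
        cfg = SimulationConfig(
            dt=20.0, t_end=800.0, mode="stochastic", n_trials=2, seed=5
        )
        m1, t1 = run_spr(cfg, small_geom, p, ev, MeshResolution(4, 8, 4))
        m2, t2 = run_spr(cfg, small_geom, p, ev, MeshResolution(4, 8, 4))
        assert np.array_equal(m1.r, m2.r)
        assert len(t1) == 2

    def test_fields_stay_nonnegative(self, small_geom):
        p = CascadeParams(k_hyd=5e-3)
        s = SPRSolver(small_geom, p, MeshResolution(4, 8, 4))
        ev = PhotoisomerizationEvent(small_geom.n_disks // 2, 0.0, 0.3)
        cfg = SimulationConfig(dt=20.0, t_end=1500.0)
        tr = s.run(cfg, ev)  # raises StepSizeError on persistent negativity
        assert np.all(np.isfinite(tr.r))
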