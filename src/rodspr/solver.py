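"""Homogenized cGMP/Ca2+ reaction-diffusion solver on the simplified ROS.

Model
-----
After homogenization the two cytosolic fields obey, on the cylinder
``0 <= r <= R, 0 <= z <= L``:

* interior: capacity ``eps0`` (cytosol volume fraction) with *transversal*
  diffusion only -- the disk stack blocks axial diffusion in the interior;
* outer shell (``r = R``): concentrated capacity ``sigma_R`` carrying full
  two-dimensional diffusion in ``(phi, z)``;
* each incisure: a vertical rectangle of capacity ``sigma_in`` carrying
  diffusion in ``(r, z)``;
* cGMP: synthesis ``alpha(Ca)`` (Ca-inhibited cyclase) minus dark hydrolysis
  ``beta_dark * cg`` on every cytosolic capacity, plus the light-activated
  sink ``k_hyd * E* * cg`` concentrated on the photoisomerized disk
  cross-section;
* Ca2+: entry through CNG channels (fraction ``f_Ca`` of the local CNG
  current) and extrusion by the Na+/Ca2+,K+ exchanger, both as surface
  sources on the shell; fast buffering scales Ca accumulation by ``B_Ca``.

The observable is the circulating current ``J(t) = J_CNG + J_ex`` computed
from the shell-local fields; responses are reported as the positive
suppression ``r(t) = J_dark - J(t)``.

Discretization: P1 triangles on the cross-section extruded into 6-node
prisms (triangle x linear-in-z tensor basis), with the shell/incisure
rectangles conforming to prism faces; time integration by the Wilson-theta
method (collocation at ``t + theta*dt``, ``theta >= 1``) with Picard
iteration on the nonlinear forcing and step rejection + dt halving if a
field would go negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.sparse.linalg import splu

from .cascade import (
    PhotoisomerizationEvent,
    SurfaceActivation,
    deterministic_rstar,
    sample_rstar,
    solve_surface_activation,
    triangle_mass_stiffness,
)
from .geometry import (
    EffectiveMedium,
    Mesh,
    MeshResolution,
    ROSGeometry,
    build_disk_triangulation,
    build_effective_medium,
    build_mesh,
    default_resolution,
)
from .params import CascadeParams, ParameterError
from .trace import ResponseTrace, mean_trace
from .units import PA_TO_FLUX_1, PA_TO_FLUX_2


class SolverError(RuntimeError):
    pass


class StepSizeError(SolverError):
    """Inner iteration failed to converge even after dt reductions."""


@dataclass
class FieldState:
    """Nodal fields at one time point: cg, ca (uM) and time (ms)."""

    cg: np.ndarray
    ca: np.ndarray
    t: float

    def copy(self) -> "FieldState":
        return FieldState(self.cg.copy(), self.ca.copy(), self.t)


@dataclass(frozen=True)
class SimulationConfig:
    """Time integration settings for SPR simulations.

    ``theta >= 1`` selects the unconditionally stable Wilson-theta regime;
    ``mode`` is 'deterministic' (exponential R*, fixed event) or
    'stochastic' (CTMC R* shutoff and, when events are sampled, random
    positions).  ``n_trials`` applies to stochastic mode.
    """

    dt: float = 5.0
    theta: float = 1.37
    fixed_point_tol: float = 1.0e-8
    max_inner_iters: int = 50
    mode: str = "deterministic"
    n_trials: int = 1
    seed: int = 0
    t_end: float = 5000.0

    def __post_init__(self) -> None:
        if self.theta < 1.0:
            raise ParameterError("theta must be >= 1 for unconditional stability")
        if self.dt <= 0 or self.fixed_point_tol <= 0 or self.t_end <= 0:
            raise ParameterError("dt, tolerance and t_end must be positive")
        if self.mode not in ("deterministic", "stochastic"):
            raise ParameterError("mode must be 'deterministic' or 'stochastic'")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _line_mass_stiffness(lengths: np.ndarray, n_nodes: int, edges: np.ndarray):
    """Consistent P1 mass/stiffness of a 1-D chain given edge lengths and
    the (i, j) node pairs of each edge."""
    rows, cols, mv, kv = [], [], [], []
    for (i, j), h in zip(edges, lengths):
        for a, b, m, k in (
            (i, i, h / 3.0, 1.0 / h),
            (j, j, h / 3.0, 1.0 / h),
            (i, j, h / 6.0, -1.0 / h),
            (j, i, h / 6.0, -1.0 / h),
        ):
            rows.append(a)
            cols.append(b)
            mv.append(m)
            kv.append(k)
    M = sp.csr_matrix((mv, (rows, cols)), shape=(n_nodes, n_nodes))
    K = sp.csr_matrix((kv, (rows, cols)), shape=(n_nodes, n_nodes))
    return M, K


@dataclass
class Operators:
    """Assembled capacity/stiffness operators and boundary maps.

    ``M_cap`` is the total cytosolic capacity (volume + shell + incisures);
    multiplied by a diffusivity, ``K_geom`` is the full stiffness.  Both are
    symmetric; ``K_geom @ const = 0``.
    """

    mesh: Mesh
    medium: EffectiveMedium
    M_cap: sp.csr_matrix
    K_geom: sp.csr_matrix
    lumped_cap: np.ndarray        # row sums of M_cap (um^3 per node)
    shell_area: np.ndarray        # lumped plasma-membrane area per node (um^2)
    total_shell_area: float
    disk_lumped_area: np.ndarray  # lumped triangle areas of the cross-section
    M_tri: sp.csr_matrix          # cross-section mass (for plane augmentation)
    K_tri: sp.csr_matrix          # cross-section stiffness

    @property
    def n_nodes(self) -> int:
        return self.M_cap.shape[0]

    def total_capacity(self) -> float:
        return float(self.lumped_cap.sum())


def assemble_system(mesh: Mesh, medium: EffectiveMedium) -> Operators:
    """Mass/stiffness assembly on the extruded prism mesh.

    The tensor structure (triangle basis x linear axial basis) lets every
    block be written as a Kronecker product of cross-sectional and axial 1-D
    matrices; shell and incisure contributions are 1-D chains (rim polygon,
    radial lines) extruded the same way, which makes conformity with prism
    faces automatic.
    """
    mesh.conformity_check()
    disk = mesh.disk
    nd = disk.n_nodes
    nz = len(mesh.z_layers) - 1
    hz = mesh.z_layers[1] - mesh.z_layers[0]

    M_tri, K_tri = triangle_mass_stiffness(disk)
    edges_z = np.column_stack([np.arange(nz), np.arange(1, nz + 1)])
    M_z, K_z = _line_mass_stiffness(np.full(nz, hz), nz + 1, edges_z)

    eps0 = medium.cytosol_volume_fraction
    M_cap = eps0 * sp.kron(M_z, M_tri)
    K_geom = eps0 * sp.kron(M_z, K_tri)

    # shell: closed rim polygon x z
    rim = disk.rim_nodes
    n_a = len(rim)
    chord = 2.0 * mesh.geom.radius * math.sin(math.pi / n_a)
    rim_edges = np.column_stack([rim, np.roll(rim, -1)])
    M_rim, K_rim = _line_mass_stiffness(np.full(n_a, chord), nd, rim_edges)
    sig_R = medium.shell_capacity
    M_cap = M_cap + sig_R * sp.kron(M_z, M_rim)
    K_geom = K_geom + sig_R * (sp.kron(M_z, K_rim) + sp.kron(K_z, M_rim))

    # incisures: radial node lines x z
    for line, sig in zip(disk.incisure_node_lines, medium.incisure_capacities):
        seg = np.column_stack([line[:-1], line[1:]])
        seg_len = np.abs(disk.node_r[line[1:]] - disk.node_r[line[:-1]])
        M_l, K_l = _line_mass_stiffness(seg_len, nd, seg)
        M_cap = M_cap + sig * sp.kron(M_z, M_l)
        K_geom = K_geom + sig * (sp.kron(M_z, K_l) + sp.kron(K_z, M_l))

    M_cap = M_cap.tocsr()
    K_geom = K_geom.tocsr()

    lumped_cap = np.asarray(M_cap.sum(axis=1)).ravel()
    # plasma-membrane (shell surface) lumped areas
    z_w = np.asarray(M_z.sum(axis=1)).ravel()  # hz/2 at ends, hz inside
    rim_w = np.zeros(nd)
    rim_w[rim] = chord
    shell_area = np.kron(z_w, rim_w)
    disk_lumped = np.asarray(M_tri.sum(axis=1)).ravel()
    return Operators(
        mesh=mesh,
        medium=medium,
        M_cap=M_cap,
        K_geom=K_geom,
        lumped_cap=lumped_cap,
        shell_area=shell_area,
        total_shell_area=float(shell_area.sum()),
        disk_lumped_area=disk_lumped,
        M_tri=M_tri,
        K_tri=K_tri,
    )


# ---------------------------------------------------------------------------
# dark steady state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DarkState:
    cg0: float   # uM
    ca0: float   # uM
    j_cng: float  # pA
    j_ex: float   # pA

    @property
    def j_dark(self) -> float:
        return self.j_cng + self.j_ex


def dark_steady_state(params: CascadeParams) -> DarkState:
    """Spatially uniform dark equilibrium.

    Solves cyclase/hydrolysis balance ``alpha(ca0) = beta_dark * cg0``
    jointly with the Ca2+ flux balance ``f_Ca * J_CNG / 2 = J_ex`` (in ion
    units the CNG channel carries 2 charges per Ca2+, the exchanger one net
    charge per extruded Ca2+).  The uniform state is an exact equilibrium of
    the discretized system, so simulations started from it stay flat.
    """

    def mismatch(ca: float) -> float:
        cg = params.cyclase_rate(ca) / params.beta_dark
        j_cng = params.J_cng_sat * params.cng_open_fraction(cg)
        required = 0.5 * params.f_Ca * j_cng        # pA the exchanger must carry
        return params.J_ex_sat * params.exchanger_saturation(ca) - required

    lo, hi = 1e-6, 1e3
    if mismatch(lo) > 0 or mismatch(hi) < 0:
        raise ParameterError(
            "no positive dark steady state for these parameters "
            "(exchanger cannot balance the CNG Ca2+ influx)"
        )
    ca0 = brentq(mismatch, lo, hi, xtol=1e-12, rtol=1e-14)
    cg0 = float(params.cyclase_rate(ca0) / params.beta_dark)
    j_cng = float(params.J_cng_sat * params.cng_open_fraction(cg0))
    j_ex = float(params.J_ex_sat * params.exchanger_saturation(ca0))
    return DarkState(cg0=cg0, ca0=float(ca0), j_cng=j_cng, j_ex=j_ex)


def dark_current_two_ways(params: CascadeParams) -> tuple[float, float]:
    """J_dark via the channel sum and via the exchanger-implied identity
    ``J_CNG * (1 + f_Ca/2)`` -- an internal consistency check."""
    ds = dark_steady_state(params)
    return ds.j_dark, ds.j_cng * (1.0 + 0.5 * params.f_Ca)


# ---------------------------------------------------------------------------
# Wilson-theta stepping
# ---------------------------------------------------------------------------

def step_wilson_theta(y, dt, theta, M, K, forcing, *, tol=1e-8, max_iters=50, lu=None):
    """One Wilson-theta step of ``M dy/dt + K y = forcing(t_theta, y_theta)``.

    Collocates at the extended time ``t + theta*dt`` (backward difference
    over the extended step) and interpolates back to ``t + dt``; the
    nonlinear forcing is resolved by Picard iteration.  ``y`` may be a
    scalar-field vector; ``forcing`` receives the current iterate.
    Returns the new state vector.
    """
    y = np.asarray(y, dtype=float)
    h = theta * dt
    if lu is None:
        A = (M / h + K).tocsc() if sp.issparse(M) else (np.asarray(M) / h + K)
        solve = splu(A).solve if sp.issparse(M) else lambda b: np.linalg.solve(A, b)
    else:
        solve = lu.solve
    y_th = y.copy()
    base = (M @ y) / h
    for _ in range(max_iters):
        y_new = solve(base + forcing(y_th))
        denom = np.linalg.norm(y_new) or 1.0
        err = np.linalg.norm(y_new - y_th) / denom
        y_th = y_new
        if err < tol:
            break
    else:
        raise StepSizeError("Picard iteration did not converge; reduce dt")
    return y + (y_th - y) / theta


class SPRSolver:
    """Caches mesh, operators and factorizations for repeated SPR runs."""

    def __init__(
        self,
        geom: ROSGeometry,
        params: CascadeParams,
        resolution: MeshResolution | None = None,
    ):
        self.geom = geom
        self.params = params
        self.resolution = resolution or default_resolution(geom)
        self.medium = build_effective_medium(geom)
        self.mesh = build_mesh(geom, self.resolution)
        self.ops = assemble_system(self.mesh, self.medium)
        self.surface_mesh = build_disk_triangulation(
            geom, self.resolution, slit_incisures=True
        )
        self.dark = dark_steady_state(params)
        self._lu_cache: dict[tuple[str, float, int | None], object] = {}
        self._plane_cache: dict[int, tuple[sp.csr_matrix, sp.csr_matrix]] = {}
        self._sink_lu: tuple | None = None
        self._cap_scale = np.maximum(
            np.asarray(self.ops.M_cap.diagonal()).ravel(), 1e-12
        )
        # exchanger conductance linearized at the dark state, kept on the
        # Ca LHS so the Picard iteration stays contractive at large dt
        p, ds = self.params, self.dark
        slope = p.K_ex / (ds.ca0 + p.K_ex) ** 2
        self._g_ex = (
            self.ops.shell_area
            * (p.J_ex_sat / self.ops.total_shell_area)
            * slope
            * PA_TO_FLUX_1
        )

    # -- helpers --------------------------------------------------------
    def _plane_matrices(self, layer: int | None):
        """Capacity/stiffness including the activated cross-section, whose
        two adjacent interdiskal gaps form a concentrated quasi-2-D layer."""
        if layer is None:
            return self.ops.M_cap, self.ops.K_geom
        if layer not in self._plane_cache:
            nl = len(self.mesh.z_layers)
            sel = sp.csr_matrix(
                (np.ones(1), ([layer], [layer])), shape=(nl, nl)
            )
            sig = self.medium.activated_disk_capacity
            M = (self.ops.M_cap + sig * sp.kron(sel, self.ops.M_tri)).tocsr()
            K = (self.ops.K_geom + sig * sp.kron(sel, self.ops.K_tri)).tocsr()
            self._plane_cache[layer] = (M, K)
        return self._plane_cache[layer]

    def _lu(self, which: str, h: float, layer: int | None):
        key = (which, h, layer)
        if key not in self._lu_cache:
            p = self.params
            M, K = self._plane_matrices(layer)
            if which == "cg":
                A = M / h + p.D_cG * K + p.beta_dark * M
            else:
                A = p.B_Ca * M / h + p.D_Ca * K + sp.diags(self._g_ex)
            # symmetric-structure ordering: ~2x faster back-solves here
            self._lu_cache[key] = splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A")
        return self._lu_cache[key]

    def _lu_cg_sink(self, h: float, layer: int | None, sink: np.ndarray):
        """cg factorization carrying a snapshot of the hydrolysis sink.

        The light-driven sink is stiff relative to the nodal capacities at
        the activated plane, so leaving it entirely to Picard iteration
        forces tiny time steps.  Instead the factorized LHS includes a
        recent snapshot of the (diagonal) sink; only the drift since the
        snapshot is iterated, which stays strongly contractive.  The
        snapshot is refreshed whenever the drift-to-capacity ratio grows.
        """
        cache = self._sink_lu
        if cache is not None:
            h0, layer0, s_ref, lu = cache
            if h0 == h and layer0 == layer:
                drift = np.max(np.abs(sink - s_ref) * h / self._cap_scale)
                if drift < 0.2:
                    return s_ref, lu
        p = self.params
        M, K = self._plane_matrices(layer)
        A = M / h + p.D_cG * K + p.beta_dark * M + sp.diags(sink)
        lu = splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A")
        self._sink_lu = (h, layer, sink.copy(), lu)
        return sink, lu

    def currents(self, cg: np.ndarray, ca: np.ndarray) -> tuple[float, float]:
        """Whole-cell CNG and exchanger currents (pA) from shell fields."""
        p = self.params
        w = self.ops.shell_area / self.ops.total_shell_area
        j_cng = p.J_cng_sat * float(w @ p.cng_open_fraction(cg))
        j_ex = p.J_ex_sat * float(w @ p.exchanger_saturation(ca))
        return j_cng, j_ex

    def _ca_surface_source(self, cg: np.ndarray, ca: np.ndarray) -> np.ndarray:
        """Nodal Ca2+ source (uM*um^3/ms) from shell membrane fluxes."""
        p = self.params
        a = self.ops.shell_area
        dens_cng = p.J_cng_sat / self.ops.total_shell_area * p.cng_open_fraction(cg)
        dens_ex = p.J_ex_sat / self.ops.total_shell_area * p.exchanger_saturation(ca)
        return a * (p.f_Ca * dens_cng * PA_TO_FLUX_2 - dens_ex * PA_TO_FLUX_1)

    def _sink_weights(self, activation: SurfaceActivation, t: float) -> np.ndarray:
        """Hydrolysis weights k_hyd * integral(E*) per base disk node."""
        e = activation.at(t)
        w_slit = e * activation.lumped_area
        w = np.zeros(self.mesh.disk.n_nodes)
        np.add.at(w, self.surface_mesh.slit_parent, w_slit)
        return self.params.k_hyd * w

    # -- main time loop -------------------------------------------------
    def run(
        self,
        config: SimulationConfig,
        event: PhotoisomerizationEvent | None,
        activation: SurfaceActivation | None = None,
    ) -> ResponseTrace:
        """Integrate one SPR and return the photocurrent suppression trace."""
        p = self.params
        ops = self.ops
        nd = self.mesh.disk.n_nodes
        n = ops.n_nodes
        state = FieldState(
            cg=np.full(n, self.dark.cg0), ca=np.full(n, self.dark.ca0), t=0.0
        )
        layer_slice = None
        layer = None
        if event is not None:
            event.validate(self.geom)
            z_ev = self.geom.disk_z(event.disk_index)
            layer = self.mesh.layer_of(z_ev)
            layer_slice = slice(layer * nd, (layer + 1) * nd)
            if activation is None:
                if event.rstar_trajectory is None:
                    event = replace(event, rstar_trajectory=deterministic_rstar(p.rstar))
                t_act = np.arange(
                    0.0,
                    config.t_end + (config.theta + 1.0) * config.dt,
                    config.dt,
                )
                activation = solve_surface_activation(
                    event, p.activation(), self.surface_mesh, t_act
                )

        out_t = np.arange(0.0, config.t_end + 0.5 * config.dt, config.dt)
        rec_t = [0.0]
        j0 = sum(self.currents(state.cg, state.ca))
        rec_j = [j0]

        dt = config.dt
        theta = config.theta
        min_dt = config.dt / 64.0
        t = 0.0
        good_steps = 0
        delta = None  # previous step increment, for warm-starting Picard
        while t < config.t_end - 1e-9:
            dt_eff = min(dt, config.t_end - t)
            try:
                new = self._advance(
                    state, dt_eff, theta, config, activation, layer_slice, layer,
                    warm=delta,
                )
            except StepSizeError:
                new = None
            if new is None or new.cg.min() < 0.0 or new.ca.min() < 0.0:
                dt = dt / 2.0
                good_steps = 0
                delta = None
                if dt < min_dt:
                    raise StepSizeError(
                        "step size underflow: inner iteration failed or "
                        f"negativity persisted at t={t:.1f} ms"
                    )
                continue
            delta = (new.cg - state.cg, new.ca - state.ca, dt_eff)
            state = new
            t = state.t
            rec_t.append(t)
            rec_j.append(sum(self.currents(state.cg, state.ca)))
            good_steps += 1
            if dt < config.dt and good_steps >= 4:
                dt = min(config.dt, dt * 2.0)
                good_steps = 0

        j = np.interp(out_t, np.array(rec_t), np.array(rec_j))
        r = self.dark.j_dark - j
        meta = {
            "mode": config.mode,
            "theta": theta,
            "dt": config.dt,
            "mesh": self.mesh.element_counts(),
        }
        if event is not None:
            meta["event"] = {
                "disk_index": event.disk_index,
                "radial_position": event.radial_position,
                "angular_position": event.angular_position,
            }
        return ResponseTrace(out_t, r, j_dark=self.dark.j_dark, meta=meta)

    def _advance(self, state, dt, theta, config, activation, layer_slice, layer,
                 warm=None):
        """One accepted Wilson-theta step of the coupled cg/ca system."""
        p = self.params
        ops = self.ops
        h = theta * dt
        t_th = state.t + h
        lu_ca = self._lu("ca", h, layer)
        M_run, _ = self._plane_matrices(layer)
        sink = None
        sink_ref = None
        if activation is not None:
            sink_disk = self._sink_weights(activation, t_th)  # per disk node
            sink = np.zeros(ops.n_nodes)
            sink[layer_slice] = sink_disk
            sink_ref, lu_cg = self._lu_cg_sink(h, layer, sink)
        else:
            lu_cg = self._lu("cg", h, layer)
        if warm is not None and warm[2] > 0:
            # extrapolate the previous increment to the collocation point
            scale = h / warm[2]
            cg_th = state.cg + scale * warm[0]
            ca_th = state.ca + scale * warm[1]
        else:
            cg_th = state.cg.copy()
            ca_th = state.ca.copy()
        base_cg = M_run @ state.cg / h
        base_ca = p.B_Ca * (M_run @ state.ca) / h
        for _ in range(config.max_inner_iters):
            rhs = base_cg + M_run @ p.cyclase_rate(ca_th)
            if sink is not None:
                rhs = rhs - (sink - sink_ref) * cg_th
            cg_new = lu_cg.solve(rhs)
            ca_new = lu_ca.solve(
                base_ca
                + self._ca_surface_source(cg_new, ca_th)
                + self._g_ex * ca_th
            )
            err = max(
                np.max(np.abs(cg_new - cg_th)) / (np.max(np.abs(cg_new)) or 1.0),
                np.max(np.abs(ca_new - ca_th)) / (np.max(np.abs(ca_new)) or 1.0),
            )
            cg_th, ca_th = cg_new, ca_new
            if err < config.fixed_point_tol:
                break
        else:
            raise StepSizeError("fixed-point iteration exhausted its budget")
        cg1 = state.cg + (cg_th - state.cg) / theta
        ca1 = state.ca + (ca_th - state.ca) / theta
        return FieldState(cg1, ca1, state.t + dt)


def run_spr(
    config: SimulationConfig,
    geom: ROSGeometry,
    params: CascadeParams,
    event: PhotoisomerizationEvent | None,
    resolution: MeshResolution | None = None,
    solver: SPRSolver | None = None,
    events: list[PhotoisomerizationEvent] | None = None,
) -> ResponseTrace | tuple[ResponseTrace, list[ResponseTrace]]:
    """Simulate single photon responses.

    Deterministic mode runs the given event once (with an exponential R*
    trajectory unless the event carries its own).  Stochastic mode runs
    ``config.n_trials`` trials, each with a CTMC-sampled R* shutoff; per
    trial either the fixed ``event`` position or, if ``events`` is given, a
    pre-sampled position list is used.  Returns the (mean) trace, plus the
    per-trial traces in stochastic mode.
    """
    s = solver or SPRSolver(geom, params, resolution)
    if event is None and events is None:
        return s.run(config, None)
    if config.mode == "deterministic":
        return s.run(config, event)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_trials)
    trials = []
    for i in range(config.n_trials):
        ev = events[i % len(events)] if events else event
        rng = np.random.default_rng(children[i])
        traj = sample_rstar(params.rstar, rng)
        trials.append(s.run(config, replace(ev, rstar_trajectory=traj)))
    return mean_trace(trials), trials
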