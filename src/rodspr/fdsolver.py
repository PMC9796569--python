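"""Axisymmetric finite-difference oracle for the homogenized SPR model.

An independent discretization of the same equations as
:mod:`rodspr.solver`, restricted to axisymmetric configurations (no
incisures, photoisomerization on the cylinder axis): finite volumes on a
tensor ``(r, z)`` grid, backward-Euler time stepping with Picard iteration.
Used for cross-verification -- the two solvers share no discretization
code, so agreement localizes errors to the model, not the numerics.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .cascade import PhotoisomerizationEvent
from .geometry import GeometryError, ROSGeometry, build_effective_medium
from .params import CascadeParams
from .solver import SimulationConfig, dark_steady_state
from .trace import ResponseTrace
from .units import PA_TO_FLUX_1, PA_TO_FLUX_2


class AxisymmetryError(ValueError):
    """The oracle only supports incisure-free, on-axis configurations."""


def _radial_fv(n_r: int, R: float):
    """Node radii, annular control areas and inter-node conductance weights
    of a 1-D radial finite-volume grid (node-centred, r_0 = 0, r_n = R)."""
    dr = R / n_r
    r = np.arange(n_r + 1) * dr
    area = np.zeros(n_r + 1)
    area[0] = np.pi * (dr / 2.0) ** 2
    for i in range(1, n_r):
        area[i] = np.pi * ((r[i] + dr / 2.0) ** 2 - (r[i] - dr / 2.0) ** 2)
    area[n_r] = np.pi * (R**2 - (R - dr / 2.0) ** 2)
    # conductance (per unit diffusivity) across the face between i and i+1
    g = 2.0 * np.pi * (r[:-1] + dr / 2.0) / dr
    return r, area, g


def _surface_activation_radial(
    n_r: int, R: float, params: CascadeParams, t_grid: np.ndarray, activity
) -> np.ndarray:
    """E*(r, t) for an on-axis source: radial diffusion-decay, backward Euler."""
    r, area, g = _radial_fv(n_r, R)
    n = n_r + 1
    dt = t_grid[1] - t_grid[0]
    rows, cols, vals = [], [], []
    for i in range(n_r):
        c = params.D_E * g[i]
        for a, b, v in ((i, i, c), (i + 1, i + 1, c), (i, i + 1, -c), (i + 1, i, -c)):
            rows.append(a)
            cols.append(b)
            vals.append(v)
    K = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    M = sp.diags(area)
    A = (M / dt + K + params.k_E * M).tocsc()
    lu = splu(A)
    E = np.zeros((len(t_grid), n))
    e = np.zeros(n)
    for k in range(1, len(t_grid)):
        rhs = area * e / dt
        a_mid = float(np.mean(activity(np.linspace(t_grid[k - 1], t_grid[k], 5))))
        rhs[0] += params.nu_RG * a_mid
        e = lu.solve(rhs)
        E[k] = e
    return E


def fd_oracle(
    config: SimulationConfig,
    geom: ROSGeometry,
    params: CascadeParams,
    event: PhotoisomerizationEvent | None,
    n_r: int = 24,
    n_z: int = 48,
) -> ResponseTrace:
    """Axisymmetric finite-difference simulation of an on-axis SPR.

    Grid unknowns are ``c[i, j]`` at radii ``i*dr`` and heights ``j*dz``.
    Interior nodes carry capacity ``eps0 * area_i * dz_j`` with radial
    diffusion only; rim nodes additionally carry the shell capacity
    ``sigma_R * 2 pi R * dz_j`` with axial conduction, the membrane fluxes,
    and exchange with the interior through the shared unknown.  The
    activated disk contributes a concentrated sink on its ``z`` plane.
    """
    if geom.n_incisures:
        raise AxisymmetryError("oracle requires an incisure-free geometry")
    if event is not None and event.radial_position > 1e-9:
        raise AxisymmetryError("oracle requires the photoisomerization on the axis")

    R, L = geom.radius, geom.length
    med = build_effective_medium(geom)
    eps0 = med.cytosol_volume_fraction
    sig = med.shell_capacity
    r, area, g_r = _radial_fv(n_r, R)
    dz = L / n_z
    zw = np.full(n_z + 1, dz)
    zw[0] = zw[-1] = dz / 2.0
    nrr = n_r + 1
    n = nrr * (n_z + 1)

    def idx(i, j):
        return j * nrr + i

    cap = np.zeros(n)
    shell_a = np.zeros(n)
    for j in range(n_z + 1):
        for i in range(nrr):
            cap[idx(i, j)] = eps0 * area[i] * zw[j]
        cap[idx(n_r, j)] += sig * 2.0 * np.pi * R * zw[j]
        shell_a[idx(n_r, j)] = 2.0 * np.pi * R * zw[j]
    total_shell = shell_a.sum()

    rows, cols, vals = [], [], []

    def add_edge(a, b, c):
        rows.extend([a, b, a, b])
        cols.extend([a, b, b, a])
        vals.extend([c, c, -c, -c])

    for j in range(n_z + 1):
        for i in range(n_r):
            add_edge(idx(i, j), idx(i + 1, j), eps0 * g_r[i] * zw[j])
    for j in range(n_z):
        a = idx(n_r, j)
        b = idx(n_r, j + 1)
        add_edge(a, b, sig * 2.0 * np.pi * R / dz)

    dt = config.dt
    t_grid = np.arange(0.0, config.t_end + 0.5 * dt, dt)
    j_plane = None
    E = None
    if event is not None:
        z_ev = geom.disk_z(event.disk_index)
        j_plane = int(round(z_ev / dz))
        act = event.rstar_trajectory
        if act is None:
            from .cascade import deterministic_rstar

            act = deterministic_rstar(params.rstar)
        E = _surface_activation_radial(n_r, R, params, t_grid, act)
        # activated cross-section: concentrated capacity (two adjacent
        # interdiskal gaps) with its own transversal conduction
        sig_a = med.activated_disk_capacity
        for i in range(nrr):
            cap[idx(i, j_plane)] += sig_a * area[i]
        for i in range(n_r):
            add_edge(idx(i, j_plane), idx(i + 1, j_plane), sig_a * g_r[i])
    K_unit = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    dark = dark_steady_state(params)
    cg = np.full(n, dark.cg0)
    ca = np.full(n, dark.ca0)

    M = sp.diags(cap)
    A_cg = (M / dt + params.D_cG * K_unit + params.beta_dark * M).tocsc()
    A_ca = (params.B_Ca * M / dt + params.D_Ca * K_unit).tocsc()
    lu_cg = splu(A_cg)
    lu_ca = splu(A_ca)

    def currents(cg_v, ca_v):
        w = shell_a / total_shell
        j_cng = params.J_cng_sat * float(w @ params.cng_open_fraction(cg_v))
        j_ex = params.J_ex_sat * float(w @ params.exchanger_saturation(ca_v))
        return j_cng, j_ex

    j_out = [sum(currents(cg, ca))]
    for k in range(1, len(t_grid)):
        sink = np.zeros(n)
        if E is not None:
            sink_line = params.k_hyd * E[k] * area  # uM^-0 * um^3/ms per node
            sink[j_plane * nrr : (j_plane + 1) * nrr] = sink_line
        base_cg = cap * cg / dt
        base_ca = params.B_Ca * cap * ca / dt
        cg_i, ca_i = cg.copy(), ca.copy()
        for _ in range(config.max_inner_iters):
            rhs = base_cg + cap * params.cyclase_rate(ca_i) - sink * cg_i
            cg_new = lu_cg.solve(rhs)
            dens_cng = (
                params.J_cng_sat / total_shell * params.cng_open_fraction(cg_new)
            )
            dens_ex = (
                params.J_ex_sat / total_shell * params.exchanger_saturation(ca_i)
            )
            src = shell_a * (
                params.f_Ca * dens_cng * PA_TO_FLUX_2 - dens_ex * PA_TO_FLUX_1
            )
            ca_new = lu_ca.solve(base_ca + src)
            err = max(
                np.max(np.abs(cg_new - cg_i)) / (np.max(np.abs(cg_new)) or 1.0),
                np.max(np.abs(ca_new - ca_i)) / (np.max(np.abs(ca_new)) or 1.0),
            )
            cg_i, ca_i = cg_new, ca_new
            if err < config.fixed_point_tol:
                break
        cg, ca = cg_i, ca_i
        j_out.append(sum(currents(cg, ca)))

    r_trace = dark.j_dark - np.array(j_out)
    return ResponseTrace(
        t_grid, r_trace, j_dark=dark.j_dark, meta={"solver": "fd_axisymmetric"}
    )
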