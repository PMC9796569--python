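"""R* activity time courses and transducin/PDE activation on the disk.

A photoisomerization creates one active rhodopsin (R*) whose catalytic
activity decays either deterministically (exponential, the mean-field limit
of stepwise shutoff) or stochastically, as a continuous-time Markov chain
over phosphorylation states terminated by arrestin capping.  While active,
R* feeds activated transducin/PDE (collectively E*) onto the disk membrane
at rate ``nu_RG``; E* spreads by lateral diffusion -- the heat equation on
the disk surface -- decays at ``k_E``, and cannot cross incisures, which
partition the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import DiskMesh, GeometryError, Mesh, ROSGeometry
from .params import ActivationParams, RStarParams


@dataclass(frozen=True)
class PhotoisomerizationEvent:
    """Location and R* trajectory of one photoisomerization.

    ``radial_position``/``angular_position`` locate R* on the disk with
    axial index ``disk_index``; ``rstar_trajectory`` is a callable activity
    vs time (ms), typically from :func:`deterministic_rstar` or
    :func:`sample_rstar`.
    """

    disk_index: int
    radial_position: float
    angular_position: float
    rstar_trajectory: Callable[[np.ndarray], np.ndarray] | None = None

    def validate(self, geom: ROSGeometry) -> None:
        if not 0 <= self.disk_index < geom.n_disks:
            raise GeometryError("event disk index outside the disk stack")
        if not 0.0 <= self.radial_position <= geom.radius:
            raise GeometryError("event lies outside the disk")


class ExponentialActivity:
    """Deterministic R* activity ``exp(-t / tau)``."""

    def __init__(self, tau: float):
        self.tau = float(tau)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-np.clip(t, 0.0, None) / self.tau)

    def integral(self) -> float:
        return self.tau


class StepActivity:
    """Piecewise-constant R* activity from a sampled shutoff chain.

    ``times`` are the state-entry times (ms, starting at 0) and ``levels``
    the catalytic weights; activity is zero after the final (capped) time.
    """

    def __init__(self, times: np.ndarray, levels: np.ndarray, end_time: float):
        self.times = np.asarray(times, dtype=float)
        self.levels = np.asarray(levels, dtype=float)
        self.end_time = float(end_time)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(
            (t < 0) | (t >= self.end_time), 0.0, self.levels[np.clip(idx, 0, None)]
        )
        return out

    def integral(self) -> float:
        bounds = np.append(self.times, self.end_time)
        return float(np.sum(self.levels * np.diff(bounds)))


def deterministic_rstar(params: RStarParams) -> ExponentialActivity:
    """Mean-field R* shutoff: exponential decay with unit initial activity.

    The time constant is chosen so that the integrated activity equals the
    expected integrated activity of the stochastic chain, making the
    deterministic and stochastic modes agree in total drive.
    """
    tau = params.mean_integrated_activity()
    if not np.isfinite(tau):
        raise ValueError("R* chain never terminates; cannot form deterministic decay")
    return ExponentialActivity(tau)


def sample_rstar(
    params: RStarParams, seed: int | np.random.Generator, horizon: float = 60_000.0
) -> StepActivity:
    """Sample one R* shutoff trajectory from the phosphorylation chain.

    In each state ``i`` the chain waits an exponential time with rate
    ``p_i + c_i`` and then either advances (probability ``p_i/(p_i+c_i)``)
    or is capped by arrestin.  Returns a step function of catalytic
    activity; identical seeds give identical trajectories.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times = [0.0]
    levels = [params.activity_per_state[0]]
    t = 0.0
    n = params.n_phospho_states
    for i in range(n):
        p = params.phosphorylation_rates[i] if i < n - 1 else 0.0
        c = params.arrestin_capping_rates[i]
        lam = p + c
        if lam <= 0:
            warnings.warn(
                "all shutoff rates are zero; truncating R* activity at the horizon",
                RuntimeWarning,
            )
            return StepActivity(np.array(times), np.array(levels), horizon)
        t += rng.exponential(1.0 / lam)
        if t >= horizon:
            warnings.warn("R* shutoff exceeded the horizon; truncating", RuntimeWarning)
            return StepActivity(np.array(times), np.array(levels), horizon)
        if rng.random() < c / lam or i == n - 1:
            return StepActivity(np.array(times), np.array(levels), t)
        times.append(t)
        levels.append(params.activity_per_state[i + 1])
    return StepActivity(np.array(times), np.array(levels), t)


# ---------------------------------------------------------------------------
# P1 finite elements on the disk triangulation
# ---------------------------------------------------------------------------

def triangle_mass_stiffness(mesh: DiskMesh) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Consistent P1 mass and stiffness matrices of the disk triangulation."""
    pts = mesh.nodes
    tri = mesh.triangles
    n = mesh.n_nodes
    p0, p1, p2 = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    d1 = p1 - p0
    d2 = p2 - p0
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * np.abs(det)
    # gradients of the three barycentric shape functions
    g0 = np.column_stack([p1[:, 1] - p2[:, 1], p2[:, 0] - p1[:, 0]]) / det[:, None]
    g1 = np.column_stack([p2[:, 1] - p0[:, 1], p0[:, 0] - p2[:, 0]]) / det[:, None]
    g2 = np.column_stack([p0[:, 1] - p1[:, 1], p1[:, 0] - p0[:, 0]]) / det[:, None]
    grads = np.stack([g0, g1, g2], axis=1)  # (ntri, 3, 2)

    rows, cols, mv, kv = [], [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(tri[:, i])
            cols.append(tri[:, j])
            mv.append(area * (2.0 if i == j else 1.0) / 12.0)
            kv.append(area * np.einsum("td,td->t", grads[:, i], grads[:, j]))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    M = sp.csr_matrix((np.concatenate(mv), (rows, cols)), shape=(n, n))
    K = sp.csr_matrix((np.concatenate(kv), (rows, cols)), shape=(n, n))
    return M, K


def locate_source_node(mesh: DiskMesh, event: PhotoisomerizationEvent) -> int:
    """Nearest mesh node to the event (mass-lumped delta regularization).

    On a slit mesh, nodes on an incisure line are duplicated; the copy on
    the event's side of the cut is chosen by comparing angular positions of
    the duplicate's attached triangles.
    """
    x = event.radial_position * np.cos(event.angular_position)
    y = event.radial_position * np.sin(event.angular_position)
    d2 = (mesh.nodes[:, 0] - x) ** 2 + (mesh.nodes[:, 1] - y) ** 2
    candidates = np.nonzero(d2 <= d2.min() + 1e-12)[0]
    if len(candidates) == 1:
        return int(candidates[0])
    # duplicated (slit) node: pick the copy whose triangle fan contains the
    # event's angular side
    best, best_gap = int(candidates[0]), np.inf
    for c in candidates:
        tris = np.nonzero(np.any(mesh.triangles == c, axis=1))[0]
        cent = mesh.nodes[mesh.triangles[tris]].mean(axis=1)
        ang = np.arctan2(cent[:, 1], cent[:, 0])
        gap = np.min(
            np.abs(
                (ang - event.angular_position + np.pi) % (2 * np.pi) - np.pi
            )
        )
        if gap < best_gap:
            best, best_gap = int(c), gap
    return best


@dataclass
class SurfaceActivation:
    """E* surface density on the activated disk over a uniform time grid."""

    t_grid: np.ndarray            # (nt,), ms
    density: np.ndarray           # (nt, n_nodes), molecules/um^2
    mesh: DiskMesh
    lumped_area: np.ndarray       # nodal areas used for integration

    def total(self) -> np.ndarray:
        """Total activated effector vs time (molecules)."""
        return self.density @ self.lumped_area

    def at(self, t: float) -> np.ndarray:
        """Linear interpolation of the density field at time ``t``."""
        tg = self.t_grid
        if t <= tg[0]:
            return self.density[0]
        if t >= tg[-1]:
            return self.density[-1]
        j = int(np.searchsorted(tg, t) - 1)
        w = (t - tg[j]) / (tg[j + 1] - tg[j])
        return (1.0 - w) * self.density[j] + w * self.density[j + 1]


def solve_surface_activation(
    event: PhotoisomerizationEvent,
    params: ActivationParams,
    mesh: DiskMesh,
    t_grid: np.ndarray,
) -> SurfaceActivation:
    """Integrate E* spread on the activated disk.

    Solves ``dE/dt = D_E Lap E - k_E E + nu_RG R*(t) delta(x - x0)`` with
    no-flux boundaries at the disk rim and along incisure cuts (pass a mesh
    built with ``slit_incisures=True`` to make incisures barriers), using
    backward-Euler steps on the P1 discretization with the source lumped
    onto the nearest node.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    dt = np.diff(t_grid)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-8):
        raise ValueError("t_grid must be uniform")
    if event.rstar_trajectory is None:
        raise ValueError("event carries no R* trajectory")
    M, K = triangle_mass_stiffness(mesh)
    lumped = np.asarray(M.sum(axis=1)).ravel()
    src = locate_source_node(mesh, event)
    n = mesh.n_nodes
    E = np.zeros((len(t_grid), n))
    if len(t_grid) == 1:
        return SurfaceActivation(t_grid, E, mesh, lumped)
    h = dt[0]
    A = (M / h + params.D_E * K + params.k_E * M).tocsc()
    lu = splu(A)
    act = event.rstar_trajectory
    e = np.zeros(n)
    for i in range(1, len(t_grid)):
        rhs = M @ e / h
        # source integrated over the step: nu_RG * mean activity, applied as
        # a nodal load (delta integrates to its amplitude)
        a_mid = float(
            np.mean(act(np.linspace(t_grid[i - 1], t_grid[i], 5)))
        )
        rhs[src] += params.nu_RG * a_mid
        e = lu.solve(rhs)
        E[i] = e
    return SurfaceActivation(t_grid, E, mesh, lumped)
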