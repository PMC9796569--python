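"""Rod outer segment geometry, homogenized transport coefficients and meshes.

The rod outer segment (ROS) is a cylinder of radius ``R`` and length ``L``
stacked with ~10^3 membranous disks.  Disks nearly span the cross-section,
leaving a thin cytosolic shell between disk rim and plasma membrane, and are
pierced by radial incisures -- slots in the disk rim that act as axial
conduits for cytosolic solutes.

Rather than resolving every disk, the transport problem is homogenized: the
interior becomes a cylinder carrying transversal (radial/angular) diffusion
scaled by the cytosol volume fraction, while the thin shell and the incisures
collapse onto lower-dimensional structures (a cylindrical surface and one
vertical rectangle per incisure) that carry axial diffusion with an effective
"capacity" equal to their cytosolic thickness.

Coordinates are cylindrical ``(r, phi, z)`` with ``z = 0`` at the ROS base
(the end attached to the inner segment) and ``phi = 0`` at the first
incisure.  All lengths in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Invalid or degenerate ROS geometry."""


class MeshRefinementError(ValueError):
    """Requested mesh resolution cannot represent the geometry."""


@dataclass(frozen=True)
class IncisureSpec:
    """One radial incisure: a straight slot in the disk rim.

    Parameters
    ----------
    angular_position : float
        Angle of the incisure plane, radians in ``[0, 2*pi)``.
    depth : float
        Radial extent inward from the rim, um.
    width : float
        Cytosolic width of the slot, um.  This is the capacity of the
        homogenized incisure rectangle.
    """

    angular_position: float
    depth: float
    width: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise GeometryError("incisure depth must be >= 0")
        if self.width <= 0:
            raise GeometryError("incisure width must be > 0")
        if not (0.0 <= self.angular_position < 2.0 * math.pi):
            raise GeometryError("incisure angle must lie in [0, 2*pi)")


@dataclass(frozen=True)
class ROSGeometry:
    """Dimensions of a rod outer segment.

    All lengths in um.  ``length`` must be consistent with the disk stack
    (``n_disks * (disk_thickness + interdisk_gap)``) to within 5%.
    """

    radius: float
    length: float
    disk_thickness: float
    interdisk_gap: float
    n_disks: int
    incisures: tuple[IncisureSpec, ...] = ()
    species_tag: str = "custom"
    shell_thickness: float = 0.015  # rim-to-plasmalemma cytosol gap, um

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise GeometryError("radius and length must be positive")
        if self.disk_thickness <= 0:
            raise GeometryError("disk thickness must be positive")
        if self.interdisk_gap < 0:
            raise GeometryError("interdisk gap must be non-negative")
        stack = self.n_disks * (self.disk_thickness + self.interdisk_gap)
        if abs(stack - self.length) > 0.05 * self.length:
            raise GeometryError(
                f"length {self.length} inconsistent with disk stack {stack:.3g} "
                "(must agree within 5%)"
            )
        for inc in self.incisures:
            if inc.depth >= self.radius:
                raise GeometryError("incisure depth must be smaller than radius")
        object.__setattr__(self, "incisures", tuple(self.incisures))

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def n_incisures(self) -> int:
        return len(self.incisures)

    def disk_z(self, disk_index: int) -> float:
        """Axial position (um from base) of the centre of disk ``disk_index``."""
        if not 0 <= disk_index < self.n_disks:
            raise GeometryError(f"disk index {disk_index} out of range")
        pitch = self.length / self.n_disks
        return (disk_index + 0.5) * pitch

    def disk_index_at(self, z: float) -> int:
        """Index of the disk whose axial slab contains ``z``."""
        pitch = self.length / self.n_disks
        return int(np.clip(z // pitch, 0, self.n_disks - 1))


def evenly_spaced_incisures(n: int, depth: float, width: float) -> tuple[IncisureSpec, ...]:
    """``n`` identical incisures evenly spaced around the rim, first at phi=0."""
    return tuple(
        IncisureSpec(angular_position=2.0 * math.pi * k / n, depth=depth, width=width)
        for k in range(n)
    )


@dataclass(frozen=True)
class EffectiveMedium:
    """Homogenized transport coefficients of the disk stack.

    ``cytosol_volume_fraction`` scales transversal diffusion and capacity in
    the interior; ``shell_capacity`` and ``incisure_capacities`` are the
    effective cytosolic thicknesses (um) of the concentrated surface
    structures; ``axial_diffusion_factor`` is the ratio of the structure's
    axial conductance to that of an unobstructed cylinder of the same
    diameter (conduit cross-section over total cross-section).
    """

    cytosol_volume_fraction: float
    axial_diffusion_factor: float
    shell_capacity: float
    incisure_capacities: tuple[float, ...]
    activated_disk_capacity: float = 0.028

    def __post_init__(self) -> None:
        if not (0.0 < self.cytosol_volume_fraction <= 1.0):
            raise GeometryError("cytosol volume fraction must be in (0, 1]")
        if self.axial_diffusion_factor > 1.0:
            raise GeometryError("axial diffusion factor cannot exceed 1")
        if self.shell_capacity <= 0 or any(c <= 0 for c in self.incisure_capacities):
            raise GeometryError("all capacities must be positive")
        if self.activated_disk_capacity <= 0:
            raise GeometryError("all capacities must be positive")


def build_effective_medium(geom: ROSGeometry) -> EffectiveMedium:
    """Homogenized coefficients for a ROS geometry.

    The cytosol volume fraction is the interdiskal share of the axial repeat,
    ``gap / (gap + disk_thickness)``.  Axial transport is only possible
    through the outer shell annulus and the incisure slots, so the axial
    diffusion factor is their combined cross-sectional area over ``pi R^2``.
    The activated disk carries a concentrated capacity equal to its two
    adjacent interdiskal gaps (``2 * gap``): they form a quasi-2-D
    compartment draining to the conduits at the rim and incisure lines.
    """
    if geom.interdisk_gap <= 0:
        raise GeometryError("degenerate geometry: interdisk gap must be positive")
    eps0 = geom.interdisk_gap / (geom.interdisk_gap + geom.disk_thickness)
    conduit = 2.0 * math.pi * geom.radius * geom.shell_thickness
    conduit += sum(inc.depth * inc.width for inc in geom.incisures)
    f_ax = min(1.0, conduit / (math.pi * geom.radius**2))
    return EffectiveMedium(
        cytosol_volume_fraction=eps0,
        axial_diffusion_factor=f_ax,
        shell_capacity=geom.shell_thickness,
        incisure_capacities=tuple(inc.width for inc in geom.incisures),
        activated_disk_capacity=2.0 * geom.interdisk_gap,
    )


@dataclass(frozen=True)
class MeshResolution:
    """Discretization of the simplified domain.

    ``n_radial`` rings on the disk cross-section, ``n_angular`` angular
    sectors (must place every incisure on a mesh line) and ``n_axial``
    layers along the cylinder.
    """

    n_radial: int = 16
    n_angular: int = 46
    n_axial: int = 24

    def __post_init__(self) -> None:
        if self.n_radial < 2 or self.n_angular < 3 or self.n_axial < 1:
            raise MeshRefinementError("resolution too coarse to mesh the domain")


def default_resolution(geom: ROSGeometry, *, coarse: bool = False) -> MeshResolution:
    """Default resolution: 16 radial rings, two angular sectors per incisure
    gap (at least 16 sectors) and 24 axial layers.  ``coarse=True`` halves
    the radial/axial counts for quick surveys."""
    n_ang = 2 * max(geom.n_incisures, 8)
    if coarse:
        return MeshResolution(n_radial=8, n_angular=n_ang, n_axial=12)
    return MeshResolution(n_radial=16, n_angular=n_ang, n_axial=24)


@dataclass
class DiskMesh:
    """Triangulation of the disk cross-section (polar structured grid).

    ``slit_parent`` maps every node to its originating base node; it is the
    identity unless the mesh was built with incisures opened as slits (used
    for membrane surface diffusion, where incisures partition the membrane).
    """

    nodes: np.ndarray          # (n_nodes, 2) cartesian xy
    triangles: np.ndarray      # (n_tri, 3) node indices, CCW
    node_r: np.ndarray         # radial coordinate per node
    node_phi: np.ndarray       # angular coordinate per node
    rim_nodes: np.ndarray      # indices of nodes on r = R, in angular order
    ring_of_node: np.ndarray   # ring index per node (0 = centre)
    sector_of_node: np.ndarray  # angular index per node (-1 for centre)
    incisure_node_lines: list[np.ndarray]  # per incisure: node indices tip->rim
    slit_parent: np.ndarray
    radii: np.ndarray          # ring radii including 0
    angles: np.ndarray         # sector angles

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.abs(
            (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
            - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
        )

    def lumped_areas(self) -> np.ndarray:
        """Row-sum (lumped) nodal areas of the triangulation."""
        areas = self.triangle_areas()
        out = np.zeros(self.n_nodes)
        for i in range(3):
            np.add.at(out, self.triangles[:, i], areas / 3.0)
        return out


def _incisure_sector_indices(geom: ROSGeometry, res: MeshResolution) -> list[int]:
    """Angular grid index of each incisure; error if not representable."""
    dphi = 2.0 * math.pi / res.n_angular
    idx: list[int] = []
    for inc in geom.incisures:
        k = inc.angular_position / dphi
        k_round = int(round(k)) % res.n_angular
        if abs(k - round(k)) > 1e-6:
            raise MeshRefinementError(
                f"incisure at phi={inc.angular_position:.4f} does not lie on an "
                f"angular mesh line (n_angular={res.n_angular}); refine or "
                "realign the angular resolution"
            )
        idx.append(k_round)
    if len(set(idx)) != len(idx):
        raise MeshRefinementError("two incisures fall on the same angular mesh line")
    if geom.n_incisures and res.n_angular < 2 * geom.n_incisures:
        raise MeshRefinementError(
            "need at least two angular sectors per incisure gap"
        )
    return idx


def build_disk_triangulation(
    geom: ROSGeometry,
    res: MeshResolution,
    *,
    slit_incisures: bool = False,
) -> DiskMesh:
    """Triangulate the disk cross-section on a polar structured grid.

    Incisure angular positions must coincide with angular mesh lines and
    incisure depths are snapped to the nearest ring radius, so that the
    homogenized incisure rectangles conform to prism faces in the volume
    mesh.  With ``slit_incisures=True`` the nodes interior to each incisure
    segment are duplicated and triangles re-attached per side, turning each
    incisure into an internal no-flux cut (membrane partition).
    """
    R = geom.radius
    n_r, n_a = res.n_radial, res.n_angular
    inc_sectors = _incisure_sector_indices(geom, res)

    radii = R * np.arange(n_r + 1) / n_r
    angles = 2.0 * math.pi * np.arange(n_a) / n_a

    # node layout: centre, then rings 1..n_r each with n_a nodes
    def nid(ring: int, sector: int) -> int:
        if ring == 0:
            return 0
        return 1 + (ring - 1) * n_a + (sector % n_a)

    n_nodes = 1 + n_r * n_a
    node_r = np.zeros(n_nodes)
    node_phi = np.zeros(n_nodes)
    ring_of = np.zeros(n_nodes, dtype=int)
    sector_of = np.full(n_nodes, -1, dtype=int)
    for ring in range(1, n_r + 1):
        for k in range(n_a):
            i = nid(ring, k)
            node_r[i] = radii[ring]
            node_phi[i] = angles[k]
            ring_of[i] = ring
            sector_of[i] = k
    nodes = np.column_stack([node_r * np.cos(node_phi), node_r * np.sin(node_phi)])

    tris: list[tuple[int, int, int]] = []
    for k in range(n_a):
        tris.append((0, nid(1, k), nid(1, k + 1)))
    for ring in range(1, n_r):
        for k in range(n_a):
            a = nid(ring, k)
            b = nid(ring, k + 1)
            c = nid(ring + 1, k)
            d = nid(ring + 1, k + 1)
            tris.append((a, b, d))
            tris.append((a, d, c))
    triangles = np.asarray(tris, dtype=int)

    rim = np.array([nid(n_r, k) for k in range(n_a)], dtype=int)
    inc_lines: list[np.ndarray] = []
    for inc, k in zip(geom.incisures, inc_sectors):
        tip_ring = int(round((R - inc.depth) / R * n_r))
        tip_ring = max(0, min(n_r - 1, tip_ring))
        line = np.array([nid(ring, k) for ring in range(tip_ring, n_r + 1)], dtype=int)
        inc_lines.append(line)

    slit_parent = np.arange(n_nodes, dtype=int)
    if slit_incisures and inc_lines:
        nodes, triangles, slit_parent = _open_slits(
            nodes, triangles, inc_lines, angles, sector_of, ring_of
        )
        node_r = np.hypot(nodes[:, 0], nodes[:, 1])
        node_phi = np.arctan2(nodes[:, 1], nodes[:, 0]) % (2.0 * math.pi)
        ring_of = ring_of[slit_parent]
        sector_of = sector_of[slit_parent]

    return DiskMesh(
        nodes=nodes,
        triangles=triangles,
        node_r=node_r,
        node_phi=node_phi,
        rim_nodes=rim,
        ring_of_node=ring_of,
        sector_of_node=sector_of,
        incisure_node_lines=inc_lines,
        slit_parent=slit_parent,
        radii=radii,
        angles=angles,
    )


def _open_slits(nodes, triangles, inc_lines, angles, sector_of, ring_of):
    """Duplicate nodes strictly inside incisure segments and re-attach the
    triangles on the positive-angle side to the copies.  The innermost (tip)
    node of each line stays shared, keeping the surface connected around the
    slit tip."""
    n0 = nodes.shape[0]
    slit_parent = list(range(n0))
    extra_xy: list[np.ndarray] = []
    triangles = triangles.copy()
    for line in inc_lines:
        for node in line[1:]:  # all but the tip node
            phi_line = angles[sector_of[node]]
            copy_id = len(slit_parent)
            slit_parent.append(int(node))
            extra_xy.append(nodes[node])
            # incident triangles, split by which side of the cut plane their
            # centroid lies on (all incident triangles hug the line, so the
            # centroid angle is an unambiguous side indicator)
            for t in np.nonzero(np.any(triangles == node, axis=1))[0]:
                cen = nodes[
                    np.vectorize(lambda v: slit_parent[v])(triangles[t])
                ].mean(axis=0)
                ang = math.atan2(cen[1], cen[0])
                d = (ang - phi_line + math.pi) % (2.0 * math.pi) - math.pi
                if d > 0:
                    triangles[t][triangles[t] == node] = copy_id
    nodes_out = np.vstack([nodes] + extra_xy) if extra_xy else nodes
    return nodes_out, triangles, np.asarray(slit_parent, dtype=int)


@dataclass
class Mesh:
    """Conforming mesh of the simplified simulation domain.

    Volume nodes are the disk nodes replicated across ``n_axial + 1`` layers;
    node ``(d, l)`` has global index ``l * n_disk_nodes + d``.  Prisms are the
    disk triangles extruded one layer; shell and incisure rectangles are the
    prism faces lying on the cylindrical boundary and on the incisure planes.
    """

    geom: ROSGeometry
    resolution: MeshResolution
    disk: DiskMesh
    z_layers: np.ndarray                  # (n_axial+1,)
    prisms: np.ndarray                    # (n_prism, 6) volume node ids
    shell_rectangles: np.ndarray          # (n_shell_rect, 4) volume node ids
    incisure_rectangles: list[np.ndarray]  # per incisure: (n_rect, 4)

    @property
    def n_disk_nodes(self) -> int:
        return self.disk.n_nodes

    @property
    def n_nodes(self) -> int:
        return self.disk.n_nodes * len(self.z_layers)

    def volume_node(self, disk_node: int, layer: int) -> int:
        return layer * self.disk.n_nodes + disk_node

    def layer_of(self, z: float) -> int:
        """Nearest mesh layer to axial position ``z``."""
        return int(np.argmin(np.abs(self.z_layers - z)))

    def element_counts(self) -> dict[str, int]:
        return {
            "triangles": int(self.disk.triangles.shape[0]),
            "prisms": int(self.prisms.shape[0]),
            "shell_rectangles": int(self.shell_rectangles.shape[0]),
            "incisure_rectangles": int(sum(r.shape[0] for r in self.incisure_rectangles)),
        }

    def conformity_check(self) -> None:
        """Assert every boundary rectangle's nodes appear among prism nodes."""
        prism_nodes = set(self.prisms.ravel().tolist())
        rects = [self.shell_rectangles] + self.incisure_rectangles
        for rect_group in rects:
            missing = set(rect_group.ravel().tolist()) - prism_nodes
            if missing:
                raise MeshRefinementError(
                    f"non-conforming mesh: rectangle nodes {sorted(missing)[:5]} "
                    "are not prism nodes"
                )

    def to_tables(self):
        """Node and element tables (pandas) for external inspection."""
        import pandas as pd

        nd = self.disk.n_nodes
        layers = np.repeat(np.arange(len(self.z_layers)), nd)
        xy = np.tile(self.disk.nodes, (len(self.z_layers), 1))
        nodes = pd.DataFrame(
            {
                "node": np.arange(self.n_nodes),
                "x": xy[:, 0],
                "y": xy[:, 1],
                "z": self.z_layers[layers],
            }
        )
        prisms = pd.DataFrame(self.prisms, columns=[f"n{i}" for i in range(6)])
        return nodes, prisms


def build_mesh(geom: ROSGeometry, resolution: MeshResolution | None = None) -> Mesh:
    """Build the conforming volume/boundary mesh of the homogenized domain."""
    res = resolution or default_resolution(geom)
    disk = build_disk_triangulation(geom, res, slit_incisures=False)
    n_z = res.n_axial
    z_layers = geom.length * np.arange(n_z + 1) / n_z
    nd = disk.n_nodes

    tri = disk.triangles
    prisms = np.empty((tri.shape[0] * n_z, 6), dtype=int)
    for l in range(n_z):
        lo = l * nd
        hi = (l + 1) * nd
        prisms[l * tri.shape[0] : (l + 1) * tri.shape[0], :3] = tri + lo
        prisms[l * tri.shape[0] : (l + 1) * tri.shape[0], 3:] = tri + hi

    rim = disk.rim_nodes
    n_a = res.n_angular
    shell = np.empty((n_a * n_z, 4), dtype=int)
    i = 0
    for l in range(n_z):
        lo, hi = l * nd, (l + 1) * nd
        for k in range(n_a):
            a, b = rim[k], rim[(k + 1) % n_a]
            shell[i] = (a + lo, b + lo, b + hi, a + hi)
            i += 1

    inc_rects: list[np.ndarray] = []
    for line in disk.incisure_node_lines:
        rects = np.empty(((len(line) - 1) * n_z, 4), dtype=int)
        i = 0
        for l in range(n_z):
            lo, hi = l * nd, (l + 1) * nd
            for a, b in zip(line[:-1], line[1:]):
                rects[i] = (a + lo, b + lo, b + hi, a + hi)
                i += 1
        inc_rects.append(rects)

    mesh = Mesh(
        geom=geom,
        resolution=res,
        disk=disk,
        z_layers=z_layers,
        prisms=prisms,
        shell_rectangles=shell,
        incisure_rectangles=inc_rects,
    )
    mesh.conformity_check()
    return mesh


def species_preset(tag: str):
    """Bundled (geometry, cascade parameters) for a species tag.

    Convenience re-export; see :mod:`rodspr.presets`.
    """
    from .presets import species_preset as _preset

    return _preset(tag)


def geometry_to_dict(geom: ROSGeometry) -> dict:
    """Plain-dict form of a geometry (for structured-text configs)."""
    return {
        "radius": geom.radius,
        "length": geom.length,
        "disk_thickness": geom.disk_thickness,
        "interdisk_gap": geom.interdisk_gap,
        "n_disks": geom.n_disks,
        "shell_thickness": geom.shell_thickness,
        "species_tag": geom.species_tag,
        "incisures": [
            {"angular_position": i.angular_position, "depth": i.depth,
             "width": i.width}
            for i in geom.incisures
        ],
    }


def geometry_from_dict(data: dict) -> ROSGeometry:
    data = dict(data)
    incisures = tuple(
        IncisureSpec(**inc) for inc in data.pop("incisures", [])
    )
    return ROSGeometry(incisures=incisures, **data)


def write_geometry(geom: ROSGeometry, path) -> None:
    """Write a geometry as a YAML config file."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(geometry_to_dict(geom), fh, sort_keys=False)


def read_geometry(path) -> ROSGeometry:
    import yaml

    with open(path) as fh:
        return geometry_from_dict(yaml.safe_load(fh))
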