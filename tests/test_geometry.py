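"""Geometry, homogenized coefficients and meshing."""

import math

import numpy as np
import pytest

from rodspr.geometry import (
    GeometryError,
    IncisureSpec,
    MeshRefinementError,
    MeshResolution,
    ROSGeometry,
    build_disk_triangulation,
    build_effective_medium,
    build_mesh,
    default_resolution,
    evenly_spaced_incisures,
)


def make_geom(**kw):
    base = dict(
        radius=5.5,
        length=25.0,
        disk_thickness=0.014,
        interdisk_gap=0.014,
        n_disks=893,
        incisures=(),
    )
    base.update(kw)
    return ROSGeometry(**base)


class TestEffectiveMedium:
    def test_symmetric_gap_gives_half_volume_fraction(self):
        em = build_effective_medium(make_geom())
        assert em.cytosol_volume_fraction == pytest.approx(0.5)

    def test_volume_fraction_follows_gap_share(self):
        g = make_geom(disk_thickness=0.021, interdisk_gap=0.007)
        em = build_effective_medium(g)
        assert em.cytosol_volume_fraction == pytest.approx(0.25)

    def test_zero_gap_is_degenerate(self):
        g = make_geom(interdisk_gap=0.0, disk_thickness=0.028)
        with pytest.raises(GeometryError):
            build_effective_medium(g)

    def test_no_conduits_blocks_axial_diffusion(self):
        # shrinking the shell with no incisures sends the axial factor to 0
        factors = [
            build_effective_medium(make_geom(shell_thickness=s)).axial_diffusion_factor
            for s in (0.1, 0.01, 0.001)
        ]
        assert factors[0] > factors[1] > factors[2]
        assert factors[2] < 1e-3

    def test_incisures_enlarge_axial_conduit(self):
        plain = build_effective_medium(make_geom())
        cut = build_effective_medium(
            make_geom(incisures=evenly_spaced_incisures(23, depth=3.0, width=0.05))
        )
        assert cut.axial_diffusion_factor > plain.axial_diffusion_factor

    def test_axial_factor_matches_explicit_disk_stack(self):
        """Steady axial flux through a resolved 3-disk stack matches the
        homogenized axial factor within 10%.

        Oracle: direct numerical solution of the axisymmetric Laplace
        equation on a cylinder containing three impermeable disks (only
        the outer shell annulus conducts past them), with unit
        concentration drop top to bottom.  The net flux over the
        unobstructed-tube flux is the resolved axial transmission factor.
        The oracle geometry exaggerates the shell so both scales are
        resolvable on one grid.
        """
        import scipy.sparse as sp
        from scipy.sparse.linalg import spsolve

        R, shell = 1.0, 0.08
        pitch, gap = 0.08, 0.04
        geom = ROSGeometry(
            radius=R, length=3 * pitch * 25, disk_thickness=pitch - gap,
            interdisk_gap=gap, n_disks=75, incisures=(), species_tag="o",
            shell_thickness=shell,
        )
        em = build_effective_medium(geom)

        # resolved axisymmetric FD: grid over (r, z), 3 disks of radius R-shell
        h = 0.01
        nr, L = int(round(R / h)), 3 * pitch
        nz = int(round(L / h))
        rr = np.arange(nr + 1) * h
        disk_r = R - shell
        z_disks = [gap / 2 + k * pitch for k in range(3)]

        def idx(i, j):
            return j * (nr + 1) + i

        n = (nr + 1) * (nz + 1)
        A = sp.lil_matrix((n, n))
        b = np.zeros(n)
        area = np.where(rr > 0, 2 * math.pi * rr * h, math.pi * (h / 2) ** 2)

        def blocked(i, j_face):
            # face between z levels j_face and j_face+1 crosses a disk?
            zf = (j_face + 0.5) * h
            if rr[i] > disk_r:
                return False
            return any(zd <= zf <= zd + (pitch - gap) for zd in z_disks)

        for j in range(nz + 1):
            for i in range(nr + 1):
                k = idx(i, j)
                if j == 0 or j == nz:
                    A[k, k] = 1.0
                    b[k] = 1.0 if j == 0 else 0.0
                    continue
                if i > 0:
                    g = 2 * math.pi * (rr[i] - h / 2) / h * h
                    A[k, k] += g
                    A[k, idx(i - 1, j)] -= g
                if i < nr:
                    g = 2 * math.pi * (rr[i] + h / 2) / h * h
                    A[k, k] += g
                    A[k, idx(i + 1, j)] -= g
                for jn in (j - 1, j + 1):
                    jf = min(j, jn)
                    if not blocked(i, jf):
                        g = area[i] / h
                        A[k, k] += g
                        A[k, idx(i, jn)] -= g
        c = spsolve(A.tocsr(), b)
        # flux through the top layer
        flux = sum(
            area[i] / h * (c[idx(i, 0)] - c[idx(i, 1)])
            for i in range(nr + 1)
            if not blocked(i, 0)
        )
        open_flux = math.pi * R**2 / L  # unobstructed tube, unit drop
        resolved_factor = flux / open_flux
        assert em.axial_diffusion_factor == pytest.approx(resolved_factor, rel=0.10)


class TestDiskMesh:
    def test_triangle_areas_cover_disk(self):
        g = make_geom(radius=1.0, length=25.0)
        mesh = build_disk_triangulation(g, MeshResolution(8, 24, 8))
        assert mesh.triangle_areas().sum() == pytest.approx(math.pi, rel=0.02)

    def test_refinement_reduces_area_error(self):
        g = make_geom(radius=1.0)
        errs = []
        for n in (12, 24, 48):
            mesh = build_disk_triangulation(g, MeshResolution(8, n, 8))
            errs.append(abs(mesh.triangle_areas().sum() - math.pi))
        assert errs[0] > errs[1] > errs[2]

    def test_incisures_misaligned_with_grid_raise(self):
        g = make_geom(incisures=(IncisureSpec(0.1234, 1.0, 0.05),))
        with pytest.raises(MeshRefinementError):
            build_disk_triangulation(g, MeshResolution(8, 24, 8))

    def test_too_few_sectors_per_incisure_gap_raise(self):
        g = make_geom(incisures=evenly_spaced_incisures(23, 1.0, 0.05))
        with pytest.raises(MeshRefinementError):
            build_disk_triangulation(g, MeshResolution(8, 23, 8))

    def test_slit_mesh_duplicates_nodes_and_keeps_area(self):
        g = make_geom(incisures=evenly_spaced_incisures(4, 2.0, 0.05))
        res = MeshResolution(8, 16, 8)
        plain = build_disk_triangulation(g, res)
        slit = build_disk_triangulation(g, res, slit_incisures=True)
        assert slit.n_nodes > plain.n_nodes
        assert slit.triangle_areas().sum() == pytest.approx(
            plain.triangle_areas().sum()
        )
        # duplicated nodes map back to their base node
        dup = slit.slit_parent[plain.n_nodes :]
        assert np.all(dup < plain.n_nodes)


class TestVolumeMesh:
    def test_salamander_mesh_has_one_rectangle_group_per_incisure(self, salamander):
        geom, _ = salamander
        mesh = build_mesh(geom, MeshResolution(6, 46, 6))
        assert len(mesh.incisure_rectangles) == 23
        assert all(r.shape[0] > 0 for r in mesh.incisure_rectangles)

    def test_conformity(self, small_mesh):
        small_mesh.conformity_check()  # no exception
        counts = small_mesh.element_counts()
        assert counts["prisms"] == counts["triangles"] * 5

    def test_element_orientation_positive(self, small_mesh):
        assert np.all(small_mesh.disk.triangle_areas() > 0)

    def test_mesh_tables_roundtrip(self, small_mesh):
        nodes, prisms = small_mesh.to_tables()
        assert len(nodes) == small_mesh.n_nodes
        assert prisms.shape[1] == 6


class TestPresets:
    def test_salamander_disk_diameter_and_incisures(self, salamander):
        geom, _ = salamander
        assert geom.radius == pytest.approx(5.5)
        assert geom.n_incisures == 23

    def test_toad_is_longer_and_thinner(self, salamander, toad):
        sal, _ = salamander
        td, _ = toad
        assert td.length > sal.length
        assert td.radius < sal.radius

    def test_unknown_species_raises(self):
        from rodspr.presets import species_preset

        with pytest.raises(KeyError):
            species_preset("zebrafish")

    def test_length_consistency_invariant(self):
        with pytest.raises(GeometryError):
            make_geom(n_disks=100)  # stack length far from 25 um

    def test_incisure_deeper_than_radius_rejected(self):
        with pytest.raises(GeometryError):
            make_geom(incisures=(IncisureSpec(0.0, 6.0, 0.05),))
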