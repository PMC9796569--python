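import math

import numpy as np
import pytest

from rodspr.geometry import (
    MeshResolution,
    ROSGeometry,
    build_disk_triangulation,
    build_mesh,
    evenly_spaced_incisures,
)
from rodspr.presets import species_preset


@pytest.fixture(scope="session")
def salamander():
    return species_preset("salamander")


@pytest.fixture(scope="session")
def toad():
    return species_preset("toad")


@pytest.fixture(scope="session")
def bare_cylinder():
    """Incisure-free salamander-sized geometry (axisymmetric test domain)."""
    return ROSGeometry(
        radius=5.5,
        length=25.0,
        disk_thickness=0.014,
        interdisk_gap=0.014,
        n_disks=893,
        incisures=(),
        species_tag="bare",
    )


@pytest.fixture(scope="session")
def small_geom():
    """Tiny geometry for fast solver-level tests."""
    return ROSGeometry(
        radius=2.0,
        length=8.0,
        disk_thickness=0.014,
        interdisk_gap=0.014,
        n_disks=286,
        incisures=evenly_spaced_incisures(4, depth=0.8, width=0.05),
        species_tag="tiny",
    )


@pytest.fixture(scope="session")
def small_mesh(small_geom):
    return build_mesh(small_geom, MeshResolution(n_radial=5, n_angular=8, n_axial=5))
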