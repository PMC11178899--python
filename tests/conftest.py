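"""Shared fixtures: small canonical meshes and random-mesh factories.

Everything is generated programmatically and deterministically; no mesh
files ship with the tests.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from morphgrad.mesh_core import TriMesh


def tetrahedron() -> TriMesh:
    """Smallest closed manifold: regular-ish tetrahedron, outward winding."""
    v = np.array([[0.0, 0.0, 0.0],
                  [1.0, 0.0, 0.0],
                  [0.0, 1.0, 0.0],
                  [0.0, 0.0, 1.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(v, f)


def unit_cube() -> TriMesh:
    """Axis-aligned unit cube [0,1]^3, 8 vertices, 12 triangles."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


def icosphere(subdivisions: int = 2, radius: float = 1.0) -> TriMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def path_mesh(n_vertices: int, spacing: float = 1.0) -> TriMesh:
    """Degenerate chain mesh whose edge graph is a path of unit edges.

    Faces are collapsed triangles (i, i+1, i+1); only the graph structure
    is meaningful, which is all the cover/geodesic tests need.
    """
    v = np.column_stack([np.arange(n_vertices) * spacing,
                         np.zeros(n_vertices), np.zeros(n_vertices)])
    f = np.array([[i, i + 1, i + 1] for i in range(n_vertices - 1)])
    return TriMesh(v, f)


def random_convex_mesh(seed: int, n_points: int = 20, scale: float = 10.0) -> TriMesh:
    """Closed manifold mesh: convex hull of random points."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3)) * scale
    hull = trimesh.convex.convex_hull(pts)
    return TriMesh(np.asarray(hull.vertices), np.asarray(hull.faces))


@pytest.fixture
def tetra() -> TriMesh:
    return tetrahedron()


@pytest.fixture
def cube() -> TriMesh:
    return unit_cube()


@pytest.fixture
def sphere2() -> TriMesh:
    return icosphere(2)


@pytest.fixture(scope="session")
def default_population():
    """One moderately dimorphic population shared across evaluation tests."""
    from morphgrad.synthetic import sample_population

    return sample_population(100, sex_effect=1.0, noise_sd=0.5, rng_seed=7,
                             subdivisions=2)
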