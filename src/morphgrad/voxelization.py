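"""Surface voxelization: mesh -> dense axis-aligned binary occupancy volume.

The grid is a cube spanning the largest bounding-box extent, centered on
the mesh, at an isotropic resolution. A voxel is occupied iff its cube
intersects some triangle, decided by the separating-axis test (SAT) — the
conservative convention, which guarantees the shell of a watertight mesh is
itself watertight at grid resolution so that :func:`fill_solid` can
flood-fill a solid bone mask from it.

Voxel (i, j, k) spans [origin + i*s, origin + (i+1)*s) per axis. Geometry
lying exactly on an interior voxel-face plane is assigned to the lower
voxel only; geometry on the outermost grid planes is clamped inward.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .mesh_core import TriMesh


@dataclass
class VoxelGrid:
    occupancy: np.ndarray  # (n, n, n) bool
    origin: np.ndarray     # mm coordinates of voxel (0,0,0)'s minimum corner
    voxel_size: float      # mm per voxel edge, isotropic

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def resolution(self) -> int:
        return self.occupancy.shape[0]

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())


def _tri_boxes_overlap(tri: np.ndarray, centers: np.ndarray, half: float) -> np.ndarray:
    """Separating-axis test of one triangle against many axis-aligned cubes.

    ``tri`` is (3, 3), ``centers`` (k, 3); returns a boolean mask of cubes
    whose *closed* volume intersects the triangle. 13 candidate axes: 3 box
    normals, the triangle normal, and 9 edge cross products.
    """
    v = tri[None, :, :] - centers[:, None, :]  # (k, 3 verts, 3)
    e = np.array([tri[1] - tri[0], tri[2] - tri[1], tri[0] - tri[2]])  # (3, 3)
    ok = np.ones(len(centers), dtype=bool)

    # box normals: AABB overlap
    lo = v.min(axis=1)
    hi = v.max(axis=1)
    ok &= (lo <= half).all(axis=1) & (hi >= -half).all(axis=1)
    if not ok.any():
        return ok

    # triangle normal
    n = np.cross(e[0], e[1])
    d = v[:, 0, :] @ n  # distance of box center plane offset
    r = half * np.abs(n).sum()
    ok &= np.abs(d) <= r
    if not ok.any():
        return ok

    # 9 cross-product axes: a = unit(box axis j) x edge i
    for i in range(3):
        ei = e[i]
        for j in range(3):
            axis = np.zeros(3)
            axis[(j + 1) % 3] = -ei[(j + 2) % 3]
            axis[(j + 2) % 3] = ei[(j + 1) % 3]
            p = v @ axis  # (k, 3)
            rad = half * np.abs(axis).sum()
            ok &= (p.min(axis=1) <= rad) & (p.max(axis=1) >= -rad)
            if not ok.any():
                return ok
    return ok


def _axis_range(tmin: float, tmax: float, n: int) -> tuple[int, int]:
    """Candidate voxel index range along one axis in grid units.

    ``ceil(t) - 1`` realizes the boundary convention: coordinates exactly
    on a voxel-face plane belong to the lower voxel; clamping keeps
    geometry on the outermost grid planes inside the grid.
    """
    lo = int(np.clip(np.ceil(tmin) - 1, 0, n - 1))
    hi = int(np.clip(np.ceil(tmax) - 1, 0, n - 1))
    return lo, hi


def voxelize_surface(mesh: TriMesh, resolution: int) -> VoxelGrid:
    """Conservative surface voxelization at ``resolution`` voxels per axis."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if mesh.n_faces == 0:
        raise ValueError("cannot voxelize an empty mesh")
    lo, hi = mesh.bounds
    side = float((hi - lo).max())
    if side == 0:
        raise ValueError("mesh has zero spatial extent")
    center = 0.5 * (lo + hi)
    origin = center - side / 2.0
    s = side / resolution
    half = s / 2.0

    occ = np.zeros((resolution,) * 3, dtype=bool)
    tris = mesh.positions[mesh.faces]  # (m, 3, 3)
    t = (tris - origin) / s  # grid units
    for ti in range(len(tris)):
        tmin = t[ti].min(axis=0)
        tmax = t[ti].max(axis=0)
        ranges = [_axis_range(tmin[a], tmax[a], resolution) for a in range(3)]
        ii, jj, kk = np.meshgrid(*[np.arange(r[0], r[1] + 1) for r in ranges],
                                 indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        centers = origin + (idx + 0.5) * s
        hit = _tri_boxes_overlap(tris[ti], centers, half)
        sel = idx[hit]
        occ[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return VoxelGrid(occ, origin, s)


def fill_solid(grid: VoxelGrid) -> VoxelGrid:
    """Fill the interior of a closed shell: flood-fill empty space from the
    grid boundary; whatever empty space remains unreached is interior and
    becomes occupied.

    A leaky shell lets the exterior flood inside and silently yields less
    filling; a warning reports the situation when a non-empty shell gains
    no interior at all.
    """
    occ = grid.occupancy
    empty = ~occ
    labels, nlab = ndimage.label(empty)
    boundary_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            boundary_labels.update(np.unique(face[face > 0]).tolist())
    exterior = np.isin(labels, sorted(boundary_labels)) if boundary_labels else np.zeros_like(empty)
    interior = empty & ~exterior
    if occ.any() and empty.any() and not interior.any():
        ext_frac = exterior.sum() / empty.sum() if empty.any() else 1.0
        warnings.warn(
            f"fill_solid found no enclosed interior (exterior fills {ext_frac:.0%} "
            "of empty space); the shell may be leaky at this resolution",
            stacklevel=2)
    return VoxelGrid(occ | interior, grid.origin.copy(), grid.voxel_size)


def save_grid(grid: VoxelGrid, path: str | Path) -> Path:
    """Write occupancy as a flat uint8 binary file plus a JSON sidecar
    (``<path>.json``) recording resolution, origin and voxel size."""
    path = Path(path)
    grid.occupancy.astype(np.uint8).tofile(path)
    sidecar = {
        "resolution": grid.resolution,
        "origin_mm": grid.origin.tolist(),
        "voxel_size_mm": grid.voxel_size,
        "order": "C (x-major: index [i, j, k] for axes x, y, z)",
        "dtype": "uint8",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def load_grid(path: str | Path) -> VoxelGrid:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    n = meta["resolution"]
    occ = np.fromfile(path, dtype=np.uint8).reshape((n, n, n)).astype(bool)
    return VoxelGrid(occ, np.asarray(meta["origin_mm"]), meta["voxel_size_mm"])
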