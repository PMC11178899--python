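"""Mesh-space data augmentation: random rotation, shift, and mirroring.

Augmenting in mesh form touches only the vertex table, which is orders of
magnitude cheaper than resampling a dense volume; the augmented mesh is
voxelized afterwards when a volumetric model needs it.

Defaults follow the usual regime for rigid anatomy: rotations within
±10 degrees, per-axis shifts within ±5% of the bounding-box extent, and
mirroring (sagittal flip) with probability 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh_core import TriMesh

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class AugmentationConfig:
    max_rotation_deg: float = 10.0
    max_shift_fraction: float = 0.05
    mirror_probability: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if self.max_shift_fraction < 0:
            raise ValueError("max_shift_fraction must be >= 0")
        if not (0.0 <= self.mirror_probability <= 1.0):
            raise ValueError("mirror_probability must be in [0, 1]")


def mirror(mesh: TriMesh, axis: str = "x", center: np.ndarray | None = None) -> TriMesh:
    """Deterministic mirror about the plane ``axis = center`` (centroid by
    default), with face winding reversed so outward normals stay outward."""
    a = _AXES[axis]
    c = mesh.centroid if center is None else np.asarray(center, dtype=np.float64)
    pos = mesh.positions.copy()
    pos[:, a] = 2.0 * c[a] - pos[:, a]
    faces = mesh.faces[:, [0, 2, 1]]
    return TriMesh(pos, faces)


def random_rotation(mesh: TriMesh, config: AugmentationConfig,
                    rng: np.random.Generator) -> TriMesh:
    """Rotate about the centroid by a uniformly random axis and an angle
    uniform in [-max_rotation_deg, +max_rotation_deg].

    Axis-angle is used (rather than composed per-axis Euler rotations) so
    the single angle bound is exact: the total rotation never exceeds the
    configured limit.
    """
    axis = rng.normal(size=3)
    norm = np.linalg.norm(axis)
    axis = np.array([1.0, 0.0, 0.0]) if norm == 0 else axis / norm
    angle = np.deg2rad(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
    rot = Rotation.from_rotvec(axis * angle).as_matrix()
    c = mesh.centroid
    pos = (mesh.positions - c) @ rot.T + c
    return mesh.with_positions(pos)


def random_shift(mesh: TriMesh, config: AugmentationConfig,
                 rng: np.random.Generator) -> TriMesh:
    """Translate by a vector drawn per axis uniformly within
    ±max_shift_fraction of that axis's bounding-box extent.

    Zero-extent axes get zero shift. Each axis is drawn independently.
    """
    lo, hi = mesh.bounds
    extent = hi - lo
    limit = config.max_shift_fraction * extent
    shift = rng.uniform(-limit, limit)
    shift[extent == 0] = 0.0
    return mesh.with_positions(mesh.positions + shift)


def random_mirror(mesh: TriMesh, config: AugmentationConfig,
                  rng: np.random.Generator) -> tuple[TriMesh, bool]:
    """With probability ``mirror_probability``, mirror sagittally (x about
    the centroid) with winding flip; otherwise return the mesh unchanged.
    The flag reports which branch was taken."""
    mirrored = bool(rng.random() < config.mirror_probability)
    if mirrored:
        return mirror(mesh, axis="x"), True
    return mesh, False


def augment(mesh: TriMesh, config: AugmentationConfig,
            rng: np.random.Generator | None = None) -> TriMesh:
    """Rotation, then shift, then mirror, all drawn from one generator.

    Fully reproducible: with no generator supplied a fresh one is seeded
    from ``config.rng_seed``. Vertex and face counts are always preserved.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    out = random_rotation(mesh, config, rng)
    out = random_shift(out, config, rng)
    out, _ = random_mirror(out, config, rng)
    return out
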