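"""Morphological gradients: perturbation-based saliency on a mesh surface.

A scoring function f maps a mesh M to a class belief in [0, 1] (here, by
convention, P(female)). The morphological gradient at a vertex p0 is the
change in f when the surface around p0 is pushed outward along the vertex
normals into a smooth local bump:

    T(p; p0, delta) = p + delta * sigma(||p - p0||; R) * N(p)
    grad_{p0; delta} f(M) = f[T(M; p0, delta)] - f[M]

with the linear radial falloff sigma(r; R) = max{0, (R - r)/R}, so the bump
has height delta at p0 and fades to nothing at distance R. A positive delta
is a bump, a negative delta a dent; because f is generally nonlinear the
dent map is a separate evaluation, not the negated bump map.

Dense evaluation costs one scorer call per vertex. Assuming the gradient
varies smoothly over the surface, it is instead evaluated on a geodesic
point cover of radius rho and interpolated to all vertices, for a total of
|cover| + 1 scorer calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from . import augmentation
from .mesh_core import (
    PointCover,
    TriMesh,
    build_point_cover,
    graph_geodesic_distances,
    interpolate_cover_values,
)


class ScorerContractError(ValueError):
    """A scoring function returned a value outside [0, 1]."""


@dataclass
class ScoringFunction:
    """Callable contract: TriMesh -> score in [0, 1].

    ``positive_class`` documents the semantics of score 1 (by convention,
    "female-like"); ``calls`` counts invocations, which the sparse gradient
    evaluation budget is audited against.
    """

    fn: Callable[[TriMesh], float]
    name: str = "scorer"
    positive_class: str = "female"
    calls: int = field(default=0, compare=False)

    def __call__(self, mesh: TriMesh) -> float:
        self.calls += 1
        score = float(self.fn(mesh))
        if not (0.0 <= score <= 1.0) or not np.isfinite(score):
            raise ScorerContractError(
                f"scorer {self.name!r} returned {score!r}, outside [0, 1]")
        return score


@dataclass(frozen=True)
class DeformationSpec:
    """Bump geometry: signed height ``delta`` (mm), falloff radius
    ``range_R`` (mm), and the distance used inside the falloff.

    Euclidean distance is the default; geodesic distance avoids dragging
    surface that is spatially close but anatomically far (e.g. the inner
    skull table when bumping the outer)."""

    delta: float = 2.0
    range_R: float = 20.0
    distance_mode: str = "euclidean"  # "euclidean" | "geodesic"

    def __post_init__(self) -> None:
        if self.range_R <= 0:
            raise ValueError("range_R must be positive")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.distance_mode not in ("euclidean", "geodesic"):
            raise ValueError("distance_mode must be 'euclidean' or 'geodesic'")


@dataclass
class GradientField:
    """Per-vertex morphological gradient (score change per probe)."""

    values: np.ndarray
    spec: DeformationSpec
    cover: PointCover | None
    scorer_name: str


def sigma(r, range_R: float):
    """Linear radial falloff max{0, (R - r)/R}: 1 at the center, 0 at and
    beyond distance R. Accepts scalars or arrays; r must be nonnegative."""
    if range_R <= 0:
        raise ValueError("range_R must be positive")
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("distance r must be nonnegative")
    out = np.maximum(0.0, (range_R - r) / range_R)
    return float(out) if out.ndim == 0 else out


def deform(mesh: TriMesh, center: int, spec: DeformationSpec) -> TriMesh:
    """Apply the local bump/dent transformation T around ``center``.

    Every vertex moves along its own normal of the *input* mesh by
    delta * sigma(dist to center); vertices beyond range_R stay put. The
    input mesh is never modified.
    """
    if not (0 <= center < mesh.n_vertices):
        raise IndexError(f"center index {center} out of range")
    normals = mesh.vertex_normals
    if spec.distance_mode == "euclidean":
        dist = np.linalg.norm(mesh.positions - mesh.positions[center], axis=1)
    else:
        dist = np.full(mesh.n_vertices, np.inf)
        for v, d in graph_geodesic_distances(mesh, center, cutoff=spec.range_R).items():
            dist[v] = d
        dist = np.where(np.isfinite(dist), dist, spec.range_R)  # beyond cutoff: weight 0
    weights = sigma(dist, spec.range_R)
    new_positions = mesh.positions + spec.delta * weights[:, None] * normals
    return mesh.with_positions(new_positions)


def morphological_gradient_at(mesh: TriMesh, scorer: ScoringFunction, center: int,
                              spec: DeformationSpec,
                              baseline: float | None = None) -> float:
    """Score change caused by a bump at ``center``: f(T(M)) - f(M).

    Pass ``baseline = scorer(mesh)`` when evaluating many centers so the
    reference score is computed once.
    """
    if baseline is None:
        baseline = scorer(mesh)
    return scorer(deform(mesh, center, spec)) - baseline


def gradient_field(mesh: TriMesh, scorer: ScoringFunction,
                   spec: DeformationSpec | None = None,
                   rho: float = 10.0,
                   region_mask: np.ndarray | None = None,
                   hop_metric: bool = False) -> GradientField:
    """Morphological-gradient map over the whole surface (or a masked region).

    Builds a geodesic point cover of radius ``rho``, evaluates the gradient
    at each cover vertex (exactly |cover| + 1 scorer calls including the
    baseline), and interpolates to every vertex. Vertices outside
    ``region_mask`` get value 0.
    """
    spec = spec or DeformationSpec()
    cover = build_point_cover(mesh, rho, hop_metric=hop_metric, mask=region_mask)
    baseline = scorer(mesh)
    cover_vals = {
        int(c): morphological_gradient_at(mesh, scorer, int(c), spec, baseline=baseline)
        for c in cover.cover_indices
    }
    values = interpolate_cover_values(mesh, cover, cover_vals, hop_metric=hop_metric)
    if region_mask is not None:
        values = np.where(np.asarray(region_mask, dtype=bool), values, 0.0)
    values = np.nan_to_num(values, nan=0.0)
    return GradientField(values, spec, cover, scorer.name)


def symmetrized_field(mesh: TriMesh, scorer: ScoringFunction,
                      spec: DeformationSpec | None = None,
                      rho: float = 10.0,
                      mirror_axis: str = "x") -> GradientField:
    """Average of the gradient field on the mesh and on its mirror image.

    A scorer trained on imperfect data need not be exactly mirror-symmetric
    even when the anatomy is; averaging the field with the field of the
    mirrored sample cancels that asymmetry. Mirrored values are carried back
    through nearest-vertex correspondence after un-mirroring.
    """
    spec = spec or DeformationSpec()
    f1 = gradient_field(mesh, scorer, spec, rho)
    mirrored = augmentation.mirror(mesh, axis=mirror_axis)
    f2 = gradient_field(mirrored, scorer, spec, rho)
    # map mirrored-mesh values back: un-mirror its vertices, match to the
    # nearest original vertex
    back = augmentation.mirror(mirrored, axis=mirror_axis)
    tree = cKDTree(back.positions)
    _, nearest = tree.query(mesh.positions)
    values = 0.5 * (f1.values + f2.values[nearest])
    return GradientField(values, spec, f1.cover, scorer.name)


# -- scorer registry ----------------------------------------------------

_SCORERS: dict[str, Callable[[], ScoringFunction]] = {}


def register_scorer(name: str, factory: Callable[[], ScoringFunction]) -> None:
    """Register a named scorer factory (plugin point for trained models)."""
    _SCORERS[name] = factory


def get_scorer(name: str) -> ScoringFunction:
    if name not in _SCORERS:
        raise KeyError(
            f"unknown scorer {name!r}; available: {sorted(_SCORERS)}")
    return _SCORERS[name]()


def available_scorers() -> list[str]:
    return sorted(_SCORERS)


register_scorer("constant", lambda: ScoringFunction(lambda m: 0.5, name="constant"))
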