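"""Triangle-mesh substrate: connectivity, normals, graph geodesics, point covers.

The mesh is treated as an undirected graph whose nodes are vertices and whose
edges are triangle edges weighted by Euclidean length. Geodesic distances are
approximated by shortest paths on that graph, which is the standard cheap
surrogate for true polyhedral geodesics and converges to them under mesh
refinement.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra


class NonManifoldError(ValueError):
    """An edge is shared by more than two faces."""


@dataclass
class TriMesh:
    """Indexed triangle surface with positions in mm.

    Vertex normals and the weighted edge graph are computed lazily and
    cached; any code that mutates ``positions`` or ``faces`` in place must
    call :meth:`invalidate_caches`.
    """

    positions: np.ndarray
    faces: np.ndarray
    _vertex_normals: np.ndarray | None = field(default=None, repr=False, compare=False)
    _edge_graph: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of vertex triples")
        if not np.isfinite(self.positions).all():
            raise ValueError("vertex positions must be finite")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.positions)):
            raise ValueError("face indices out of range")

    # -- basic geometry -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] corner of the axis-aligned bounding box."""
        return np.vstack([self.positions.min(axis=0), self.positions.max(axis=0)])

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def copy(self) -> "TriMesh":
        return TriMesh(self.positions.copy(), self.faces.copy())

    def with_positions(self, positions: np.ndarray) -> "TriMesh":
        """New mesh sharing faces but with replaced vertex positions."""
        return TriMesh(np.asarray(positions, dtype=np.float64), self.faces)

    def invalidate_caches(self) -> None:
        self._vertex_normals = None
        self._edge_graph = None

    # -- cached derived structure ---------------------------------------

    @property
    def vertex_normals(self) -> np.ndarray:
        if self._vertex_normals is None:
            self._vertex_normals = compute_vertex_normals(self)
        return self._vertex_normals

    @property
    def edge_graph(self) -> sp.csr_matrix:
        """Symmetric sparse matrix of Euclidean edge lengths."""
        if self._edge_graph is None:
            self._edge_graph = _build_edge_graph(self)
        return self._edge_graph

    def face_areas(self) -> np.ndarray:
        v = self.positions
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def signed_volume(self) -> float:
        """Signed enclosed volume via the divergence theorem (positive for
        outward-wound closed surfaces)."""
        v = self.positions
        f = self.faces
        return float(np.einsum("ij,ij->i", v[f[:, 0]],
                               np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)


@dataclass(frozen=True)
class PointCover:
    """Sparse vertex subset covering the mesh to geodesic radius ``radius_rho``.

    Every mesh vertex lies within graph distance ``radius_rho`` of some cover
    vertex, and no two cover vertices are within ``radius_rho`` of each other
    (greedy maximal packing).
    """

    cover_indices: np.ndarray
    radius_rho: float

    def __len__(self) -> int:
        return len(self.cover_indices)


def _build_edge_graph(mesh: TriMesh) -> sp.csr_matrix:
    f = mesh.faces
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges.sort(axis=1)
    edges = np.unique(edges, axis=0)
    lengths = np.linalg.norm(mesh.positions[edges[:, 0]] - mesh.positions[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sp.coo_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    )
    return g.tocsr()


def compute_vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Area-weighted average of incident face normals, normalized per vertex.

    Orientation follows face winding (counter-clockwise seen from outside
    gives outward normals). Isolated vertices get a zero normal; a vertex
    whose incident faces are all degenerate (zero area) is an error because
    its normal is undefined.
    """
    v = mesh.positions
    f = mesh.faces
    # cross product = 2 * area * unit normal, so summing it per vertex is
    # exactly the area weighting
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    acc = np.zeros_like(v)
    for k in range(3):
        np.add.at(acc, f[:, k], cross)
    norms = np.linalg.norm(acc, axis=1)
    incident = np.zeros(mesh.n_vertices, dtype=bool)
    incident[f.ravel()] = True
    degenerate = incident & (norms < 1e-300)
    if degenerate.any():
        bad = np.flatnonzero(degenerate)
        raise ValueError(
            f"vertex normal undefined (all incident faces degenerate) at vertices {bad[:10].tolist()}"
        )
    out = np.zeros_like(v)
    out[incident] = acc[incident] / norms[incident, None]
    return out


def face_adjacency(mesh: TriMesh) -> list[list[int]]:
    """Per-face list of faces sharing an edge ("cross-edge neighbors").

    On a closed manifold every face has exactly three neighbors; boundary
    edges contribute none. An edge shared by more than two faces raises
    :class:`NonManifoldError`.
    """
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        for e in ((a, b), (b, c), (c, a)):
            key = (int(min(e)), int(max(e)))
            owners = edge_faces.setdefault(key, [])
            owners.append(fi)
            if len(owners) > 2:
                raise NonManifoldError(f"edge {key} shared by more than two faces: {owners}")
    neighbors: list[list[int]] = [[] for _ in range(mesh.n_faces)]
    for owners in edge_faces.values():
        if len(owners) == 2:
            a, b = owners
            neighbors[a].append(b)
            neighbors[b].append(a)
    return [sorted(n) for n in neighbors]


def vertex_neighborhood(mesh: TriMesh, center: int, radius: float, k_max: int) -> np.ndarray:
    """Vertices strictly within Euclidean ``radius`` of ``center`` (the
    center itself excluded), capped at the ``k_max`` nearest.

    Ties in distance are broken by lowest vertex index.
    """
    if not (0 <= center < mesh.n_vertices):
        raise IndexError(f"center index {center} out of range")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    d = np.linalg.norm(mesh.positions - mesh.positions[center], axis=1)
    candidates = np.flatnonzero((d < radius) & (np.arange(mesh.n_vertices) != center))
    if len(candidates) > k_max:
        order = np.lexsort((candidates, d[candidates]))
        candidates = np.sort(candidates[order[:k_max]])
    return candidates


def graph_geodesic_distances(mesh: TriMesh, source: int, cutoff: float,
                             hop_metric: bool = False) -> dict[int, float]:
    """Shortest-path distances from ``source`` truncated at ``cutoff``.

    Edge weights are Euclidean edge lengths by default; with
    ``hop_metric=True`` every edge counts 1 (plain breadth-first distance).
    Vertices farther than the cutoff (or disconnected) are absent.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not (0 <= source < mesh.n_vertices):
        raise IndexError(f"source index {source} out of range")
    d = dijkstra(mesh.edge_graph, indices=source, limit=cutoff,
                 unweighted=hop_metric)
    reachable = np.flatnonzero(np.isfinite(d))
    return {int(i): float(d[i]) for i in reachable}


def _bfs_order(mesh: TriMesh, mask: np.ndarray | None = None) -> list[int]:
    """Breadth-first vertex order, per connected component, components and
    ties visited in ascending index order."""
    n = mesh.n_vertices
    graph = mesh.edge_graph
    indptr, indices = graph.indptr, graph.indices
    allowed = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    seen = ~allowed.copy()
    order: list[int] = []
    for start in range(n):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        while queue:
            u = queue.popleft()
            order.append(u)
            nbrs = indices[indptr[u]:indptr[u + 1]]
            for w in np.sort(nbrs):
                if not seen[w]:
                    seen[w] = True
                    queue.append(int(w))
    return order


def build_point_cover(mesh: TriMesh, rho: float, hop_metric: bool = False,
                      mask: np.ndarray | None = None) -> PointCover:
    """Greedy geodesic point cover.

    Vertices are visited in breadth-first order (from the lowest index of
    each connected component); a vertex joins the cover iff no existing
    cover vertex lies within graph distance ``rho``. The result both covers
    the mesh (every vertex within ``rho`` of the cover) and is packed (no
    two cover vertices within ``rho``). With ``mask`` the cover is built on
    the induced subgraph of the masked vertices only.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    graph = mesh.edge_graph
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        keep = np.flatnonzero(mask)
        sub = graph[np.ix_(keep, keep)].tocsr()
    else:
        keep = np.arange(mesh.n_vertices)
        sub = graph
    order = _bfs_order(mesh, mask)
    # positions in the submatrix for distance queries
    pos_of = {int(v): i for i, v in enumerate(keep)}
    min_dist = np.full(len(keep), np.inf)
    cover: list[int] = []
    for v in order:
        i = pos_of[v]
        if min_dist[i] < rho:
            continue
        cover.append(v)
        d = dijkstra(sub, indices=i, limit=rho, unweighted=hop_metric)
        np.minimum(min_dist, d, out=min_dist)
    return PointCover(np.asarray(cover, dtype=np.int64), float(rho))


def cover_distances(mesh: TriMesh, cover: PointCover, hop_metric: bool = False,
                    limit: float = np.inf) -> np.ndarray:
    """(|cover|, n_vertices) matrix of graph distances from each cover vertex."""
    return dijkstra(mesh.edge_graph, indices=cover.cover_indices,
                    limit=limit, unweighted=hop_metric)


def interpolate_cover_values(mesh: TriMesh, cover: PointCover,
                             cover_values: dict[int, float],
                             k_nearest: int = 3,
                             hop_metric: bool = False) -> np.ndarray:
    """Spread values known on the cover to every vertex.

    Inverse-graph-distance weighting (exponent 1) over the ``k_nearest``
    nearest cover vertices; exact at cover vertices themselves. Output is
    bounded by the range of the given values. Vertices unreachable from any
    cover vertex get NaN.
    """
    if len(cover) == 0:
        raise ValueError("empty cover")
    given = set(int(i) for i in cover.cover_indices)
    if set(map(int, cover_values)) != given:
        raise ValueError("cover_values must be keyed exactly by cover_indices")
    vals = np.array([cover_values[int(i)] for i in cover.cover_indices], dtype=np.float64)
    dmat = cover_distances(mesh, cover, hop_metric=hop_metric)  # (c, n)
    n = mesh.n_vertices
    out = np.full(n, np.nan)
    k = min(k_nearest, len(cover))
    # k smallest distances per vertex
    nearest = np.argpartition(dmat, k - 1, axis=0)[:k]  # (k, n)
    dn = np.take_along_axis(dmat, nearest, axis=0)
    vn = vals[nearest]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / dn
    finite_any = np.isfinite(dn).any(axis=0)
    exact = (dn == 0).any(axis=0)
    # exact hits: take the value at distance zero (cover vertex itself)
    exact_src = np.argmax(dn == 0, axis=0)
    w[~np.isfinite(w) & ~np.isfinite(dn)] = 0.0  # unreachable neighbors drop out
    w[np.isinf(dn)] = 0.0
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        blended = (w * vn).sum(axis=0) / wsum
    out[finite_any] = blended[finite_any]
    out[exact] = vn[exact_src[exact], np.arange(n)[exact]]
    return out
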