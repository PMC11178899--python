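"""Reading and writing surface meshes: STL in, colored PLY out.

STL stores an unindexed triangle soup, so reading always ends with a weld
that merges duplicated vertices. The default weld is exact bitwise
coordinate equality — STL exporters emit the same 32-bit coordinates for
shared vertices, and an epsilon weld risks collapsing genuinely close
anatomy (inner vs outer skull table). An optional tolerance weld is
available for meshes that need it.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .mesh_core import TriMesh


class STLParseError(ValueError):
    """Malformed STL file; the message names the offending byte offset."""


@dataclass
class RawMeshRecord:
    """A welded mesh as read from disk, with provenance."""

    vertex_positions: np.ndarray
    face_vertex_indices: np.ndarray
    source_path: str
    dialect: str  # "binary" | "ascii"

    def to_trimesh(self) -> TriMesh:
        return TriMesh(self.vertex_positions, self.face_vertex_indices)


def weld_vertices(soup_vertices: np.ndarray, soup_faces: np.ndarray,
                  tolerance: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Merge duplicate vertices of a triangle soup.

    ``tolerance == 0`` merges only bitwise-identical coordinates and is
    idempotent. A positive tolerance snaps coordinates to a grid of that
    pitch before comparing (approximate epsilon weld).
    """
    v = np.asarray(soup_vertices, dtype=np.float64)
    if tolerance > 0:
        key = np.round(v / tolerance)
    else:
        key = v
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    welded_v = v[first]  # representative = first occurrence of each key
    welded_f = inverse[np.asarray(soup_faces, dtype=np.int64)]
    return welded_v, welded_f


def _detect_dialect(path: Path) -> str:
    with open(path, "rb") as fh:
        head = fh.read(512)
    if not head.strip():
        raise STLParseError(f"{path}: empty file (0 bytes of content)")
    # ASCII STL starts with "solid", but so can a binary header; check that
    # the facet keyword appears too
    if head.lstrip().lower().startswith(b"solid") and b"facet" in head.lower():
        return "ascii"
    return "binary"


def _validate_binary_stl(path: Path) -> None:
    size = path.stat().st_size
    if size < 84:
        raise STLParseError(
            f"{path}: binary STL truncated at byte {size}; 84-byte header+count required")
    with open(path, "rb") as fh:
        fh.seek(80)
        (count,) = struct.unpack("<I", fh.read(4))
    expected = 84 + 50 * count
    if size != expected:
        raise STLParseError(
            f"{path}: facet count {count} implies {expected} bytes but file has {size}; "
            f"record stream ends at byte {min(size, expected)}")
    if count == 0:
        raise STLParseError(f"{path}: zero facets declared at byte 80")


def read_stl(path: str | Path, weld_tolerance: float = 0.0) -> RawMeshRecord:
    """Read a binary or ASCII STL file and weld its triangle soup.

    Face winding is preserved as stored; normals in the file are ignored
    and recomputed downstream from the winding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such STL file: {path}")
    dialect = _detect_dialect(path)
    if dialect == "binary":
        _validate_binary_stl(path)
    try:
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - trimesh internal formats vary
        raise STLParseError(f"{path}: unparseable STL ({exc})") from exc
    soup_v = np.asarray(mesh.vertices, dtype=np.float64)
    soup_f = np.asarray(mesh.faces, dtype=np.int64)
    if len(soup_f) == 0:
        raise STLParseError(f"{path}: mesh contains no facets")
    v, f = weld_vertices(soup_v, soup_f, tolerance=weld_tolerance)
    return RawMeshRecord(v, f, str(path), dialect)


def write_stl(mesh: RawMeshRecord | TriMesh, path: str | Path,
              dialect: str = "binary") -> Path:
    """Write a mesh as STL. Binary files are exactly 84 + 50*n_faces bytes."""
    path = Path(path)
    if isinstance(mesh, RawMeshRecord):
        v, f = mesh.vertex_positions, mesh.face_vertex_indices
    else:
        v, f = mesh.positions, mesh.faces
    if len(f) == 0:
        raise ValueError("refusing to write an empty mesh")
    tm = trimesh.Trimesh(vertices=v, faces=f, process=False)
    if dialect == "binary":
        data = tm.export(file_type="stl")
        path.write_bytes(data)
    elif dialect == "ascii":
        text = tm.export(file_type="stl_ascii")
        path.write_text(text)
    else:
        raise ValueError(f"unknown STL dialect {dialect!r} (binary|ascii)")
    return path


def _diverging_colors(values: np.ndarray) -> np.ndarray:
    """Map signed scalars to RGB via a diverging colormap centered at 0.

    Positive values are red, negative blue, zero the near-white midpoint;
    scaling is symmetric in max |value| so the midpoint never drifts. The
    map is built by hand rather than taken from a stock colormap so the
    red channel is strictly monotone in the scalar (stock diverging maps
    saturate, which destroys rank information in the rendered color).
    """
    v = np.asarray(values, dtype=np.float64)
    vmax = np.abs(v).max()
    t = np.full(len(v), 0.5) if vmax == 0 else 0.5 * (1.0 + v / vmax)
    # red: steep ramp to 235 over the blue half, gentle 235->255 over the
    # red half; blue mirrors it; green peaks at the midpoint
    red = np.minimum(np.round(470.0 * t), np.round(215.0 + 40.0 * t))
    blue = np.minimum(np.round(470.0 * (1.0 - t)), np.round(215.0 + 40.0 * (1.0 - t)))
    green = np.round(255.0 * (1.0 - np.abs(2.0 * t - 1.0)))
    return np.clip(np.column_stack([red, green, blue]), 0, 255).astype(np.uint8)


def write_colored_surface(mesh: RawMeshRecord | TriMesh, vertex_scalars: np.ndarray,
                          path: str | Path) -> Path:
    """Write a heat-map PLY: per-vertex RGB from the scalars plus the raw
    scalar stored as a float vertex property named ``gradient``.

    Red marks positive values (outward push raises the score), blue
    negative; the raw values survive a round-trip through
    :func:`read_colored_surface`.
    """
    path = Path(path)
    if isinstance(mesh, RawMeshRecord):
        v, f = mesh.vertex_positions, mesh.face_vertex_indices
    else:
        v, f = mesh.positions, mesh.faces
    scalars = np.asarray(vertex_scalars, dtype=np.float32).ravel()
    if len(scalars) != len(v):
        raise ValueError(f"need one scalar per vertex: {len(scalars)} != {len(v)}")
    tm = trimesh.Trimesh(vertices=v, faces=f, process=False)
    tm.visual.vertex_colors = np.hstack([
        _diverging_colors(scalars),
        np.full((len(v), 1), 255, dtype=np.uint8),
    ])
    tm.vertex_attributes["gradient"] = scalars
    data = trimesh.exchange.ply.export_ply(tm)  # binary little-endian
    path.write_bytes(data)
    return path


def read_colored_surface(path: str | Path) -> tuple[TriMesh, np.ndarray, np.ndarray]:
    """Read back a heat-map PLY: (mesh, gradient scalars, RGB colors)."""
    tm = trimesh.load(str(path), file_type="ply", process=False)
    raw = tm.metadata["_ply_raw"]["vertex"]["data"]
    scalars = np.asarray(raw["gradient"], dtype=np.float64).ravel()
    colors = np.asarray(tm.visual.vertex_colors[:, :3], dtype=np.uint8)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces)), scalars, colors


def dump_field_text(values: np.ndarray, path: str | Path) -> Path:
    """Two-column plain-text dump: vertex index, value."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, x in enumerate(np.asarray(values).ravel()):
            fh.write(f"{i}\t{x:.9g}\n")
    return path
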