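"""Mesh I/O and geometry primitives.

Everything downstream (synthetic hip generation, morphometry, shape
difference analysis) runs on triangle surface meshes in millimetres.  This
module provides the mesh container, STL/PLY reading and writing (through
:mod:`trimesh`), surface area and enclosed volume, rigid ICP alignment and
sagittal mirroring, plus the anatomical frame and rigid transform types the
rest of the package shares.

Conventions
-----------
* All coordinates are millimetres; areas mm^2, volumes mm^3.
* The canonical pose is a *left* hip in a right-handed frame with
  ``lateral = +x``, ``anterior = +y``, ``superior = +z``.  Right hips are
  mirrored into this pose before any bilateral comparison.
* Vertices are merged at 1e-6 mm on load (STL duplicates every vertex per
  facet); zero-area faces are dropped.
* Watertightness (every edge shared by exactly two consistently wound
  faces) is enforced only where a volume is computed — the acetabular inner
  surface is an open patch by nature.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "MeshError",
    "MeshFormatError",
    "EmptyMeshError",
    "WatertightnessError",
    "DegenerateInputError",
    "TriangleMesh",
    "AnatomicalFrame",
    "RigidTransform",
    "ICPResult",
    "read_mesh",
    "write_mesh",
    "surface_area",
    "mesh_volume",
    "boundary_edge_count",
    "is_watertight",
    "align_rigid",
    "mirror_sagittal",
]

#: Vertex-merge tolerance applied at load time (mm).
MERGE_TOL_MM = 1e-6
#: Faces with area below this (mm^2) are considered degenerate and dropped.
DEGENERATE_AREA_MM2 = 1e-10

_MERGE_DECIMALS = 6  # decimal places corresponding to MERGE_TOL_MM


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class MeshError(Exception):
    """Base class for mesh-related errors."""


class MeshFormatError(MeshError):
    """File could not be parsed as the requested mesh format."""


class EmptyMeshError(MeshError):
    """Mesh has no vertices or no faces."""


class WatertightnessError(MeshError):
    """Volume requested on a surface that does not enclose a solid."""

    def __init__(self, message: str, boundary_edges: int = 0):
        super().__init__(message)
        self.boundary_edges = boundary_edges


class DegenerateInputError(MeshError):
    """Input is geometrically degenerate for the requested operation."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Indexed triangle surface in mm, with optional per-vertex region labels.

    ``labels`` is an array of strings aligned with ``vertices``; the empty
    string means "unlabelled".  Region labels name anatomical patches
    (``"head"``, ``"cup"``, ``"neck"``, ``"shaft"``, ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshError("face indices out of range")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype="U32")
            if len(self.labels) != len(self.vertices):
                raise MeshError("labels length does not match vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def region_vertex_mask(self, regions) -> np.ndarray:
        if self.labels is None:
            raise MeshError("mesh carries no region labels")
        if isinstance(regions, str):
            regions = (regions,)
        return np.isin(self.labels, list(regions))

    def region_points(self, regions) -> np.ndarray:
        """Coordinates of all vertices labelled with any of ``regions``."""
        return self.vertices[self.region_vertex_mask(regions)]

    def submesh_from_faces(self, face_mask: np.ndarray) -> "TriangleMesh":
        """Extract the faces selected by ``face_mask``, compacting vertices."""
        faces = self.faces[np.asarray(face_mask)]
        used, inverse = np.unique(faces, return_inverse=True)
        return TriangleMesh(
            self.vertices[used],
            inverse.reshape(-1, 3),
            None if self.labels is None else self.labels[used],
        )

    def region_submesh(self, regions) -> "TriangleMesh":
        """Faces whose three vertices all belong to ``regions``."""
        mask = self.region_vertex_mask(regions)
        face_mask = mask[self.faces].all(axis=1)
        if not face_mask.any():
            raise EmptyMeshError(f"no faces entirely within regions {regions!r}")
        return self.submesh_from_faces(face_mask)

    def transformed(self, transform: "RigidTransform") -> "TriangleMesh":
        out = self.copy()
        out.vertices = transform.apply(out.vertices)
        if transform.is_reflecting:
            out.faces = out.faces[:, ::-1]
        return out

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin plus lateral/anterior/superior orthonormal right-handed axes."""

    origin: np.ndarray
    lateral: np.ndarray
    anterior: np.ndarray
    superior: np.ndarray

    def __post_init__(self):
        for name in ("origin", "lateral", "anterior", "superior"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64).reshape(3))
        axes = np.stack([self.lateral, self.anterior, self.superior])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise DegenerateInputError("anatomical frame axes are not orthonormal")
        if not np.allclose(np.cross(self.lateral, self.anterior), self.superior, atol=1e-9):
            raise DegenerateInputError("anatomical frame is not right-handed (lateral x anterior != superior)")

    @classmethod
    def canonical(cls, origin=(0.0, 0.0, 0.0)) -> "AnatomicalFrame":
        return cls(np.asarray(origin, float), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express world points as (lateral, anterior, superior) coordinates."""
        axes = np.stack([self.lateral, self.anterior, self.superior])
        return (np.atleast_2d(points) - self.origin) @ axes.T


@dataclass(frozen=True)
class RigidTransform:
    """Orthonormal linear map plus translation; improper only when mirrored.

    The linear part has determinant +1, or -1 if and only if ``mirror`` is
    set.  Points transform as ``p @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    mirror: bool = False

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=np.float64).reshape(3))
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise DegenerateInputError("rotation is not orthonormal")
        det = np.linalg.det(r)
        expected = -1.0 if self.mirror else 1.0
        if not np.isclose(det, expected, atol=1e-8):
            raise DegenerateInputError(
                f"rotation determinant {det:+.6f} inconsistent with mirror={self.mirror}")

    @property
    def is_reflecting(self) -> bool:
        return self.mirror

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            mirror=self.mirror != other.mirror,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, mirror=self.mirror)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("stl-binary", "stl-ascii", "ply")


def _canonical_clean(vertices: np.ndarray, faces: np.ndarray):
    """Merge duplicate vertices at MERGE_TOL_MM and drop degenerate faces.

    The resulting vertex order is a pure function of the input stream
    (merged vertices in first-occurrence order), so writer and reader agree
    on vertex indices for label sidecars, and meshes sharing a facet
    structure keep identical topology after a round trip.
    """
    rounded = np.round(np.asarray(vertices, float), _MERGE_DECIMALS)
    rounded[rounded == 0.0] = 0.0  # normalise -0.0
    uniq, first_idx, inverse = np.unique(rounded, axis=0, return_index=True,
                                         return_inverse=True)
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    uniq = uniq[order]
    inverse = rank[inverse.reshape(-1)]
    faces = inverse[np.asarray(faces, np.int64)].reshape(-1, 3)
    f = faces
    nondegenerate = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    faces = faces[nondegenerate]
    if len(faces):
        a, b, c = uniq[faces[:, 0]], uniq[faces[:, 1]], uniq[faces[:, 2]]
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        faces = faces[areas > DEGENERATE_AREA_MM2]
    return uniq, faces, inverse.reshape(-1)


def _sniff_stl_dialect(path: Path) -> str:
    with open(path, "rb") as fh:
        head = fh.read(512)
    if head.lstrip().startswith(b"solid"):
        try:
            text = head.decode("ascii")
        except UnicodeDecodeError:
            return "stl-binary"
        if "facet" in text or len(head) < 84:
            return "stl-ascii"
    return "stl-binary"


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix == ".ply":
        return "ply"
    if suffix == ".stl":
        return _sniff_stl_dialect(path)
    raise ValueError(f"cannot infer mesh format from {path.name!r}; pass format=")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".labels.json")


def read_mesh(path, format: str | None = None) -> TriangleMesh:
    """Read an STL (binary or ASCII) or ASCII PLY surface.

    Duplicate vertices are merged at 1e-6 mm and degenerate faces dropped.
    If a ``<name>.labels.json`` sidecar exists next to the file, per-vertex
    region labels are loaded from it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)

    if fmt == "stl-binary":
        size = os.path.getsize(path)
        if size < 84:
            raise MeshFormatError(
                f"{path}: truncated binary STL — need at least 84 bytes, file ends at byte {size}")
        with open(path, "rb") as fh:
            fh.seek(80)
            n_facets = int(np.frombuffer(fh.read(4), dtype="<u4")[0])
        expected = 84 + 50 * n_facets
        if size < expected:
            raise MeshFormatError(
                f"{path}: truncated binary STL — header promises {n_facets} facets "
                f"({expected} bytes) but file ends at byte {size}")

    try:
        loaded = trimesh.load(
            str(path), file_type="ply" if fmt == "ply" else "stl", process=False)
    except MeshFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise MeshFormatError(f"{path}: unreadable as {fmt}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"{path}: file contains no geometry")
        loaded = trimesh.util.concatenate(geoms)
    vertices = np.asarray(loaded.vertices, float)
    faces = np.asarray(loaded.faces, np.int64)
    if vertices.size == 0 or faces.size == 0:
        raise EmptyMeshError(f"{path}: empty mesh")

    vertices, faces, _ = _canonical_clean(vertices, faces)
    if faces.size == 0:
        raise EmptyMeshError(f"{path}: no non-degenerate faces after cleaning")

    labels = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        mapping = json.loads(sidecar.read_text())
        labels = np.full(len(vertices), "", dtype="U32")
        for key, name in mapping.items():
            idx = int(key)
            if 0 <= idx < len(vertices):
                labels[idx] = name
    return TriangleMesh(vertices, faces, labels)


def write_mesh(mesh: TriangleMesh, path, format: str = "stl-binary") -> None:
    """Write a mesh as binary/ASCII STL or ASCII PLY.

    STL carries no vertex attributes, so region labels are persisted to a
    ``<name>.labels.json`` sidecar keyed by the vertex indices the file will
    have after :func:`read_mesh` (merge-canonical order).
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write an empty mesh")
    path = Path(path)
    tm = mesh.to_trimesh()
    try:
        if format == "stl-binary":
            data = trimesh.exchange.stl.export_stl(tm)
            path.write_bytes(data)
        elif format == "stl-ascii":
            data = trimesh.exchange.stl.export_stl_ascii(tm)
            path.write_text(data)
        else:
            data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
            path.write_bytes(data)
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc

    if mesh.labels is not None and np.any(mesh.labels != ""):
        # Predict the vertex order read_mesh will produce (STL loses indexing;
        # float32 quantisation applies to the STL dialects).
        verts = mesh.vertices
        if format in ("stl-binary",):
            verts = verts.astype(np.float32).astype(np.float64)
        _, _, inverse = _canonical_clean(verts, mesh.faces)
        mapping = {}
        for old_idx, label in enumerate(mesh.labels):
            if label:
                # coincident vertices merge on read; the first label wins
                mapping.setdefault(str(int(inverse[old_idx])), str(label))
        _sidecar_path(path).write_text(
            json.dumps(mapping, sort_keys=True, indent=0) + "\n")


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def surface_area(mesh: TriangleMesh) -> float:
    """Total triangle area in mm^2."""
    if mesh.n_faces == 0:
        raise EmptyMeshError("surface_area of an empty mesh")
    return float(mesh.triangle_areas().sum())


def boundary_edge_count(mesh: TriangleMesh) -> int:
    """Number of edges not shared by exactly two faces."""
    edges = np.sort(np.concatenate([
        mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


def is_watertight(mesh: TriangleMesh) -> bool:
    tm = mesh.to_trimesh()
    return bool(tm.is_watertight and tm.is_winding_consistent)


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem; orientation-free.

    Raises :class:`WatertightnessError` for open or inconsistently wound
    surfaces, reporting the boundary-edge count.
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("mesh_volume of an empty mesh")
    tm = mesh.to_trimesh()
    if not (tm.is_watertight and tm.is_winding_consistent):
        n_bad = boundary_edge_count(mesh)
        raise WatertightnessError(
            f"mesh is not watertight: {n_bad} boundary/odd edges", boundary_edges=n_bad)
    return float(abs(tm.volume))


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    converged: bool
    n_iterations: int


def _kabsch(source: np.ndarray, target: np.ndarray):
    """Proper rotation + translation minimising ||R s + t - target||^2."""
    cs, ct = source.mean(axis=0), target.mean(axis=0)
    h = (source - cs).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, ct - r @ cs


def _pca_init_candidates(source: np.ndarray, target: np.ndarray):
    """Coarse alignments matching centroids and principal axes.

    ICP is a local method: a rotation about an axis of near-symmetry (e.g.
    the femoral head's own centre) can leave most nearest-neighbour pairs
    satisfied and stall the refinement.  Principal-axes matching gives an
    exact starting pose for congruent shapes; the four proper sign
    combinations are all returned (axis signs are ambiguous), along with
    the identity.
    """
    cs, ct = source.mean(axis=0), target.mean(axis=0)
    _, _, vs = np.linalg.svd(source - cs, full_matrices=False)
    _, _, vt = np.linalg.svd(target - ct, full_matrices=False)
    candidates = [RigidTransform.identity()]
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            signs = np.diag([sx, sy, sx * sy])  # proper combinations only
            r = vt.T @ signs @ vs
            if np.linalg.det(r) < 0:
                r = vt.T @ (signs @ np.diag([1.0, 1.0, -1.0])) @ vs
            candidates.append(RigidTransform(r, ct - r @ cs))
    return candidates


def align_rigid(
    source: TriangleMesh,
    target: TriangleMesh,
    init: RigidTransform | None = None,
    max_iterations: int = 200,
    rms_improvement_tol: float = 1e-8,
) -> ICPResult:
    """Point-to-point ICP refinement aligning source onto target.

    Nearest neighbours come from a KD-tree over the target vertices; the
    loop stops when the RMS nearest-neighbour distance improves by less than
    ``rms_improvement_tol`` mm.  With no ``init``, the start pose is chosen
    among centroid/principal-axes matches and the identity by lowest initial
    RMS.  A mirrored ``init`` is refined within the improper branch
    (incremental updates are proper rotations).
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise EmptyMeshError("align_rigid requires non-empty meshes")
    if init is None:
        candidates = _pca_init_candidates(source.vertices, target.vertices)
        tree0 = cKDTree(target.vertices)
        best_rms, init = np.inf, candidates[0]
        for cand in candidates:
            d, _ = tree0.query(cand.apply(source.vertices))
            rms0 = float(np.sqrt(np.mean(d**2)))
            if rms0 < best_rms:
                best_rms, init = rms0, cand
    pts = source.vertices
    tree = cKDTree(target.vertices)
    rot, trans = init.rotation.copy(), init.translation.copy()
    current = pts @ rot.T + trans
    prev_rms = np.inf
    rms = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        dists, idx = tree.query(current)
        rms = float(np.sqrt(np.mean(dists**2)))
        if prev_rms - rms < rms_improvement_tol:
            converged = True
            break
        prev_rms = rms
        r_d, t_d = _kabsch(current, target.vertices[idx])
        current = current @ r_d.T + t_d
        rot = r_d @ rot
        trans = r_d @ trans + t_d
    transform = RigidTransform(rot, trans, mirror=init.mirror)
    return ICPResult(transform, rms, converged, iterations)


def mirror_sagittal(mesh: TriangleMesh, frame: AnatomicalFrame) -> TriangleMesh:
    """Reflect across the sagittal plane (normal = lateral axis) through the
    frame origin; face winding is flipped so outward normals are preserved."""
    lat = frame.lateral
    out = mesh.copy()
    d = (out.vertices - frame.origin) @ lat
    out.vertices = out.vertices - 2.0 * d[:, None] * lat[None, :]
    out.faces = out.faces[:, ::-1]
    return out
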