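"""Triangle-mesh data model, file I/O, validation and elementary geometry.

The :class:`TriangleMesh` is the single carrier of geometry for the whole
package: a vertex array, an oriented triangle array (counterclockwise when
viewed from outside), and optional named per-vertex scalar fields.  File
access goes through :mod:`trimesh` so that OBJ/PLY/STL/OFF dialects are
handled by a battle-tested reader; the in-memory model stays a plain pair
of numpy arrays with no silent processing (no merging, no re-winding).

Indices are 0-based internally; OBJ's 1-based indices are converted at the
I/O boundary.  Coordinates are dimensionless lengths.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "RegionMask",
    "VertexField",
    "ValidationReport",
    "load_mesh",
    "save_mesh",
    "load_region_mask",
    "save_region_mask",
    "validate",
    "vertex_adjacency",
    "surface_area",
    "enclosed_volume",
]

_FORMATS = {"obj", "ply", "stl", "off"}


@dataclass
class VertexField:
    """One scalar per vertex (e.g. signed furrow depth, Gaussian curvature)."""

    values: np.ndarray
    name: str
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()


@dataclass
class RegionMask:
    """A named subset of vertex indices (cap / stalk / base, dome subregions...)."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.intp).ravel())
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_bool(self, n_vertices: int) -> np.ndarray:
        """Boolean membership vector of length ``n_vertices``."""
        if self.indices.size and (self.indices.min() < 0 or self.indices.max() >= n_vertices):
            raise ValueError(
                f"mask {self.name!r} has indices outside [0, {n_vertices})"
            )
        out = np.zeros(n_vertices, dtype=bool)
        out[self.indices] = True
        return out


@dataclass
class TriangleMesh:
    """Oriented triangle surface mesh.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array, counterclockwise seen from outside
    attributes : dict of named :class:`VertexField`
    name : free-text label
    """

    vertices: np.ndarray
    faces: np.ndarray
    attributes: dict[str, VertexField] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- basic counts ------------------------------------------------------
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
            {k: VertexField(v.values.copy(), v.name, v.units) for k, v in self.attributes.items()},
            self.name,
        )

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity and attributes, new vertex positions."""
        out = self.copy()
        out.vertices = np.ascontiguousarray(vertices, dtype=np.float64).reshape(-1, 3)
        if len(out.vertices) != self.n_vertices:
            raise ValueError("vertex count must not change")
        return out

    def set_field(self, fld: VertexField) -> None:
        if len(fld.values) != self.n_vertices:
            raise ValueError(
                f"field {fld.name!r} has {len(fld.values)} values for {self.n_vertices} vertices"
            )
        self.attributes[fld.name] = fld

    # -- derived connectivity ---------------------------------------------
    def edges_unique(self) -> np.ndarray:
        """(E, 2) array of undirected edges, each row sorted, rows unique."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def boundary_edges(self) -> np.ndarray:
        """Undirected edges with exactly one incident face, as (B, 2) sorted rows."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_vertices(self) -> np.ndarray:
        """Sorted vertex indices lying on any boundary edge."""
        be = self.boundary_edges()
        return np.unique(be.ravel()) if len(be) else np.empty(0, dtype=np.int64)

    def boundary_loop(self) -> np.ndarray:
        """The single boundary polyline as an ordered cycle of vertex indices.

        Raises if the mesh is closed or has more than one boundary loop.
        """
        directed = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        und = np.sort(directed, axis=1)
        uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        bmask = counts[inv] == 1
        bdir = directed[bmask]
        if len(bdir) == 0:
            raise ValueError("mesh is closed: no boundary loop")
        # boundary directed edges form cycles; walk one
        nxt = {int(u): int(v) for u, v in bdir}
        start = int(bdir[0, 0])
        loop = [start]
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            cur = nxt[cur]
            if len(loop) > len(bdir):
                raise ValueError("boundary is not a single simple loop")
        if len(loop) != len(bdir):
            raise ValueError(f"mesh has more than one boundary loop ({len(bdir)} boundary edges)")
        return np.asarray(loop, dtype=np.int64)

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalized:
            ln = np.linalg.norm(n, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                n = np.where(ln > 0, n / ln, 0.0)
        return n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, normalized."""
        fn = self.face_normals(normalized=False)  # magnitude = 2 * area
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        ln = np.linalg.norm(vn, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ln > 0, vn / ln, 0.0)

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of incident face areas."""
        fa = self.face_areas() / 3.0
        va = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(va, self.faces[:, k], fa)
        return va


@dataclass
class ValidationReport:
    manifold: bool
    oriented: bool
    closed: bool
    n_vertices: int
    n_edges: int
    n_faces: int
    euler_characteristic: int
    offending_edges: np.ndarray
    degenerate_faces: np.ndarray

    @property
    def ok(self) -> bool:
        return self.manifold and self.oriented and len(self.degenerate_faces) == 0


def validate(mesh: TriangleMesh, area_eps: float = 1e-12) -> ValidationReport:
    """Check manifoldness, orientation consistency, closedness and Euler count.

    Reports rather than raises; degenerate (zero-area) faces are listed,
    never repaired.
    """
    f = mesh.faces
    bad_index = (f.min() < 0) or (f.max() >= mesh.n_vertices) if len(f) else False
    if bad_index:
        raise ValueError("face indices out of range")
    if len(f) and np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 2] == f[:, 0])):
        raise ValueError("a face repeats a vertex")

    directed = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)

    manifold = bool(np.all(counts <= 2))
    closed = bool(np.all(counts == 2))
    offending = uniq[counts > 2]

    # orientation: no directed edge may appear twice
    d_uniq, d_counts = np.unique(directed, axis=0, return_counts=True)
    oriented = bool(np.all(d_counts == 1))
    if not oriented:
        offending = np.unique(np.vstack([offending, np.sort(d_uniq[d_counts > 1], axis=1)]), axis=0)

    areas = mesh.face_areas()
    degenerate = np.flatnonzero(areas <= area_eps)

    V, E, F = mesh.n_vertices, len(uniq), mesh.n_faces
    return ValidationReport(
        manifold=manifold,
        oriented=oriented,
        closed=closed,
        n_vertices=V,
        n_edges=E,
        n_faces=F,
        euler_characteristic=V - E + F,
        offending_edges=offending,
        degenerate_faces=degenerate,
    )


def vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """Per-vertex sorted arrays of neighboring vertex indices.

    Symmetric by construction (edges are undirected)."""
    e = mesh.edges_unique()
    nbr: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(mesh.n_vertices)]
    both = np.vstack([e, e[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    starts = np.searchsorted(both[:, 0], np.arange(mesh.n_vertices + 1))
    for i in range(mesh.n_vertices):
        nbr[i] = both[starts[i] : starts[i + 1], 1]
    return nbr


def surface_area(mesh: TriangleMesh) -> float:
    """Total area as the sum of triangle areas."""
    return float(mesh.face_areas().sum())


def enclosed_volume(
    mesh: TriangleMesh, closure_centroid: np.ndarray | None = None
) -> float:
    """Signed volume enclosed by a consistently oriented closed mesh.

    Computed as ``(1/6) * sum_f det(p0, p1, p2)``; positive when faces wind
    counterclockwise seen from outside.  Open meshes raise unless
    ``closure_centroid`` is given, in which case the single boundary loop is
    closed by an implicit triangle fan to that point (the pinned-base
    convention used by the inflation module for drumhead fixtures).
    """
    v = mesh.vertices
    f = mesh.faces
    vol = float(np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)
    be = mesh.boundary_edges()
    if len(be) == 0:
        return vol
    if closure_centroid is None:
        raise ValueError(
            f"mesh is open ({len(be)} boundary edges, e.g. {be[:5].tolist()}); "
            "pass closure_centroid to use the pinned-base fan closure"
        )
    # fan triangles must wind opposite to the boundary's directed edges
    directed = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    bdir = directed[counts[inv] == 1]
    c = np.asarray(closure_centroid, dtype=np.float64).reshape(3)
    # triangle (v, u, c) for each boundary directed edge (u, v)
    a = v[bdir[:, 1]]
    b = v[bdir[:, 0]]
    vol += float(np.einsum("ij,ij->i", a, np.cross(b, np.broadcast_to(c, a.shape))).sum() / 6.0)
    return vol


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        fmt = fmt.lower()
        if fmt not in _FORMATS:
            raise ValueError(f"unsupported format {fmt!r}; expected one of {sorted(_FORMATS)}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in _FORMATS:
        raise ValueError(f"cannot infer mesh format from suffix {path.suffix!r}")
    return suffix


def load_mesh(path: str | Path, format: str = "auto", triangulate: bool = False) -> TriangleMesh:
    """Read a surface mesh from OBJ / PLY / STL / OFF.

    Non-triangular faces are rejected unless ``triangulate=True``, in which
    case they are fan-triangulated with a warning.  Duplicate vertices are
    left untouched.  Per-vertex scalar properties and RGB colors found in a
    PLY file are attached as attribute fields (colors as ``red``, ``green``,
    ``blue`` in 0..255).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    faces = np.asarray(tm.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        if not triangulate:
            raise ValueError(
                f"{path} contains non-triangular faces; pass triangulate=True to fan-triangulate"
            )
        warnings.warn(f"fan-triangulating non-triangular faces in {path}", stacklevel=2)
        tm = trimesh.load(str(path), file_type=fmt, process=True, force="mesh")
        faces = np.asarray(tm.faces)
    mesh = TriangleMesh(np.asarray(tm.vertices, dtype=np.float64), faces, name=path.stem)

    # recover PLY per-vertex scalar properties beyond x, y, z
    raw = tm.metadata.get("_ply_raw") if hasattr(tm, "metadata") else None
    if raw and "vertex" in raw:
        vdata = raw["vertex"]["data"]
        names = vdata.dtype.names or ()
        for prop in names:
            if prop in ("x", "y", "z", "alpha"):
                continue
            col = np.asarray(vdata[prop], dtype=np.float64).ravel()
            if len(col) == mesh.n_vertices:
                mesh.set_field(VertexField(col, prop))
    return mesh


_CLASS_COLORS = {1: (220, 40, 40), -1: (60, 80, 220), 0: (160, 160, 160)}  # ridge/valley/neutral


def save_mesh(
    mesh: TriangleMesh,
    path: str | Path,
    format: str = "auto",
    fields: list[str] | None = None,
) -> None:
    """Write a mesh; PLY embeds the requested scalar fields as vertex properties.

    When a field named ``furrow_class`` exists (values +1 ridge, -1 valley,
    0 neutral) it is additionally exported as RGB vertex colors: ridge red,
    valley blue, neutral gray.  STL and OFF cannot carry vertex fields; a
    warning is emitted and the fields dropped.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fields is None:
        fields = []
    for name in fields:
        if name not in mesh.attributes:
            raise KeyError(f"field {name!r} not present on mesh")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if fields and fmt in ("stl", "off"):
        warnings.warn(f"{fmt.upper()} cannot embed vertex fields; dropping {fields}", stacklevel=2)
        fields = []
    if fmt == "ply":
        for name in fields:
            tm.vertex_attributes[name] = mesh.attributes[name].values.astype(np.float64)
        if "furrow_class" in mesh.attributes:
            cls = np.rint(mesh.attributes["furrow_class"].values).astype(int)
            rgba = np.empty((mesh.n_vertices, 4), dtype=np.uint8)
            rgba[:, 3] = 255
            for value, color in _CLASS_COLORS.items():
                rgba[cls == value, :3] = color
            tm.visual.vertex_colors = rgba
    tm.export(str(path), file_type=fmt)


def load_region_mask(path: str | Path, name: str | None = None) -> RegionMask:
    """Read a plain-text mask: one vertex index per line, ``#`` comments allowed."""
    path = Path(path)
    indices: list[int] = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            indices.append(int(line))
    return RegionMask(name or path.stem, np.asarray(indices, dtype=np.int64))


def save_region_mask(mask: RegionMask, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# region mask: {mask.name} ({len(mask)} vertices)"]
    lines += [str(int(i)) for i in mask.indices]
    path.write_text("\n".join(lines) + "\n")
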