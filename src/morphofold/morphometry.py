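"""Morphometrics of the three transformation modes: elongation, angular
change, branching — plus curvature diagnostics.

All measurements use the package-wide anatomical frame: +Z proximodistal
(distal up), +Y dorsal, +X the animal's left.  A positive bend angle means
the distal end is tipped dorsally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .mesh import RegionMask, TriangleMesh, VertexField, surface_area, enclosed_volume

__all__ = [
    "MorphometryReport",
    "axial_extent",
    "centerline",
    "bend_angle",
    "count_branches",
    "groove_angle",
    "apex_offset",
    "discrete_gaussian_curvature",
    "measure",
]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class MorphometryReport:
    """Named scalar measurements of one mesh (lengths dimensionless)."""

    axial_extent: float
    dorsoventral_extent: float
    lateral_extent: float
    bend_angle: float | None
    branch_count: int
    groove_angle: float | None
    apex_offset: float | None
    area: float
    volume: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def axial_extent(mesh: TriangleMesh, axis: np.ndarray = _Z) -> float:
    """Extent (max - min) of vertex projections on a unit axis."""
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    proj = mesh.vertices @ axis
    return float(proj.max() - proj.min())


def centerline(mesh: TriangleMesh, axis: np.ndarray = _Z, n_slices: int = 20) -> np.ndarray:
    """Polyline of slab centroids marched from the proximal end.

    Starting from the area-weighted centroid of the proximal 5% band of
    the axis projection, the tracer repeatedly takes the centroid of the
    vertices in a slab one step ahead *along the current local direction*
    and re-orients toward it.  The step length is the mesh's maximal
    geodesic (surface graph) distance from the proximal band divided by
    ``n_slices``, so the node count is comparable for straight and bent
    tubes.  Marching follows the tube through arbitrary bends, which
    fixed-axis slabs cannot (past ~45 degrees of bend a fixed-axis slab
    mixes both arms).  Not meant for self-approaching (U-shaped) tubes.
    """
    if n_slices < 3:
        raise ValueError("n_slices must be >= 3")
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    v = mesh.vertices
    proj = v @ axis
    span = proj.max() - proj.min()
    if span <= 0:
        raise ValueError("mesh has zero extent along the axis")
    va = mesh.vertex_areas()
    seed = proj <= proj.min() + 0.05 * span
    p = np.average(v[seed], axis=0, weights=va[seed])

    # geodesic length scale from the proximal band
    e = mesh.edges_unique()
    w = np.linalg.norm(v[e[:, 1]] - v[e[:, 0]], axis=1)
    n = mesh.n_vertices
    g = sp.csr_matrix(
        (
            np.concatenate([w, w]),
            (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]])),
        ),
        shape=(n, n),
    )
    from scipy.sparse.csgraph import dijkstra

    dist = dijkstra(g, directed=False, indices=np.flatnonzero(seed), min_only=True)
    finite = np.isfinite(dist)
    if not finite.all():
        raise ValueError("mesh is not connected")
    h = dist.max() / n_slices
    if h <= 0:
        raise ValueError("degenerate geodesic span")

    d = axis.copy()
    nodes = [p]
    for _ in range(4 * n_slices):
        t = (v - p) @ d
        sel = (t > 0.25 * h) & (t <= 1.75 * h)
        if sel.sum() < 3 or va[sel].sum() <= 0:
            break
        c = np.average(v[sel], axis=0, weights=va[sel])
        dn = c - p
        ln = np.linalg.norm(dn)
        if ln < 1e-12 * h:
            break
        dn = dn / ln
        if dn @ d < np.cos(np.radians(45.0)):
            break  # sharper than the tracer trusts: end of tube (cap rim)
        # smooth the heading: single-step secants wobble when the tube is
        # thicker than the step length
        d = 0.5 * d + 0.5 * dn
        d = d / np.linalg.norm(d)
        p = c
        nodes.append(c)
    if len(nodes) < 3:
        raise ValueError("fewer than 3 centerline nodes could be traced")
    return np.asarray(nodes)


def _end_tangents(nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tangents of a centerline at its two ends.

    Fits each coordinate as a cubic in arc length over the whole polyline
    and differentiates at the endpoints.  A global smooth fit averages out
    the node-placement noise of the slab tracer, and unlike a per-chunk
    least-squares *line* it does not average the tangent over the chunk —
    which would bias the measured bend of a 90-degree arc low by over 20
    degrees."""
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate (zero-length) centerline")
    deg = min(3, len(nodes) - 1)
    coef = [np.polyder(np.polyfit(s, nodes[:, k], deg)) for k in range(3)]
    out = []
    for at in (0.0, s[-1]):
        tangent = np.array([np.polyval(c, at) for c in coef])
        n = np.linalg.norm(tangent)
        if n < 1e-12:
            raise ValueError("degenerate (zero-length) end tangent")
        out.append(tangent / n)
    return out[0], out[1]


def bend_angle(line: np.ndarray) -> float:
    """Signed bend of a centerline in the sagittal (Y-Z) plane, degrees.

    Angle between the tangent at the proximal end and the tangent at the
    distal end of a cubic fit through the centerline nodes, both projected
    to the Y-Z plane; the sign follows the dorsoventral (Y) component of
    the distal direction relative to the proximal one, positive = distal
    end tipped dorsally (+Y).
    """
    line = np.asarray(line, dtype=np.float64)
    if len(line) < 3:
        raise ValueError("need at least 3 centerline nodes")
    d_prox, d_dist = _end_tangents(line)
    # project to Y-Z
    p = d_prox[[1, 2]]
    q = d_dist[[1, 2]]
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ < 1e-12 or nq < 1e-12:
        raise ValueError("degenerate (axis-normal) segment direction")
    p, q = p / np_, q / nq
    # signed angle from proximal to distal in the (y, z) plane; with the
    # proximal direction ~ +z, a distal tilt toward +y is positive
    ang = np.degrees(np.arctan2(p[1] * q[0] - p[0] * q[1], p @ q))
    return float(ang)


def count_branches(
    mesh: TriangleMesh,
    axis: np.ndarray = _Z,
    height_fraction: float = 0.6,
    min_component: int = 5,
) -> int:
    """Number of branch tips: connected components of the super-level set.

    Counts components of the vertex subgraph above
    ``height_fraction * (max - min)`` of the axis projection, discarding
    components with fewer than ``min_component`` vertices as noise.
    """
    if not (0.0 < height_fraction < 1.0):
        raise ValueError("height_fraction must be in (0, 1)")
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    proj = mesh.vertices @ axis
    cut = proj.min() + height_fraction * (proj.max() - proj.min())
    keep = proj >= cut
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        return 0
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    e = mesh.edges_unique()
    sel = keep[e[:, 0]] & keep[e[:, 1]]
    rows = remap[e[sel, 0]]
    cols = remap[e[sel, 1]]
    g = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(idx), len(idx))
    )
    n_comp, labels = connected_components(g, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return int((sizes >= min_component).sum())


def _section_polylines(mesh: TriangleMesh, axis: np.ndarray, position: float):
    """Cross-section of the mesh with the plane axis . x = position.

    Returns a list of ``(points, normals)`` pairs: the chained polyline and
    the outward surface normal (from the faces the plane cut) at each node.
    """
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    origin = position * axis
    segments, face_idx = trimesh.intersections.mesh_plane(
        tm, axis, origin, return_faces=True
    )
    if len(segments) == 0:
        return []
    fnormals = mesh.face_normals()[face_idx]
    # chain segments into polylines by matching endpoints
    pts = segments.reshape(-1, 3)
    key = np.round(pts / (1e-9 + 1e-6 * np.abs(pts).max()), 0)
    _, ids = np.unique(key, axis=0, return_inverse=True)
    ids = ids.reshape(-1, 2)
    coords: dict[int, np.ndarray] = {}
    adj: dict[int, list[int]] = {}
    nsum: dict[int, np.ndarray] = {}
    for (a, b), seg, fn in zip(ids, segments, fnormals):
        coords[a], coords[b] = seg[0], seg[1]
        for c in (a, b):
            nsum[c] = nsum.get(c, np.zeros(3)) + fn
        if a == b:
            continue
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    seen: set[int] = set()
    lines = []
    has_open_end = any(len(v) == 1 for v in adj.values())
    for start in adj:
        if start in seen or len(adj[start]) > 2:
            continue
        if len(adj[start]) == 2 and has_open_end:
            continue  # prefer starting at open ends
        chain = [start]
        seen.add(start)
        cur = start
        while True:
            nxt = [n for n in adj.get(cur, []) if n not in seen]
            if not nxt:
                break
            cur = nxt[0]
            chain.append(cur)
            seen.add(cur)
        if len(chain) >= 3:
            p = np.asarray([coords[c] for c in chain])
            nrm = np.asarray([nsum[c] for c in chain])
            ln = np.linalg.norm(nrm, axis=1, keepdims=True)
            nrm = np.where(ln > 0, nrm / ln, 0.0)
            lines.append((p, nrm))
    return lines


def groove_angle(
    mesh: TriangleMesh,
    slice_axis: np.ndarray = np.array([0.0, 1.0, 0.0]),
    slice_position: float | None = None,
    max_groove_degrees: float = 172.0,
) -> float | None:
    """Opening angle (degrees) of the sharpest groove in one cross-section.

    The mesh is sliced by the plane normal to ``slice_axis`` (default at
    the mid-position of its projection span).  On the longest section
    polyline, every node gets the interior angle between the two tangent
    arms taken 10% of the section arc length to each side.  A node is a
    *groove* candidate when the wedge between the arms opens toward the
    outward surface normal (a valley, not a ridge); the sharpest such
    angle is returned.  ``None`` when no concave node turns more than
    ``180 - max_groove_degrees`` degrees (e.g. a smooth convex cylinder).
    """
    axis = np.asarray(slice_axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    proj = mesh.vertices @ axis
    if slice_position is None:
        slice_position = 0.5 * (proj.max() + proj.min())
    lines = _section_polylines(mesh, axis, slice_position)
    if not lines:
        raise ValueError("slicing plane does not intersect the mesh")
    line, normals = max(lines, key=lambda l: len(l[0]))
    # in-plane 2D coordinates
    u = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(axis, [0.0, 1.0, 0.0])
    u = u / np.linalg.norm(u)
    v = np.cross(axis, u)
    p2 = np.stack([line @ u, line @ v], axis=1)
    n2 = np.stack([normals @ u, normals @ v], axis=1)

    seg = np.linalg.norm(np.diff(p2, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return None
    diam = np.linalg.norm(p2.max(axis=0) - p2.min(axis=0))
    closed = np.linalg.norm(p2[0] - p2[-1]) < 0.05 * diam

    def point_at(target: float) -> np.ndarray:
        if closed:
            target = target % total
        target = np.clip(target, 0.0, total)
        j = int(np.clip(np.searchsorted(s, target), 1, len(s) - 1))
        t = (target - s[j - 1]) / max(s[j] - s[j - 1], 1e-30)
        return p2[j - 1] + t * (p2[j] - p2[j - 1])

    delta = 0.1 * total
    best: float | None = None
    for k in range(len(p2)):
        if not closed and (s[k] < delta or s[k] > total - delta):
            continue
        a = point_at(s[k] - delta) - p2[k]
        b = point_at(s[k] + delta) - p2[k]
        la, lb = np.linalg.norm(a), np.linalg.norm(b)
        if la < 1e-12 or lb < 1e-12:
            continue
        cosang = np.clip((a @ b) / (la * lb), -1.0, 1.0)
        ang = float(np.degrees(np.arccos(cosang)))
        if ang > max_groove_degrees:
            continue
        # concave (groove) iff the wedge opens along the outward normal
        bis = a / la + b / lb
        if bis @ n2[k] <= 0:
            continue
        if best is None or ang < best:
            best = ang
    return best


def apex_offset(mesh: TriangleMesh, base_ring: RegionMask) -> float:
    """Lateral offset of the highest point, in units of the base radius.

    ``base_ring`` is the pinned boundary ring defining the base plane.  The
    highest vertex is the one farthest from the base plane along its normal
    (oriented toward the mesh interior); the offset is its in-plane
    distance from the ring centroid divided by the ring's mean radius.
    An upright cone scores ~0, an oblique overhanging cone well above 0.
    """
    ring = mesh.vertices[base_ring.indices]
    if len(ring) < 3:
        raise ValueError("base ring needs at least 3 vertices")
    c = ring.mean(axis=0)
    # plane normal = smallest principal direction of the ring
    _, _, vt = np.linalg.svd(ring - c)
    n = vt[-1]
    h = (mesh.vertices - c) @ n
    if np.abs(h.max()) < np.abs(h.min()):
        n, h = -n, -h
    if h.max() <= 0:
        raise ValueError("no vertices above the base plane")
    top = mesh.vertices[int(np.argmax(h))]
    lateral = (top - c) - ((top - c) @ n) * n
    mean_radius = float(np.linalg.norm(ring - c, axis=1).mean())
    return float(np.linalg.norm(lateral) / mean_radius)


def discrete_gaussian_curvature(mesh: TriangleMesh) -> VertexField:
    """Angle-deficit Gaussian curvature, 1/length^2.

    Interior vertices: ``K_i = (2 pi - sum of incident face angles) / A_i``
    with ``A_i`` one third of the incident face areas; boundary vertices
    use ``pi`` instead of ``2 pi``.  For any closed mesh the total deficit
    equals ``2 pi chi`` exactly (combinatorial Gauss-Bonnet); for a
    developable surface such as a cylinder wall the interior deficit is
    zero.
    """
    v = mesh.vertices
    f = mesh.faces
    angsum = np.zeros(mesh.n_vertices)
    for k in range(3):
        a = v[f[:, k]]
        b = v[f[:, (k + 1) % 3]]
        c = v[f[:, (k + 2) % 3]]
        u1 = b - a
        u2 = c - a
        cosang = np.einsum("ij,ij->i", u1, u2) / (
            np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1)
        )
        np.add.at(angsum, f[:, k], np.arccos(np.clip(cosang, -1.0, 1.0)))
    areas = mesh.vertex_areas()
    if np.any(areas <= 0):
        raise ValueError("vertex with zero-area neighborhood")
    full = np.full(mesh.n_vertices, 2.0 * np.pi)
    bverts = mesh.boundary_vertices()
    full[bverts] = np.pi
    return VertexField((full - angsum) / areas, "gaussian_curvature", "1/length^2")


def measure(
    mesh: TriangleMesh,
    base_ring: RegionMask | None = None,
    branch_height_fraction: float = 0.6,
    groove_slice_axis: np.ndarray | None = None,
    n_slices: int = 20,
) -> MorphometryReport:
    """Full morphometric report of one mesh.

    Bend angle / volume / groove angle / apex offset are set to ``None``
    where undefined (too flat for a centerline, open without base ring,
    no groove found).
    """
    v = mesh.vertices
    try:
        line = centerline(mesh, n_slices=n_slices)
        bend = bend_angle(line)
    except ValueError:
        bend = None
    closed = len(mesh.boundary_edges()) == 0
    if closed:
        vol = enclosed_volume(mesh)
    elif base_ring is not None:
        vol = enclosed_volume(mesh, closure_centroid=v[base_ring.indices].mean(axis=0))
    else:
        vol = None
    try:
        groove = groove_angle(
            mesh,
            groove_slice_axis if groove_slice_axis is not None else np.array([0.0, 1.0, 0.0]),
        )
    except ValueError:
        groove = None
    offset = None
    if base_ring is not None:
        try:
            offset = apex_offset(mesh, base_ring)
        except ValueError:
            offset = None
    return MorphometryReport(
        axial_extent=axial_extent(mesh),
        dorsoventral_extent=axial_extent(mesh, np.array([0.0, 1.0, 0.0])),
        lateral_extent=axial_extent(mesh, np.array([1.0, 0.0, 0.0])),
        bend_angle=bend,
        branch_count=count_branches(mesh, height_fraction=branch_height_fraction),
        groove_angle=groove,
        apex_offset=offset,
        area=surface_area(mesh),
        volume=vol,
    )
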