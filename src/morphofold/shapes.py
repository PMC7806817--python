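"""Seeded parametric generators of folded test meshes.

Real horn-primordium scans are not publicly deposited, so every pipeline
stage is exercised on synthetic meshes that emulate the salient folded
structures of the primordium: an accordion-pleated cylinder (the elongating
stalk), a tube with ventrally biased circumferential furrows (the
orientation-setting base), furrowed disks with concentric full-circle /
semicircle / parallel patterns (the simplified cone models), a Yoshimura
zigzag cylinder (passive axial buckling), and a dome "cap" with lateral
macro-lobes plus medial semicircular furrow patches (the branch-forming
region).  Plain primitives double as analytic oracles for the
morphometrics.

All furrows are sinusoidal displacements along local normals: the real
furrow cross-section is unknown and a sinusoid makes the ridge/valley sign
analytically checkable.  Generators are deterministic given their
parameters (the optional ``jitter``/``seed`` pair adds reproducible vertex
noise); every output passes :func:`morphofold.mesh.validate`.
"""

from __future__ import annotations

import numpy as np

from .mesh import RegionMask, TriangleMesh, enclosed_volume

__all__ = [
    "make_primitive",
    "make_accordion_cylinder",
    "make_furrowed_disk",
    "make_yoshimura_cylinder",
    "make_biased_base",
    "make_cap_model",
    "make_notched_plate",
    "make_corrugated_plate",
    "make_corrugated_sphere",
    "make_bent_tube",
]


# ---------------------------------------------------------------------------
# structured-grid helpers
# ---------------------------------------------------------------------------

def _grid_faces(n_rows: int, n_cols: int, wrap_cols: bool) -> np.ndarray:
    """Triangulate an (n_rows x n_cols) vertex grid, optionally periodic in cols.

    Vertex (i, j) has index i * n_cols + j.  Faces wind counterclockwise for
    a surface whose outward normal is (d_col x d_row)."""
    i = np.arange(n_rows - 1)
    j = np.arange(n_cols if wrap_cols else n_cols - 1)
    jj, ii = np.meshgrid(j, i)
    j1 = (jj + 1) % n_cols if wrap_cols else jj + 1
    v00 = ii * n_cols + jj
    v01 = ii * n_cols + j1
    v10 = (ii + 1) * n_cols + jj
    v11 = (ii + 1) * n_cols + j1
    f1 = np.stack([v00, v01, v10], axis=-1).reshape(-1, 3)
    f2 = np.stack([v01, v11, v10], axis=-1).reshape(-1, 3)
    return np.vstack([f1, f2])


def _revolve(
    profile_r: np.ndarray,
    profile_z: np.ndarray,
    n_theta: int,
    cap_bottom: bool,
    cap_top: bool,
    name: str = "",
) -> TriangleMesh:
    """Revolve an r(z) profile about +Z into a triangulated surface.

    Profile nodes must all have r > 0; caps are center-vertex fans.  The
    result is oriented outward (checked by signed volume when closed)."""
    profile_r = np.asarray(profile_r, dtype=np.float64)
    profile_z = np.asarray(profile_z, dtype=np.float64)
    if np.any(profile_r <= 0):
        raise ValueError("profile radii must be positive")
    n_rows = len(profile_r)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    verts = np.empty((n_rows, n_theta, 3))
    verts[:, :, 0] = profile_r[:, None] * ct[None, :]
    verts[:, :, 1] = profile_r[:, None] * st[None, :]
    verts[:, :, 2] = profile_z[:, None]
    vertices = verts.reshape(-1, 3)
    faces = _grid_faces(n_rows, n_theta, wrap_cols=True)
    extra_v = []
    extra_f = []
    nv = len(vertices)
    if cap_bottom:
        extra_v.append([0.0, 0.0, profile_z[0]])
        c = nv + len(extra_v) - 1
        j = np.arange(n_theta)
        j1 = (j + 1) % n_theta
        extra_f.append(np.stack([np.full(n_theta, c), j1, j], axis=-1))
    if cap_top:
        extra_v.append([0.0, 0.0, profile_z[-1]])
        c = nv + len(extra_v) - 1
        base = (n_rows - 1) * n_theta
        j = base + np.arange(n_theta)
        j1 = base + (np.arange(n_theta) + 1) % n_theta
        extra_f.append(np.stack([np.full(n_theta, c), j, j1], axis=-1))
    if extra_v:
        vertices = np.vstack([vertices, np.asarray(extra_v)])
        faces = np.vstack([faces] + extra_f)
    mesh = TriangleMesh(vertices, faces, name=name)
    if cap_bottom and cap_top:
        if enclosed_volume(mesh) < 0:
            mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh


def _halves_masks(mesh: TriangleMesh) -> dict[str, RegionMask]:
    y = mesh.vertices[:, 1]
    return {
        "ventral": RegionMask("ventral", np.flatnonzero(y < 0)),
        "dorsal": RegionMask("dorsal", np.flatnonzero(y >= 0)),
    }


def _apply_jitter(mesh: TriangleMesh, jitter: float, seed: int) -> None:
    if jitter > 0:
        rng = np.random.default_rng(seed)
        mesh.vertices = mesh.vertices + jitter * rng.standard_normal(mesh.vertices.shape)


# ---------------------------------------------------------------------------
# primitives (oracles)
# ---------------------------------------------------------------------------

def make_primitive(
    kind: str,
    *,
    radius: float = 1.0,
    height: float = 4.0,
    side: float = 1.0,
    subdivisions: int = 3,
    major_radius: float = 2.0,
    arc_degrees: float = 90.0,
    n_theta: int = 24,
    n_axial: int = 16,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[TriangleMesh, dict[str, RegionMask]]:
    """Closed analytic primitives with ventral/dorsal half masks.

    kind is one of ``sphere`` (icosphere), ``cylinder`` (capped),
    ``cube``, ``cone`` (capped), ``torus_segment`` (capped tube bending
    from +Z toward +Y over ``arc_degrees``).
    """
    if kind == "sphere":
        import trimesh

        tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), name="sphere")
    elif kind == "cylinder":
        z = np.linspace(0.0, height, n_axial + 1)
        r = np.full_like(z, radius)
        mesh = _revolve(r, z, n_theta, cap_bottom=True, cap_top=True, name="cylinder")
    elif kind == "cube":
        import trimesh

        tm = trimesh.creation.box(extents=(side, side, side))
        tm.process(validate=False)
        mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), name="cube")
    elif kind == "cone":
        z = np.linspace(0.0, height, n_axial + 1)
        r = radius * (1.0 - z / height)
        r[-1] = max(radius * 1e-3, 1e-9)  # avoid the degenerate apex ring
        mesh = _revolve(r, z, n_theta, cap_bottom=True, cap_top=True, name="cone")
    elif kind == "torus_segment":
        mesh = make_bent_tube(
            tube_radius=radius,
            bend_radius=major_radius,
            arc_degrees=arc_degrees,
            n_theta=n_theta,
            n_axial=n_axial,
        )
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")
    _apply_jitter(mesh, jitter, seed)
    return mesh, _halves_masks(mesh)


def make_bent_tube(
    tube_radius: float = 0.4,
    bend_radius: float = 2.0,
    arc_degrees: float = 90.0,
    n_theta: int = 24,
    n_axial: int = 24,
) -> TriangleMesh:
    """Capped tube starting along +Z and bending toward +Y over the arc.

    A quarter arc (90 degrees) is the analytic oracle for a +90 degree
    dorsal bend angle."""
    phi = np.radians(arc_degrees) * np.linspace(0.0, 1.0, n_axial + 1)
    # center curve and cross-section frame
    cy = bend_radius * (1.0 - np.cos(phi))
    cz = bend_radius * np.sin(phi)
    mhat = np.stack([np.zeros_like(phi), np.cos(phi), -np.sin(phi)], axis=1)
    psi = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    xhat = np.array([1.0, 0.0, 0.0])
    verts = (
        np.stack([np.zeros_like(phi), cy, cz], axis=1)[:, None, :]
        + tube_radius * np.cos(psi)[None, :, None] * xhat[None, None, :]
        + tube_radius * np.sin(psi)[None, :, None] * mhat[:, None, :]
    )
    vertices = verts.reshape(-1, 3)
    faces = _grid_faces(n_axial + 1, n_theta, wrap_cols=True)
    # caps
    nv = len(vertices)
    c0 = np.array([0.0, 0.0, 0.0])
    c1 = np.array([0.0, cy[-1], cz[-1]])
    vertices = np.vstack([vertices, c0[None], c1[None]])
    j = np.arange(n_theta)
    j1 = (j + 1) % n_theta
    f0 = np.stack([np.full(n_theta, nv), j1, j], axis=-1)
    base = n_axial * n_theta
    f1 = np.stack([np.full(n_theta, nv + 1), base + j, base + j1], axis=-1)
    faces = np.vstack([faces, f0, f1])
    mesh = TriangleMesh(vertices, faces, name="bent_tube")
    if enclosed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh


# ---------------------------------------------------------------------------
# folded fixtures
# ---------------------------------------------------------------------------

def make_accordion_cylinder(
    radius: float = 0.8,
    folded_height: float = 1.0,
    n_pleats: int = 12,
    pleat_slant_length: float = 0.25,
    n_theta: int = 24,
    n_axial: int = 64,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[TriangleMesh, dict[str, RegionMask]]:
    """Accordion-pleated capped cylinder: the synthetic elongating stalk.

    The meridional profile is a triangle wave of ``2 * n_pleats`` straight
    segments, each of slant length ``pleat_slant_length``, spanning
    ``folded_height`` axially.  Total meridional arc length is therefore
    ``2 * n_pleats * pleat_slant_length``; with the defaults the stored
    meridian is six times the folded height, the ratio the inflated stalk
    should recover.  ``radius`` is the mean radius of the bellows.
    """
    n_seg = 2 * n_pleats
    dz = folded_height / n_seg
    if pleat_slant_length < dz:
        raise ValueError("pleats do not fit: pleat_slant_length < axial span per segment")
    dr = np.sqrt(pleat_slant_length**2 - dz**2)
    # profile corner nodes alternate between radius -/+ dr/2
    corners_z = np.linspace(0.0, folded_height, n_seg + 1)
    corners_r = radius + dr / 2.0 * np.where(np.arange(n_seg + 1) % 2 == 0, -1.0, 1.0)
    if corners_r.min() <= 0:
        raise ValueError("pleat amplitude exceeds the mean radius")
    # subdivide each slant segment for a finer axial resolution
    m = max(1, round(n_axial / n_seg))
    t = np.linspace(0.0, 1.0, m + 1)[:-1]
    zs, rs = [], []
    for k in range(n_seg):
        zs.append(corners_z[k] + t * (corners_z[k + 1] - corners_z[k]))
        rs.append(corners_r[k] + t * (corners_r[k + 1] - corners_r[k]))
    zs.append(corners_z[-1:])
    rs.append(corners_r[-1:])
    profile_z = np.concatenate(zs)
    profile_r = np.concatenate(rs)
    mesh = _revolve(profile_r, profile_z, n_theta, cap_bottom=True, cap_top=True,
                    name="accordion_cylinder")
    _apply_jitter(mesh, jitter, seed)
    return mesh, _halves_masks(mesh)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_furrowed_disk(
    outer_radius: float = 1.0,
    pattern: str = "full_circle",
    n_furrows: int = 5,
    amplitude: float = 0.04,
    band_fractions: tuple[float, float] = (0.25, 0.75),
    n_rings: int = 40,
    n_theta: int = 64,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[TriangleMesh, dict[str, RegionMask]]:
    """Flat disk with sinusoidal out-of-plane furrows; the cone models.

    pattern:
      - ``full_circle``: furrow rings concentric with the center; inflation
        erects an upright cone (apex over the center).
      - ``semicircle``: the same rings restricted to the ``x < 0`` half
        (the pattern is "outwardly vacant" toward +x); only half the
        meridians store extra arc, so inflation erects an oblique,
        overhanging cone whose apex sits well off the base center.
      - ``parallel``: straight furrows whose crests run along y.

    Ring furrows occupy the annulus ``band_fractions * outer_radius``:
    concentric furrows are a family of rings around a vacant center, and
    placing the stored arc mid-radius is what lets the slack erect a cone
    instead of pooling into a central mound.  Returns the open mesh plus
    masks ``boundary`` (the rim to pin) and ``furrows`` (the patch that
    carries the pattern).
    """
    if pattern not in ("full_circle", "semicircle", "parallel"):
        raise ValueError(f"unknown pattern {pattern!r}")
    r_in = band_fractions[0] * outer_radius
    r_out = band_fractions[1] * outer_radius
    if not (0.0 <= r_in < r_out < outer_radius):
        raise ValueError("band_fractions must satisfy 0 <= inner < outer < 1")
    radii = np.linspace(0.0, outer_radius, n_rings + 1)[1:]
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rr, tt = np.meshgrid(radii, theta, indexing="ij")
    x = rr * np.cos(tt)
    y = rr * np.sin(tt)

    edge = 0.15 * (r_out - r_in)
    if pattern == "parallel":
        env = _smoothstep((r_out - rr) / edge)
        phase = 2.0 * np.pi * n_furrows * x / (2.0 * r_out)
    else:
        env = _smoothstep((rr - r_in) / edge) * _smoothstep((r_out - rr) / edge)
        phase = 2.0 * np.pi * n_furrows * (rr - r_in) / (r_out - r_in)
    z = amplitude * np.sin(phase) * env
    if pattern == "semicircle":
        z = z * _smoothstep((0.0 - np.cos(tt)) / 0.35)
    vertices = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    vertices = np.vstack([[[0.0, 0.0, 0.0]], vertices])
    # rows grow radially, so reverse winding to orient the disk +Z (up)
    faces = _grid_faces(n_rings, n_theta, wrap_cols=True)[:, ::-1] + 1
    j = np.arange(n_theta)
    j1 = (j + 1) % n_theta
    fan = np.stack([np.zeros(n_theta, dtype=int), 1 + j, 1 + j1], axis=-1)
    mesh = TriangleMesh(vertices, np.vstack([fan, faces]), name=f"furrowed_disk_{pattern}")
    _apply_jitter(mesh, jitter, seed)

    rad = np.linalg.norm(mesh.vertices[:, :2], axis=1)
    rim = np.flatnonzero(np.abs(rad - outer_radius) < 1e-9)
    if pattern == "parallel":
        in_patch = rad < r_out
    else:
        in_patch = (rad > r_in) & (rad < r_out)
        if pattern == "semicircle":
            in_patch &= mesh.vertices[:, 0] < 0.0
    masks = {
        "boundary": RegionMask("boundary", rim),
        "furrows": RegionMask("furrows", np.flatnonzero(in_patch)),
    }
    return mesh, masks


def make_yoshimura_cylinder(
    radius: float = 1.0,
    height: float = 3.0,
    n_axial: int = 12,
    n_circumferential: int = 12,
    fold_depth: float = 0.12,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[TriangleMesh, dict[str, RegionMask]]:
    """Zigzag (Yoshimura) buckled cylinder: the passive stalk fold.

    Rings alternate between ``radius`` and ``radius - fold_depth`` and are
    offset by half an angular cell, producing the diamond tessellation of
    an axially compressed tube.  Ring spacing is chosen so the meridional
    slant length stays ``height / n_axial``: the folded tube is axially
    shorter than ``height`` but stores (approximately) that much developable
    meridian, which inflation should recover.
    """
    if n_axial < 3 or n_circumferential < 3:
        raise ValueError("n_axial and n_circumferential must be >= 3")
    seg = height / n_axial
    if fold_depth >= seg:
        raise ValueError("fold_depth must be smaller than height / n_axial")
    dz = np.sqrt(seg**2 - fold_depth**2)
    n_rows = n_axial + 1
    rows_z = dz * np.arange(n_rows)
    rows_r = radius - fold_depth * (np.arange(n_rows) % 2)
    dtheta = 2.0 * np.pi / n_circumferential
    verts = np.empty((n_rows, n_circumferential, 3))
    for i in range(n_rows):
        th = dtheta * (np.arange(n_circumferential) + 0.5 * (i % 2))
        verts[i, :, 0] = rows_r[i] * np.cos(th)
        verts[i, :, 1] = rows_r[i] * np.sin(th)
        verts[i, :, 2] = rows_z[i]
    vertices = verts.reshape(-1, 3)
    faces = _grid_faces(n_rows, n_circumferential, wrap_cols=True)
    nv = len(vertices)
    vertices = np.vstack([vertices, [[0, 0, rows_z[0]]], [[0, 0, rows_z[-1]]]])
    j = np.arange(n_circumferential)
    j1 = (j + 1) % n_circumferential
    f0 = np.stack([np.full(n_circumferential, nv), j1, j], axis=-1)
    base = (n_rows - 1) * n_circumferential
    f1 = np.stack([np.full(n_circumferential, nv + 1), base + j, base + j1], axis=-1)
    mesh = TriangleMesh(np.asarray(vertices), np.vstack([faces, f0, f1]),
                        name="yoshimura_cylinder")
    if enclosed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    _apply_jitter(mesh, jitter, seed)
    return mesh, _halves_masks(mesh)


def make_biased_base(
    radius: float = 0.5,
    length: float = 2.0,
    n_ventral_furrows: int = 5,
    n_dorsal_furrows: int = 1,
    amplitude: float = 0.08,
    n_theta: int = 24,
    n_axial: int = 48,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[TriangleMesh, dict[str, RegionMask]]:
    """Tube with more circumferential furrows ventrally than dorsally.

    The ventral (-Y) half of the wall carries ``n_ventral_furrows``
    sinusoidal rings, the dorsal (+Y) half ``n_dorsal_furrows``, blended
    smoothly through the lateral seams; the furrow band is tapered away
    from the pinned proximal ring (z = 0) and the distal cap.  The ventral
    side therefore stores more meridional arc, so inflation elongates it
    more and tips the tube dorsally (+Y): the orientation-setting mechanism
    of the horn base.
    """
    if n_ventral_furrows < n_dorsal_furrows or n_dorsal_furrows < 0:
        raise ValueError("need n_ventral_furrows >= n_dorsal_furrows >= 0")
    z = np.linspace(0.0, length, n_axial + 1)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    zz, tt = np.meshgrid(z, theta, indexing="ij")
    wv = 0.5 * (1.0 - np.sin(tt))  # 1 at ventral pole (-Y), 0 at dorsal pole
    taper = _smoothstep(zz / (0.15 * length)) * _smoothstep((length - zz) / (0.15 * length))
    phase_v = 2.0 * np.pi * n_ventral_furrows * zz / length
    phase_d = 2.0 * np.pi * n_dorsal_furrows * zz / length
    dr = amplitude * taper * (wv * np.sin(phase_v) + (1.0 - wv) * np.sin(phase_d))
    r = radius + dr
    verts = np.stack([r * np.cos(tt), r * np.sin(tt), zz], axis=-1)
    vertices = verts.reshape(-1, 3)
    faces = _grid_faces(n_axial + 1, n_theta, wrap_cols=True)
    nv = len(vertices)
    vertices = np.vstack([vertices, [[0.0, 0.0, length]]])
    base = n_axial * n_theta
    j = np.arange(n_theta)
    j1 = (j + 1) % n_theta
    f1 = np.stack([np.full(n_theta, nv), base + j, base + j1], axis=-1)
    mesh = TriangleMesh(vertices, np.vstack([faces, f1]), name="biased_base")
    # orientation check against the fan-closed volume
    ring = np.arange(n_theta)
    if enclosed_volume(mesh, closure_centroid=np.zeros(3)) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    _apply_jitter(mesh, jitter, seed)
    y = mesh.vertices[:, 1]
    masks = {
        "ventral": RegionMask("ventral", np.flatnonzero(y < 0)),
        "dorsal": RegionMask("dorsal", np.flatnonzero(y >= 0)),
        # the whole furrowed tube: the unit of base-wide furrow removal
        "base": RegionMask("base", np.arange(mesh.n_vertices)),
        "boundary": RegionMask("boundary", ring),
    }
    return mesh, masks


def make_notched_plate(
    notch_angle_degrees: float = 90.0,
    depth: float = 1.0,
    groove_length: float = 2.0,
    n_x: int = 81,
    n_y: int = 21,
) -> tuple[TriangleMesh, dict[str, RegionMask]]:
    """Rectangular plate with a machined V-groove of exactly the given angle.

    The groove runs along +Y at x = 0; slicing the plate normal to +Y
    recovers the notch profile, the analytic oracle for ``groove_angle``.
    ``notch_angle_degrees`` must lie in (10, 170).
    """
    if not (10.0 < notch_angle_degrees < 170.0):
        raise ValueError("notch angle must be in (10, 170) degrees")
    half = np.radians(notch_angle_degrees) / 2.0
    w_notch = depth * np.tan(half)
    width = 2.0 * w_notch  # flats half as long as the notch half-width
    # build the x grid from exact breakpoints so the apex and the
    # flank/flat corners are mesh vertices
    breaks = [-w_notch - width, -w_notch, 0.0, w_notch, w_notch + width]
    n_per = max(2, n_x // 4)
    segs = [np.linspace(a, b, n_per)[:-1] for a, b in zip(breaks[:-1], breaks[1:])]
    xs = np.concatenate(segs + [[breaks[-1]]])
    ys = np.linspace(0.0, groove_length, n_y)
    zz = np.where(np.abs(xs) <= w_notch, np.abs(xs) / np.tan(half), depth)
    xv, yv = np.meshgrid(xs, ys, indexing="ij")
    zv = np.broadcast_to(zz[:, None], xv.shape)
    vertices = np.stack([xv, yv, zv], axis=-1).reshape(-1, 3)
    faces = _grid_faces(len(xs), len(ys), wrap_cols=False)[:, ::-1]  # orient +Z up
    mesh = TriangleMesh(vertices, faces, name=f"notched_plate_{notch_angle_degrees:g}")
    masks = {"groove": RegionMask("groove", np.flatnonzero(np.abs(mesh.vertices[:, 0]) <= w_notch))}
    return mesh, masks


def make_corrugated_plate(
    amplitude: float = 0.1,
    wavelength: float = 0.5,
    size: float = 2.0,
    n: int = 41,
) -> TriangleMesh:
    """Plate z = A sin(2 pi x / lambda): the sign oracle for furrow fields."""
    xs = np.linspace(-size / 2.0, size / 2.0, n)
    ys = np.linspace(-size / 2.0, size / 2.0, n)
    xv, yv = np.meshgrid(xs, ys, indexing="ij")
    zv = amplitude * np.sin(2.0 * np.pi * xv / wavelength)
    vertices = np.stack([xv, yv, zv], axis=-1).reshape(-1, 3)
    faces = _grid_faces(n, n, wrap_cols=False)[:, ::-1]  # orient +Z up
    return TriangleMesh(vertices, faces, name="corrugated_plate")


def make_corrugated_sphere(
    radius: float = 1.0,
    amplitude: float = 0.05,
    n_lobes: int = 6,
    subdivisions: int = 3,
) -> TriangleMesh:
    """Icosphere with a radial sinusoid: the HC-vs-plain shrinkage fixture."""
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(tm.vertices)
    r = np.linalg.norm(v, axis=1, keepdims=True)
    zn = np.clip(v[:, 2:3] / r, -1.0, 1.0)
    bump = amplitude * np.sin(n_lobes * np.arccos(zn)) * np.cos(
        n_lobes * np.arctan2(v[:, 1:2], v[:, 0:1])
    )
    vertices = v * (1.0 + bump / r)
    return TriangleMesh(vertices, np.asarray(tm.faces), name="corrugated_sphere")


# ---------------------------------------------------------------------------
# the cap model
# ---------------------------------------------------------------------------

def make_cap_model(
    dome_radius: float = 1.0,
    dome_flattening: float = 0.12,
    overhang_degrees: float = 112.0,
    lobe_height: float = 1.2,
    lobe_polar_degrees: float = 62.0,
    lobe_sigma_degrees: float = 22.0,
    lobe_tilt: float = 2.0,
    medial_polar_degrees: float = 28.0,
    medial_patch_degrees: float = 24.0,
    medial_furrows: int = 2,
    medial_amplitude: float = 0.09,
    medial_vacancy: float = 0.4,
    bottom_furrows: int = 8,
    bottom_amplitude: float = 0.03,
    n_polar: int = 56,
    n_theta: int = 84,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[TriangleMesh, dict[str, RegionMask]]:
    """Dome "cap" that inflates into a four-branched tip.

    A deliberately constructed composite of the three branch mechanisms:

    * two **lateral macro-lobes** at azimuth 0 and 180 degrees — tall
      smooth bumps, displaced up-and-outward, already present in the
      folded macro-shape (these branches survive furrow removal);
    * two **medial concentric-semicircle furrow patches** on the upper
      surface, nearer the midline — annular furrow rings whose stored arc
      unfolds into oblique cones, erecting two branches that did *not*
      exist in the folded shape (these vanish when ``medial_amplitude`` is
      zero);
    * **parallel furrows on the bottom surface** of the overhang (the band
      past 90 degrees polar angle), whose unfolding elongates the
      underside and lifts the lateral branches.

    The dome body is strongly flattened along Z (``dome_flattening``) so
    the four erected tips, not the dome apex, dominate the top of the
    inflated shape.  The rim (polar angle ``overhang_degrees``) is the
    pinned proximal ring.  Returns the mesh plus masks ``medial_tips``,
    ``lateral_tips``, ``upper_surface``, ``bottom_surface``, ``boundary``.
    """
    psi_max = np.radians(overhang_degrees)
    psi = np.linspace(np.radians(2.0), psi_max, n_polar)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    pp, tt = np.meshgrid(psi, theta, indexing="ij")

    # angular distance on the unit sphere to a center (psi_c, theta_c)
    def angdist(psi_c: float, theta_c: float) -> np.ndarray:
        c = (
            np.cos(pp) * np.cos(psi_c)
            + np.sin(pp) * np.sin(psi_c) * np.cos(tt - theta_c)
        )
        return np.arccos(np.clip(c, -1.0, 1.0))

    # flattened dome body
    x = dome_radius * np.sin(pp) * np.cos(tt)
    y = dome_radius * np.sin(pp) * np.sin(tt)
    z = dome_flattening * dome_radius * np.cos(pp)

    # lateral macro-lobes: bumps displaced up-and-outward at +-X
    sig = np.radians(lobe_sigma_degrees)
    psi_l = np.radians(lobe_polar_degrees)
    lobe_bump = np.zeros_like(pp)
    for th_c in (0.0, np.pi):
        d = angdist(psi_l, th_c)
        g = np.exp(-((d / sig) ** 2))
        lobe_bump += g
        u = np.array([np.sin(psi_l) * np.cos(th_c), np.sin(psi_l) * np.sin(th_c), lobe_tilt])
        u = u / np.linalg.norm(u)
        x = x + dome_radius * lobe_height * g * u[0]
        y = y + dome_radius * lobe_height * g * u[1]
        z = z + dome_radius * lobe_height * g * u[2]

    # medial furrow patches: annular concentric rings, outwardly vacant
    psi_m = np.radians(medial_polar_degrees)
    patch = np.radians(medial_patch_degrees)
    medial_mask = np.zeros_like(pp, dtype=bool)
    medial_disp = np.zeros_like(pp)
    r_in = 0.25 * patch
    for th_c in (0.0, np.pi):
        d = angdist(psi_m, th_c)
        edge = 0.15 * (patch - r_in)
        win = _smoothstep((d - r_in) / edge) * _smoothstep((patch - d) / edge)
        # partially vacant on the outward side (toward the nearby lateral
        # lobe) so the erected cone tilts outward; medial_vacancy sets how
        # deep the vacancy cuts (0 = full rings, 1 = fully open half)
        out_dir = (pp - psi_m) * np.cos(tt - th_c)
        semis = (1.0 - medial_vacancy) + medial_vacancy * _smoothstep(
            (0.1 * patch - out_dir) / (0.5 * patch)
        )
        medial_disp += np.sin(2.0 * np.pi * medial_furrows * (d - r_in) / (patch - r_in)) * win * semis
        medial_mask |= d < patch
    # displacement along the local sphere normal (dominantly +z up here)
    nx, ny, nz = np.sin(pp) * np.cos(tt), np.sin(pp) * np.sin(tt), np.cos(pp)
    x = x + dome_radius * medial_amplitude * medial_disp * nx
    y = y + dome_radius * medial_amplitude * medial_disp * ny
    z = z + dome_radius * medial_amplitude * medial_disp * nz

    # parallel furrows (lines along Y) on the bottom surface of the overhang
    band = _smoothstep((pp - np.radians(92.0)) / np.radians(8.0)) * _smoothstep(
        (psi_max - pp) / np.radians(8.0)
    )
    xcoord = np.sin(pp) * np.cos(tt)
    bottom_disp = np.sin(2.0 * np.pi * bottom_furrows * xcoord / 2.0) * band
    x = x + dome_radius * bottom_amplitude * bottom_disp * nx
    y = y + dome_radius * bottom_amplitude * bottom_disp * ny
    z = z + dome_radius * bottom_amplitude * bottom_disp * nz

    grid_verts = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    apex = np.array([[0.0, 0.0, dome_flattening * dome_radius]])
    vertices = np.vstack([apex, grid_verts])
    # rows grow with polar angle (downward), so reverse winding for outward
    faces = _grid_faces(n_polar, n_theta, wrap_cols=True)[:, ::-1] + 1
    j = np.arange(n_theta)
    j1 = (j + 1) % n_theta
    fan = np.stack([np.zeros(n_theta, dtype=int), 1 + j, 1 + j1], axis=-1)
    mesh = TriangleMesh(vertices, np.vstack([fan, faces]), name="cap_model")
    _apply_jitter(mesh, jitter, seed)

    pp_flat = np.concatenate([[0.0], pp.ravel()])
    lobe_flat = np.concatenate([[0.0], lobe_bump.ravel()])
    med_flat = np.concatenate([[False], medial_mask.ravel()])
    band_flat = np.concatenate([[0.0], band.ravel()])
    rim = np.flatnonzero(np.isclose(pp_flat, psi_max))
    lateral = lobe_flat > np.exp(-1.0)
    bottom = band_flat > 0.2
    upper = (pp_flat < np.radians(90.0)) & ~lateral & ~med_flat
    masks = {
        "medial_tips": RegionMask("medial_tips", np.flatnonzero(med_flat)),
        "lateral_tips": RegionMask("lateral_tips", np.flatnonzero(lateral)),
        "upper_surface": RegionMask("upper_surface", np.flatnonzero(upper)),
        "bottom_surface": RegionMask("bottom_surface", np.flatnonzero(bottom)),
        "boundary": RegionMask("boundary", rim),
    }
    return mesh, masks
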