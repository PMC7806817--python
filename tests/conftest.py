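"""Shared fixtures: small analytic meshes and cached heavy inflations.

The expensive pressure-inflation runs (stalk, disks, base, cap) are
session-scoped so each is computed once however many tests read it.
"""

from __future__ import annotations

import numpy as np
import pytest

from morphofold import MaterialParams, inflate, shapes
from morphofold.mesh import TriangleMesh


# ---------------------------------------------------------------------------
# small analytic meshes
# ---------------------------------------------------------------------------

@pytest.fixture()
def tetrahedron() -> TriangleMesh:
    """Unit right tetrahedron (0,0,0),(1,0,0),(0,1,0),(0,0,1), outward faces."""
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f, name="tetrahedron")


@pytest.fixture()
def cube() -> TriangleMesh:
    mesh, _ = shapes.make_primitive("cube", side=1.0)
    return mesh


@pytest.fixture()
def icosphere() -> TriangleMesh:
    mesh, _ = shapes.make_primitive("sphere", subdivisions=3)
    return mesh


@pytest.fixture()
def icosphere_small() -> TriangleMesh:
    mesh, _ = shapes.make_primitive("sphere", subdivisions=2)
    return mesh


@pytest.fixture()
def corrugated_plate() -> TriangleMesh:
    return shapes.make_corrugated_plate()


@pytest.fixture()
def corrugated_sphere() -> TriangleMesh:
    return shapes.make_corrugated_sphere()


# ---------------------------------------------------------------------------
# cached inflations (session scope: computed once)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def accordion_run():
    """Default accordion stalk and its inflation trajectory."""
    mesh, masks = shapes.make_accordion_cylinder()
    traj = inflate(mesh, MaterialParams(snapshot_stride=500))
    return mesh, masks, traj


@pytest.fixture(scope="session")
def disk_runs():
    """Inflated furrowed disks: {pattern: (mesh, masks, trajectory)}."""
    out = {}
    for pattern in ("full_circle", "semicircle"):
        mesh, masks = shapes.make_furrowed_disk(pattern=pattern)
        params = MaterialParams.with_pressure_ratio(
            mesh, 0.0125, pinned=masks["boundary"], snapshot_stride=5000
        )
        out[pattern] = (mesh, masks, inflate(mesh, params))
    return out


@pytest.fixture(scope="session")
def biased_base_runs():
    """Inflated biased base: original, ventral-dorsal mirrored, furrow-smoothed."""
    from morphofold.smoothing import SmoothingParams, hc_laplacian_smooth

    mesh, masks = shapes.make_biased_base()
    params = MaterialParams(pinned=masks["boundary"], snapshot_stride=5000)
    original = inflate(mesh, params)

    mirrored = mesh.copy()
    mirrored.vertices = mirrored.vertices * np.array([1.0, -1.0, 1.0])
    mirrored.faces = mirrored.faces[:, ::-1].copy()
    mirrored_run = inflate(mirrored, params)

    smoothed = hc_laplacian_smooth(
        mesh, SmoothingParams(mask=masks["base"], feather_width=2)
    )
    smoothed_run = inflate(smoothed, params)
    return {
        "mesh": mesh,
        "masks": masks,
        "original": original,
        "mirrored": mirrored_run,
        "smoothed": smoothed_run,
    }


@pytest.fixture(scope="session")
def cap_runs():
    """Inflated cap model: full and medial-ablated variants."""
    out = {}
    for tag, kwargs in (("full", {}), ("no_medial", {"medial_amplitude": 0.0})):
        mesh, masks = shapes.make_cap_model(**kwargs)
        params = MaterialParams.with_pressure_ratio(
            mesh, 0.0125, pinned=masks["boundary"], snapshot_stride=5000
        )
        out[tag] = (mesh, masks, inflate(mesh, params))
    return out
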