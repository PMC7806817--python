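"""Furrow visualization (signed depth, classes) and removal analysis."""

import numpy as np
import pytest

from morphofold import shapes
from morphofold.furrows import furrow_density, furrow_field, remove_furrows
from morphofold.inflation import MaterialParams
from morphofold.mesh import RegionMask
from morphofold.smoothing import SmoothingParams


@pytest.fixture(scope="module")
def plate_field():
    mesh = shapes.make_corrugated_plate(amplitude=0.1, wavelength=0.5, size=2.0, n=41)
    return mesh, furrow_field(mesh)


def test_smooth_sphere_is_all_neutral():
    """A featureless sphere carries no furrow signal: beyond the uniform
    residual-shrink offset, the depth stays under 1e-3 of the radius.
    (Resolution matters: the umbrella smoother's valence footprint scales
    with the squared edge length, so a 4-subdivision icosphere is used.)"""
    mesh, _ = shapes.make_primitive("sphere", subdivisions=4)
    cls = furrow_field(mesh, SmoothingParams(n_iterations=10), threshold=1e-3)
    assert np.abs(cls.centered_depth).max() < 1e-3  # radius 1
    assert np.all(cls.classes == 0)


def test_corrugated_plate_sign_matches_generator(plate_field):
    """sign(depth) equals sign(sin(2 pi x / lambda)) away from the zero crossings."""
    mesh, cls = plate_field
    x = mesh.vertices[:, 0]
    interior = np.ones(mesh.n_vertices, dtype=bool)
    interior[mesh.boundary_vertices()] = False
    s = np.sin(2 * np.pi * x / 0.5)
    strong = interior & (np.abs(s) > 0.5)
    agree = np.sign(cls.depth[strong]) == np.sign(s[strong])
    assert agree.mean() > 0.99


def test_ridge_valley_classes_follow_threshold(plate_field):
    _, cls = plate_field
    d, t = cls.centered_depth, cls.threshold
    assert np.all(cls.classes[d > t] == 1)
    assert np.all(cls.classes[d < -t] == -1)
    assert np.all(cls.classes[np.abs(d) <= t] == 0)


def test_accordion_band_count_along_meridian():
    """An n-pleat accordion shows 2n alternating ridge/valley bands."""
    n_pleats = 6
    mesh, _ = shapes.make_accordion_cylinder(n_pleats=n_pleats, pleat_slant_length=0.25,
                                             folded_height=1.0, radius=0.8)
    cls = furrow_field(mesh)
    v = mesh.vertices
    theta = np.arctan2(v[:, 1], v[:, 0])
    meridian = np.flatnonzero((np.abs(theta) < 1e-9) & (np.linalg.norm(v[:, :2], axis=1) > 1e-6))
    meridian = meridian[np.argsort(v[meridian, 2])]
    z = v[meridian, 2]
    inner = (z > 0.04) & (z < 0.96)  # clip the cap junctions
    d = cls.centered_depth[meridian][inner]
    signs = np.sign(d[np.abs(d) > cls.threshold])
    changes = int((np.diff(signs) != 0).sum())
    # 2n bands = 2n - 1 alternations; band edges can add or drop a couple
    assert abs((changes + 1) - 2 * n_pleats) <= 2


def test_field_equivariant_under_rigid_motion(corrugated_sphere):
    from scipy.spatial.transform import Rotation

    base = furrow_field(corrugated_sphere)
    moved = corrugated_sphere.copy()
    rot = Rotation.from_euler("xyz", [0.4, -0.2, 1.0]).as_matrix()
    moved.vertices = moved.vertices @ rot.T + np.array([5.0, 6.0, -7.0])
    rotated = furrow_field(moved)
    np.testing.assert_allclose(rotated.depth, base.depth, atol=1e-9)


def test_already_smoothed_mesh_has_much_shallower_furrows():
    mesh = shapes.make_corrugated_plate(amplitude=0.1, wavelength=0.5, n=41)
    from morphofold.smoothing import hc_laplacian_smooth

    params = SmoothingParams(n_iterations=200)
    once = hc_laplacian_smooth(mesh, params)
    d0 = np.abs(furrow_field(mesh, params).centered_depth).max()
    d1 = np.abs(furrow_field(once, params).centered_depth).max()
    assert d1 < d0 / 5


def test_furrow_density_ordering_on_biased_base():
    mesh, masks = shapes.make_biased_base(n_ventral_furrows=5, n_dorsal_furrows=1)
    cls = furrow_field(mesh)
    dv = furrow_density(cls, mesh, masks["ventral"])
    dd = furrow_density(cls, mesh, masks["dorsal"])
    assert 0.0 <= dd < dv <= 1.0


def test_furrow_density_symmetric_on_uniform_accordion():
    """Mirror-symmetric halves of a uniform accordion carry equal valley
    fractions (masks built symmetric about y = 0, seam rows excluded)."""
    mesh, _ = shapes.make_accordion_cylinder()
    cls = furrow_field(mesh)
    y = mesh.vertices[:, 1]
    vent = RegionMask("vent", np.flatnonzero(y < -1e-6))
    dors = RegionMask("dors", np.flatnonzero(y > 1e-6))
    dv = furrow_density(cls, mesh, vent)
    dd = furrow_density(cls, mesh, dors)
    assert dv == pytest.approx(dd, rel=0.05)


def test_furrow_density_rejects_empty_region(icosphere_small):
    cls = furrow_field(icosphere_small)
    with pytest.raises(ValueError):
        furrow_density(cls, icosphere_small, RegionMask("none", np.array([], dtype=int)))


def test_remove_furrows_empty_region_gives_zero_deltas():
    mesh, masks = shapes.make_biased_base(n_theta=12, n_axial=16)
    empty = RegionMask("empty", np.array([], dtype=int))
    with pytest.warns(UserWarning, match="empty"):
        _, rep = remove_furrows(
            mesh,
            empty,
            mparams=MaterialParams(pinned=masks["boundary"], max_steps=300),
        )
    for key, val in rep.deltas.items():
        if val is not None:
            assert val == pytest.approx(0.0, abs=1e-9)


def test_remove_furrows_outside_region_untouched_and_deterministic():
    mesh, masks = shapes.make_biased_base(n_theta=12, n_axial=16)
    region = masks["ventral"]
    sp = SmoothingParams(feather_width=0)
    mp = MaterialParams(pinned=masks["boundary"], max_steps=200)
    sm1, rep1 = remove_furrows(mesh, region, sp, mp)
    sm2, rep2 = remove_furrows(mesh, region, sp, mp)
    outside = np.setdiff1d(np.arange(mesh.n_vertices), region.indices)
    assert np.array_equal(sm1.vertices[outside], mesh.vertices[outside])
    assert np.array_equal(sm1.vertices, sm2.vertices)
    assert rep1.to_dict() == rep2.to_dict()


def test_remove_furrows_is_nearly_idempotent():
    """A second pass removes far less furrow signal than the first."""
    mesh, masks = shapes.make_biased_base()
    region = masks["base"]
    sp = SmoothingParams(n_iterations=200)
    mp = MaterialParams(pinned=masks["boundary"], max_steps=1)  # folded meshes only
    once, _ = remove_furrows(mesh, region, sp, mp)
    twice, _ = remove_furrows(once, region, sp, mp)
    sel = region.to_bool(mesh.n_vertices)
    d0 = np.abs(furrow_field(mesh, sp).centered_depth[sel]).max()
    d1 = np.abs(furrow_field(once, sp).centered_depth[sel]).max()
    d2 = np.abs(furrow_field(twice, sp).centered_depth[sel]).max()
    first_change = d0 - d1
    second_change = abs(d1 - d2)
    assert second_change < 0.2 * first_change
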