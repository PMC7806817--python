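"""Generator validity, determinism, and construction arithmetic."""

import numpy as np
import pytest

from morphofold import shapes
from morphofold.mesh import surface_area, validate
from morphofold.morphometry import axial_extent


ALL_CLOSED = [
    ("sphere", lambda: shapes.make_primitive("sphere")[0]),
    ("cylinder", lambda: shapes.make_primitive("cylinder")[0]),
    ("cube", lambda: shapes.make_primitive("cube")[0]),
    ("cone", lambda: shapes.make_primitive("cone")[0]),
    ("bent_tube", lambda: shapes.make_bent_tube()),
    ("accordion", lambda: shapes.make_accordion_cylinder()[0]),
    ("yoshimura", lambda: shapes.make_yoshimura_cylinder()[0]),
    ("corrugated_sphere", lambda: shapes.make_corrugated_sphere()),
]

ALL_OPEN = [
    ("disk_full", lambda: shapes.make_furrowed_disk(pattern="full_circle")[0]),
    ("disk_semi", lambda: shapes.make_furrowed_disk(pattern="semicircle")[0]),
    ("disk_par", lambda: shapes.make_furrowed_disk(pattern="parallel")[0]),
    ("biased_base", lambda: shapes.make_biased_base()[0]),
    ("cap", lambda: shapes.make_cap_model()[0]),
    ("notched", lambda: shapes.make_notched_plate(90.0)[0]),
    ("corrugated_plate", lambda: shapes.make_corrugated_plate()),
]


@pytest.mark.parametrize("name,maker", ALL_CLOSED, ids=[n for n, _ in ALL_CLOSED])
def test_closed_generators_are_valid_sphere_topology(name, maker):
    mesh = maker()
    rep = validate(mesh)
    assert rep.manifold and rep.oriented and rep.closed
    assert rep.euler_characteristic == 2
    assert len(rep.degenerate_faces) == 0


@pytest.mark.parametrize("name,maker", ALL_OPEN, ids=[n for n, _ in ALL_OPEN])
def test_open_generators_are_valid_disk_topology(name, maker):
    mesh = maker()
    rep = validate(mesh)
    assert rep.manifold and rep.oriented and not rep.closed
    assert rep.euler_characteristic == 1
    assert len(rep.degenerate_faces) == 0


def test_generators_are_deterministic():
    a, _ = shapes.make_cap_model()
    b, _ = shapes.make_cap_model()
    assert np.array_equal(a.vertices, b.vertices)
    c = shapes.make_accordion_cylinder(jitter=1e-3, seed=11)[0]
    d = shapes.make_accordion_cylinder(jitter=1e-3, seed=11)[0]
    e = shapes.make_accordion_cylinder(jitter=1e-3, seed=12)[0]
    assert np.array_equal(c.vertices, d.vertices)
    assert not np.array_equal(c.vertices, e.vertices)


def test_accordion_arithmetic():
    """Meridian arc = 2 * n_pleats * slant; folded extent = folded_height."""
    mesh, masks = shapes.make_accordion_cylinder(
        n_pleats=12, pleat_slant_length=0.25, folded_height=1.0
    )
    assert axial_extent(mesh) == pytest.approx(1.0)
    # reconstruct the meridional arc length from one column of wall vertices
    v = mesh.vertices
    theta = np.arctan2(v[:, 1], v[:, 0])
    r = np.linalg.norm(v[:, :2], axis=1)
    wall = np.flatnonzero((np.abs(theta) < 1e-9) & (r > 1e-6))  # theta=0 meridian, no cap centers
    wall = wall[np.argsort(v[wall, 2])]
    rz = np.stack([np.linalg.norm(v[wall, :2], axis=1), v[wall, 2]], axis=1)
    arc = np.linalg.norm(np.diff(rz, axis=0), axis=1).sum()
    assert arc == pytest.approx(2 * 12 * 0.25, rel=1e-9)
    assert set(masks) >= {"ventral", "dorsal"}


def test_accordion_single_pleat_degenerates_to_cylinder():
    mesh, _ = shapes.make_accordion_cylinder(
        n_pleats=1, pleat_slant_length=0.5, folded_height=1.0, radius=0.8
    )
    r = np.linalg.norm(mesh.vertices[:, :2], axis=1)
    wall = r > 1e-6
    assert r[wall].max() - r[wall].min() < 1e-9  # constant radius: a plain cylinder


def test_accordion_rejects_impossible_pleats():
    with pytest.raises(ValueError):
        shapes.make_accordion_cylinder(n_pleats=2, pleat_slant_length=0.1, folded_height=1.0)


def test_flat_disk_at_zero_amplitude():
    mesh, masks = shapes.make_furrowed_disk(amplitude=0.0)
    assert np.abs(mesh.vertices[:, 2]).max() == 0.0
    assert len(masks["boundary"]) > 0


def test_semicircle_furrows_only_on_negative_x():
    mesh, masks = shapes.make_furrowed_disk(pattern="semicircle")
    z = mesh.vertices[:, 2]
    x = mesh.vertices[:, 0]
    assert np.abs(z[x > 0.2]).max() < 0.1 * np.abs(z).max()


def test_yoshimura_degenerates_and_shortens():
    plain, _ = shapes.make_yoshimura_cylinder(fold_depth=0.0, radius=1.0, height=3.0)
    r = np.linalg.norm(plain.vertices[:, :2], axis=1)
    assert r[r > 1e-6].max() - r[r > 1e-6].min() < 1e-9
    folded, _ = shapes.make_yoshimura_cylinder(fold_depth=0.12, radius=1.0, height=3.0)
    assert axial_extent(folded) < 3.0


def test_yoshimura_inflation_recovers_developable_height():
    """The zigzag tube stores ~its nominal height of meridian; inflation
    at the drumhead pressure ratio deploys at least 95% of it without
    significant stretching."""
    from morphofold import MaterialParams, inflate

    mesh, _ = shapes.make_yoshimura_cylinder()  # nominal height 3.0
    params = MaterialParams.with_pressure_ratio(mesh, 0.0125, snapshot_stride=1000)
    fin = inflate(mesh, params).final_mesh
    assert axial_extent(fin) >= 0.95 * 3.0
    assert surface_area(fin) / surface_area(mesh) < 1.05


def test_biased_base_requires_ventral_majority():
    with pytest.raises(ValueError):
        shapes.make_biased_base(n_ventral_furrows=1, n_dorsal_furrows=5)


def test_cap_model_masks_cover_disjoint_subregions():
    mesh, masks = shapes.make_cap_model()
    expected = {"medial_tips", "lateral_tips", "upper_surface", "bottom_surface", "boundary"}
    assert expected <= set(masks)
    med = set(masks["medial_tips"].indices.tolist())
    lat = set(masks["lateral_tips"].indices.tolist())
    bot = set(masks["bottom_surface"].indices.tolist())
    assert med and lat and bot
    assert not med & bot


def test_notched_plate_angle_bounds():
    with pytest.raises(ValueError):
        shapes.make_notched_plate(5.0)
    with pytest.raises(ValueError):
        shapes.make_notched_plate(175.0)


@pytest.mark.parametrize(
    "maker",
    [
        lambda n_theta, n_axial: shapes.make_accordion_cylinder(n_theta=n_theta, n_axial=n_axial)[0],
        lambda n_theta, n_axial: shapes.make_biased_base(n_theta=n_theta, n_axial=n_axial)[0],
    ],
    ids=["accordion", "biased_base"],
)
def test_resolution_convergence_of_surface_area(maker):
    coarse = surface_area(maker(24, 48))
    fine = surface_area(maker(48, 96))
    assert abs(fine - coarse) / fine < 0.01
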