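"""Geometry: meshes, sensor caps, patches and the Sarvas forward model."""

import numpy as np
import pytest

from megcoh.errors import (
    GeometryError,
    InsufficientMeshError,
    MeshFormatError,
    UnsupportedMeshError,
)
from megcoh.geometry import (
    SourceSpace,
    build_sensor_cap,
    build_sphere_source_space,
    build_wrinkled_source_space,
    compute_lead_field,
    grow_patch,
    load_mesh,
    normalize_lead_field,
    write_obj,
    _sarvas_field,
    _vertex_normals_and_areas,
)


# --- icosphere source spaces -------------------------------------------------

@pytest.mark.parametrize(
    "level, n_vertices, n_triangles",
    [(0, 12, 20), (1, 42, 80), (3, 642, 1280)],
)
def test_icosphere_counts(level, n_vertices, n_triangles):
    ss = build_sphere_source_space(level, 0.08)
    assert ss.n_vertices == n_vertices
    assert ss.triangles.shape[0] == n_triangles


def test_icosphere_area_approximates_sphere():
    """Flat-triangle vertex areas sum to the analytic 4πr² within 3%."""
    ss = build_sphere_source_space(2, 0.08)
    analytic = 4 * np.pi * 0.08**2
    assert abs(ss.total_area - analytic) / analytic < 0.03


def test_source_space_invariants():
    ss = build_sphere_source_space(1, 0.08, center=(0.01, 0.0, -0.02))
    assert np.allclose(np.linalg.norm(ss.normals, axis=1), 1.0, atol=1e-9)
    assert np.all(ss.vertex_area > 0)
    # normals point away from the center
    rel = ss.vertex_positions - np.array([0.01, 0.0, -0.02])
    assert np.all(np.einsum("ij,ij->i", ss.normals, rel) > 0)
    # every vertex belongs to at least one triangle
    assert set(ss.triangles.ravel()) == set(range(ss.n_vertices))


def test_wrinkled_sphere_tilts_normals_and_stays_inside():
    ss = build_wrinkled_source_space(3, 0.08, 0.1)
    radii = np.linalg.norm(ss.vertex_positions, axis=1)
    assert radii.max() <= 0.08 * 1.1 + 1e-12
    radial = ss.vertex_positions / radii[:, None]
    cos_tilt = np.einsum("ij,ij->i", ss.normals, radial)
    assert np.median(np.degrees(np.arccos(np.clip(cos_tilt, -1, 1)))) > 5.0


# --- mesh file I/O -----------------------------------------------------------

def test_obj_tetrahedron(tmp_path):
    path = tmp_path / "tet.obj"
    path.write_text(
        "v 0 0 0\nv 1 0 0\nv 0 1 0\nv 0 0 1\n"
        "f 1 2 3\nf 1 2 4\nf 1 3 4\nf 2 3 4\n"
    )
    ss = load_mesh(path)
    assert ss.n_vertices == 4
    assert ss.triangles.shape == (4, 3)


def test_obj_round_trip(tmp_path):
    ss = build_sphere_source_space(1, 0.08)
    path = tmp_path / "ico.obj"
    write_obj(ss, path)
    back = load_mesh(path)
    assert np.allclose(back.vertex_positions, ss.vertex_positions, atol=1e-6)
    assert np.array_equal(back.triangles, ss.triangles)


def test_obj_quad_face_rejected(tmp_path):
    path = tmp_path / "quad.obj"
    path.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
    with pytest.raises(UnsupportedMeshError, match="line 5"):
        load_mesh(path)


def test_obj_malformed_line_named(tmp_path):
    path = tmp_path / "bad.obj"
    path.write_text("v 0 0 0\nv 1 0 zz\nv 0 1 0\nf 1 2 3\n")
    with pytest.raises(MeshFormatError, match="line 2"):
        load_mesh(path)


def test_freesurfer_ascii(tmp_path):
    path = tmp_path / "surf.asc"
    path.write_text(
        "#!ascii version of a surface\n"
        "4 4\n"
        "0 0 0 0\n1 0 0 0\n0 1 0 0\n0 0 1 0\n"
        "0 1 2 0\n0 1 3 0\n0 2 3 0\n1 2 3 0\n"
    )
    ss = load_mesh(path)
    assert ss.n_vertices == 4 and ss.triangles.shape == (4, 3)


# --- sensor caps -------------------------------------------------------------

def test_sensor_cap_single_sensor():
    sa = build_sensor_cap(1, 0.12, 1.0)
    assert sa.n_sensors == 1
    assert np.isclose(np.linalg.norm(sa.positions[0]), 0.12)
    assert np.allclose(sa.orientations[0], sa.positions[0] / 0.12)


def test_sensor_cap_positions_distinct_and_on_shell():
    sa = build_sensor_cap(275, 0.12, 0.6)
    assert sa.n_sensors == 275
    d = np.linalg.norm(sa.positions[:, None] - sa.positions[None], axis=-1)
    assert d[np.triu_indices(275, 1)].min() > 0
    assert np.allclose(np.linalg.norm(sa.positions, axis=1), 0.12)


def test_sensor_cap_hemisphere_stays_above_equator():
    sa = build_sensor_cap(100, 0.12, 0.5)
    assert np.all(sa.positions[:, 2] >= -1e-12)


def test_sensor_cap_inside_conductor_rejected():
    with pytest.raises(GeometryError):
        build_sensor_cap(10, 0.08, 0.5, conductor_radius=0.09)


# --- Sarvas lead field -------------------------------------------------------

def _sarvas_oracle(r0, q, r):
    """Independent scalar evaluation of the spherical-conductor dipole field,
    written from the closed form with plain Python floats."""
    import math

    def dot(a, b):
        return sum(x * y for x, y in zip(a, b))

    def cross(a, b):
        return (
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        )

    a_vec = tuple(ri - r0i for ri, r0i in zip(r, r0))
    a = math.sqrt(dot(a_vec, a_vec))
    rn = math.sqrt(dot(r, r))
    F = a * (rn * a + rn**2 - dot(r0, r))
    c1 = a**2 / rn + dot(a_vec, r) / a + 2 * a + 2 * rn
    c2 = a + 2 * rn + dot(a_vec, r) / a
    gradF = tuple(c1 * ri - c2 * r0i for ri, r0i in zip(r, r0))
    qxr0 = cross(q, r0)
    k = 1e-7 / F**2
    return tuple(
        k * (F * qc - dot(qxr0, r) * gc) for qc, gc in zip(qxr0, gradF)
    )


def test_sarvas_matches_independent_oracle():
    """Tangential unit dipole at (0, 0, 0.06), radial magnetometer at
    (0, 0, 0.12): vectorized field equals the scalar re-derivation."""
    r0 = np.array([[0.0, 0.0, 0.06]])
    q = np.array([[1.0, 0.0, 0.0]])
    sens = np.array([[0.03, 0.02, 0.12]])  # off-axis so the field is nonzero
    B = _sarvas_field(r0, q, sens)[0, 0]
    expected = _sarvas_oracle((0.0, 0.0, 0.06), (1.0, 0.0, 0.0), (0.03, 0.02, 0.12))
    assert np.allclose(B, expected, rtol=1e-12)
    assert np.linalg.norm(B) > 0


def test_radial_dipoles_are_silent(rng):
    """Spherical-conductor silence: radial moments produce vanishing fields
    compared to matched tangential dipoles at the same positions."""
    n = 100
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    pos = 0.07 * u
    tang = np.cross(u, rng.standard_normal((n, 3)))
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    sens = build_sensor_cap(50, 0.12, 1.0).positions
    b_radial = _sarvas_field(pos, u, sens)
    b_tang = _sarvas_field(pos, tang, sens)
    assert np.abs(b_radial).max() < 1e-10 * np.abs(b_tang).max()


def test_lead_field_linearity_and_scale_law(small_geometry):
    ss, sa, _ = small_geometry
    lf = compute_lead_field(ss, sa, conductor_radius=0.09)
    s1 = np.zeros((ss.n_vertices, 1))
    s2 = np.zeros((ss.n_vertices, 1))
    s1[3] = 1.0
    s2[10] = 1.0
    lhs = lf.gain @ (2.0 * s1 + 3.0 * s2)
    rhs = 2.0 * (lf.gain @ s1) + 3.0 * (lf.gain @ s2)
    assert np.allclose(lhs, rhs, rtol=0, atol=1e-18)
    # doubling a dipole moment doubles every channel value exactly
    assert np.allclose(lf.gain @ (2 * s1), 2 * (lf.gain @ s1))
    # scaling all geometry by k rescales unit-dipole gains by k^-2
    ss2 = SourceSpace(2 * ss.vertex_positions, ss.triangles, ss.normals,
                      4 * ss.vertex_area)
    sa2 = build_sensor_cap(60, 0.24, 0.75)
    lf2 = compute_lead_field(ss2, sa2, conductor_radius=0.18)
    assert np.allclose(lf2.gain, lf.gain / 4.0, rtol=1e-9)


def test_normalize_lead_field_unit_median(small_geometry):
    _, _, lf = small_geometry
    assert np.isclose(np.median(np.linalg.norm(lf.gain, axis=0)), 1.0)


# --- patch growth ------------------------------------------------------------

def _flat_grid_source_space(n=9, h=np.sqrt(0.5e-4)):
    """Planar triangulated grid whose interior vertices all carry area h²."""
    xs, ys = np.meshgrid(np.arange(n) * h, np.arange(n) * h)
    vertices = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    tris = np.asarray(tris)
    normals, areas = _vertex_normals_and_areas(vertices, tris)
    return SourceSpace(vertices, tris, normals, areas)


def test_grow_patch_point_like(small_geometry):
    ss, _, _ = small_geometry
    p = grow_patch(ss, 5, 0.0)
    assert list(p.member_vertices) == [5]
    assert p.achieved_area == pytest.approx(ss.vertex_area[5] * 1e4)


def test_grow_patch_uniform_area_counts():
    """On a mesh with uniform 0.5 cm² vertices, a 2 cm² target takes exactly
    4 members (brute-force accumulation oracle)."""
    ss = _flat_grid_source_space()
    seed = 4 * 9 + 4  # central vertex, interior ring all interior
    assert np.isclose(ss.vertex_area[seed] * 1e4, 0.5)
    p = grow_patch(ss, seed, 2.0)
    assert len(p.member_vertices) == 4
    assert p.achieved_area >= 2.0 * (1 - 1e-9)
    # minimal covering: dropping the last-added vertex falls below target
    last_area = ss.vertex_area[p.member_vertices[-1]] * 1e4
    assert p.achieved_area - last_area < 2.0


def test_grow_patch_total_area_takes_all(small_geometry):
    ss, _, _ = small_geometry
    p = grow_patch(ss, 0, ss.total_area * 1e4)
    assert len(p.member_vertices) == ss.n_vertices
    with pytest.raises(InsufficientMeshError):
        grow_patch(ss, 0, ss.total_area * 1e4 * 1.01)


@pytest.mark.parametrize("seed_vertex", [0, 17, 101])
def test_grow_patch_monotone_in_target(small_geometry, seed_vertex):
    ss, _, _ = small_geometry
    members = [
        set(grow_patch(ss, seed_vertex, a).member_vertices.tolist())
        for a in (0.0, 2.0, 4.0, 8.0)
    ]
    for smaller, larger in zip(members, members[1:]):
        assert smaller <= larger
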