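"""Mesh constructors, atlas assembly, and topology invariants."""

import numpy as np
import pytest

from shapestage.errors import ConfigError, GeometryError, ParameterError
from shapestage.graph import adjacency_matrix
from shapestage.mesh import (
    DEFAULT_ATLAS_CONFIG,
    ShapeSpec,
    SphericalParam,
    build_atlas,
    build_icosphere,
    build_sphere_mesh,
    build_tube,
    build_uv_sphere,
    deform_to_structure,
    mesh_edges,
    validate_mesh,
)


@pytest.mark.parametrize(
    "kind,kwargs,expect_v",
    [
        ("icosphere", {"subdivisions": 0}, 12),
        ("icosphere", {"subdivisions": 1}, 42),  # V' = V + E, E = 30
        ("icosphere", {"subdivisions": 2}, 162),
        ("uv", {"rings": 5, "cols": 8}, 42),
        ("uv", {"rings": 10, "cols": 12}, 122),
    ],
)
def test_sphere_vertex_counts(kind, kwargs, expect_v):
    mesh = build_sphere_mesh(kind, **kwargs)
    assert mesh.n_vertices == expect_v
    validate_mesh(mesh)


def test_icosahedron_has_20_faces_and_degree_5():
    mesh = build_icosphere(0)
    assert mesh.n_faces == 20
    adj = adjacency_matrix(mesh_edges(mesh.faces), 12)
    assert (np.asarray(adj.sum(axis=1)).ravel() == 5).all()


@pytest.mark.parametrize("builder,args", [
    (build_icosphere, (3,)),
    (build_uv_sphere, (12, 20)),
    (lambda: build_tube(20.0, 2.0, rings=15, cols=12, bend=0.02), ()),
])
def test_euler_characteristic_is_two(builder, args):
    mesh = builder(*args)
    E = len(mesh_edges(mesh.faces))
    assert mesh.n_vertices - E + mesh.n_faces == 2
    validate_mesh(mesh)


def test_uv_vertex_count_mismatch_raises():
    with pytest.raises(ParameterError):
        build_sphere_mesh("uv", rings=5, cols=8, n_vertices=50)


def test_identity_deformation_preserves_vertices():
    mesh = build_icosphere(1)
    out = deform_to_structure(mesh, ShapeSpec(), seed=3)
    np.testing.assert_array_equal(out.vertices, mesh.vertices)
    np.testing.assert_array_equal(out.faces, mesh.faces)


def test_axis_scaling_doubles_extent():
    mesh = build_icosphere(2)
    out = deform_to_structure(mesh, ShapeSpec(axes=(2.0, 1.0, 1.0)), seed=0)
    d = np.linalg.norm(out.vertices[:, None] - out.vertices[None], axis=-1)
    assert d.max() == pytest.approx(4.0, rel=1e-6)


def test_bend_moves_section_centroids_off_axis():
    mesh = build_uv_sphere(12, 16)
    bent = deform_to_structure(mesh, ShapeSpec(axes=(10.0, 2.0, 2.0), bend=0.5), seed=0)
    # slice along x and check centroid y values are nonzero off-center
    x = bent.vertices[:, 0]
    sel = (x > 2) & (x < 8)
    assert np.abs(bent.vertices[sel, 1].mean()) > 0.1


def test_deform_is_deterministic_given_seed():
    mesh = build_icosphere(1)
    spec = ShapeSpec(axes=(3.0, 2.0, 1.0), bend=0.2, rotate=True)
    a = deform_to_structure(mesh, spec, seed=7)
    b = deform_to_structure(mesh, spec, seed=7)
    np.testing.assert_array_equal(a.vertices, b.vertices)
    c = deform_to_structure(mesh, spec, seed=8)
    assert not np.allclose(a.vertices, c.vertices)


def test_default_atlas_totals_27120_vertices():
    total = sum(e["rings"] * e["cols"] + 2 for e in DEFAULT_ATLAS_CONFIG)
    assert total == 27120
    assert len(DEFAULT_ATLAS_CONFIG) == 14


def test_toy_atlas_blocking_and_adjacency(toy_atlas):
    atlas = toy_atlas
    assert atlas.n_vertices == sum(m.n_vertices for m in atlas.meshes)
    # no cross-structure edges
    for key in atlas.structure_keys:
        start, stop = atlas.vertex_offsets[key]
        inside = (atlas.adjacency >= start) & (atlas.adjacency < stop)
        crossing = inside[:, 0] != inside[:, 1]
        assert not crossing.any()
    # symmetric, no self-loops
    assert (atlas.adjacency[:, 0] != atlas.adjacency[:, 1]).all()
    adj = adjacency_matrix(atlas.adjacency, atlas.n_vertices)
    assert (adj != adj.T).nnz == 0


def test_duplicate_structure_raises():
    config = [
        {"name": "putamen", "hemisphere": "left", "kind": "uv", "rings": 4, "cols": 8},
        {"name": "putamen", "hemisphere": "left", "kind": "uv", "rings": 4, "cols": 8},
    ]
    with pytest.raises(ConfigError):
        build_atlas(config)


def test_spherical_param_requires_unit_norm():
    with pytest.raises(ParameterError):
        SphericalParam(np.array([[1.0, 1.0, 0.0]]))


def test_validate_mesh_catches_broken_topology():
    mesh = build_icosphere(0)
    bad = mesh.faces.copy()
    bad[0] = bad[1]  # duplicate face
    from shapestage.mesh import SurfaceMesh

    with pytest.raises(GeometryError):
        validate_mesh(SurfaceMesh(mesh.vertices, bad))
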