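"""Registered spherical-topology meshes for the 14 subcortical structures.

Every structure is represented by a closed genus-0 triangle mesh obtained by
deforming a sphere (icosphere or uv-sphere).  The undeformed unit-sphere
vertex directions are kept as the per-vertex spherical registration used by
the spin permutation test.  Structures are assembled into a :class:`MeshAtlas`
with globally blocked 0-based vertex indices and a within-structure edge
adjacency; the default configuration totals 27,120 vertices over seven
bilateral structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, GeometryError, ParameterError

__all__ = [
    "SurfaceMesh",
    "SphericalParam",
    "ShapeSpec",
    "MeshAtlas",
    "build_sphere_mesh",
    "build_icosphere",
    "build_uv_sphere",
    "deform_to_structure",
    "build_atlas",
    "validate_mesh",
    "mesh_edges",
    "DEFAULT_ATLAS_CONFIG",
]


@dataclass
class SurfaceMesh:
    """Closed orientable triangle mesh for one subcortical structure."""

    vertices: np.ndarray  # (V, 3) float64, mm
    faces: np.ndarray  # (F, 3) int64, 0-based
    structure_name: str = ""
    hemisphere: str = ""  # "left" | "right" | ""

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ParameterError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ParameterError("faces must be an (F, 3) array")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]


@dataclass
class SphericalParam:
    """Per-vertex registration of a mesh onto the common unit sphere."""

    unit_coords: np.ndarray  # (V, 3), rows have unit norm

    def __post_init__(self):
        self.unit_coords = np.ascontiguousarray(self.unit_coords, dtype=np.float64)
        norms = np.linalg.norm(self.unit_coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ParameterError("spherical coordinates must have unit norm (±1e-9)")

    @property
    def n_vertices(self) -> int:
        return self.unit_coords.shape[0]


@dataclass
class ShapeSpec:
    """Ellipsoid axes plus bend/taper deformation for one structure.

    axes are half-axis lengths in mm along (x, y, z) of the unit sphere;
    ``bend`` curves the long (x) axis into a banana by displacing y
    quadratically, ``taper`` shrinks/grows the cross-section linearly
    along x.  ``center`` translates the structure in atlas space.
    """

    axes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bend: float = 0.0
    taper: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotate: bool = False  # seed-driven random orientation about the center

    def __post_init__(self):
        if min(self.axes) <= 0:
            raise ParameterError("axis lengths must be positive")


def mesh_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges (E, 2) with lo < hi, from triangle faces."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def validate_mesh(mesh: SurfaceMesh) -> None:
    """Check closed-orientable-manifold and spherical-topology invariants.

    Raises :class:`GeometryError` when the mesh has degenerate or duplicate
    faces, out-of-range indices, boundary or non-manifold edges, inconsistent
    winding, or Euler characteristic != 2.
    """
    V, F = mesh.n_vertices, mesh.n_faces
    faces = mesh.faces
    if faces.min(initial=0) < 0 or (F > 0 and faces.max() >= V):
        raise GeometryError("face indices out of range")
    if np.any(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    ):
        raise GeometryError("degenerate face (repeated vertex)")
    if len(np.unique(np.sort(faces, axis=1), axis=0)) != F:
        raise GeometryError("duplicate faces")
    # directed edges: orientability means each appears exactly once
    de = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    if len(np.unique(de, axis=0)) != 3 * F:
        raise GeometryError("inconsistent winding (repeated directed edge)")
    edges = mesh_edges(faces)
    # closed 2-manifold: every undirected edge shared by exactly two faces
    if 2 * len(edges) != 3 * F:
        raise GeometryError("mesh is not a closed 2-manifold")
    euler = V - len(edges) + F
    if euler != 2:
        raise GeometryError(f"Euler characteristic {euler} != 2 (not genus 0)")


# ---------------------------------------------------------------------------
# sphere constructors


def build_icosphere(subdivisions: int) -> SurfaceMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to unit sphere.

    V = 10 * 4**s + 2; s=0 is the icosahedron (12 vertices, 20 faces).
    """
    if subdivisions < 0:
        raise ParameterError("subdivisions must be >= 0")
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        vlist = list(verts)
        cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            idx = cache.get(key)
            if idx is None:
                m = vlist[a] + vlist[b]
                m = m / np.linalg.norm(m)
                idx = len(vlist)
                vlist.append(m)
                cache[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    return SurfaceMesh(verts, faces)


def build_uv_sphere(rings: int, cols: int) -> SurfaceMesh:
    """Latitude/longitude sphere with V = rings*cols + 2 (poles included)."""
    if rings < 1 or cols < 3:
        raise ParameterError("uv sphere needs rings >= 1 and cols >= 3")
    theta = np.pi * (np.arange(1, rings + 1)) / (rings + 1)
    phi = 2 * np.pi * np.arange(cols) / cols
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    ring_pts = np.column_stack(
        [
            (np.sin(tt) * np.cos(pp)).ravel(),
            (np.sin(tt) * np.sin(pp)).ravel(),
            np.cos(tt).ravel(),
        ]
    )
    verts = np.vstack([[0.0, 0.0, 1.0], ring_pts, [0.0, 0.0, -1.0]])
    north, south = 0, rings * cols + 1

    def vid(i: int, j: int) -> int:  # ring i, column j (wrapping)
        return 1 + i * cols + (j % cols)

    faces = []
    for j in range(cols):
        faces.append([north, vid(0, j), vid(0, j + 1)])
    for i in range(rings - 1):
        for j in range(cols):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    for j in range(cols):
        faces.append([south, vid(rings - 1, j + 1), vid(rings - 1, j)])
    return SurfaceMesh(verts, np.array(faces, dtype=np.int64))


def build_tube(
    length: float,
    radius: float,
    rings: int = 30,
    cols: int = 24,
    bend: float = 0.0,
) -> SurfaceMesh:
    """Capped-cylinder phantom along x, with an optional quadratic bend.

    The cross-section stays a circle of ``radius`` in the plane orthogonal to
    x; the centerline is y = bend * x**2 (analytically known, which makes the
    phantom a ground-truth oracle for medial-curve fitting).  Cone caps close
    the tube; topology matches a uv-sphere (V = rings*cols + 2).
    """
    if length <= 0 or radius <= 0:
        raise ParameterError("length and radius must be positive")
    base = build_uv_sphere(rings, cols)
    v = base.vertices.copy()
    # z of the uv sphere in [-1, 1] becomes the axial coordinate; the
    # sin(theta) radial falloff is replaced by a constant radius except at
    # the two pole caps which taper to points.
    axial = v[:, 2]
    rad = np.linalg.norm(v[:, :2], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.divide(v[:, :2], rad[:, None], out=np.zeros_like(v[:, :2]), where=rad[:, None] > 0)
    x = axial * (length / 2.0)
    yz = dirs * radius
    # taper only within the outermost 10% toward each cap so the body is a
    # true cylinder
    t = np.clip((np.abs(axial) - 0.9) / 0.1, 0.0, 1.0)
    yz *= (1.0 - t)[:, None]
    out = np.column_stack([x, yz[:, 0], yz[:, 1]])
    out[:, 1] += bend * out[:, 0] ** 2
    return SurfaceMesh(out, base.faces.copy(), "tube", "")


def build_sphere_mesh(
    kind: str,
    *,
    subdivisions: int | None = None,
    rings: int | None = None,
    cols: int | None = None,
    n_vertices: int | None = None,
) -> SurfaceMesh:
    """Build a unit sphere mesh of the requested kind.

    ``icosphere`` takes ``subdivisions`` (V = 10*4**s + 2); ``uv`` takes
    ``rings`` and ``cols`` (V = rings*cols + 2).  If ``n_vertices`` is given
    it must match exactly, otherwise a :class:`ParameterError` is raised.
    """
    if kind == "icosphere":
        if subdivisions is None:
            raise ParameterError("icosphere requires subdivisions")
        mesh = build_icosphere(subdivisions)
    elif kind == "uv":
        if rings is None or cols is None:
            raise ParameterError("uv sphere requires rings and cols")
        mesh = build_uv_sphere(rings, cols)
    else:
        raise ParameterError(f"unknown sphere kind {kind!r}")
    if n_vertices is not None and mesh.n_vertices != n_vertices:
        raise ParameterError(
            f"{kind} parameters give {mesh.n_vertices} vertices, "
            f"requested {n_vertices}"
        )
    if mesh.n_vertices < 12:
        raise ParameterError("need at least 12 vertices")
    return mesh


# ---------------------------------------------------------------------------
# deformation


def _triangles_intersect(t1: np.ndarray, t2: np.ndarray) -> bool:
    """Separating-axis test for two non-coplanar triangles."""
    axes = []
    e1 = [t1[1] - t1[0], t1[2] - t1[1], t1[0] - t1[2]]
    e2 = [t2[1] - t2[0], t2[2] - t2[1], t2[0] - t2[2]]
    axes.append(np.cross(e1[0], e1[1]))
    axes.append(np.cross(e2[0], e2[1]))
    for a in e1:
        for b in e2:
            axes.append(np.cross(a, b))
    for ax in axes:
        n = np.linalg.norm(ax)
        if n < 1e-12:
            continue
        ax = ax / n
        p1 = t1 @ ax
        p2 = t2 @ ax
        if p1.max() < p2.min() - 1e-12 or p2.max() < p1.min() - 1e-12:
            return False
    return True


def check_self_intersection(mesh: SurfaceMesh) -> bool:
    """Brute-force pairwise triangle test (intended for small meshes only).

    Pairs sharing a vertex are skipped.  Returns True when an intersecting
    pair is found.
    """
    tris = mesh.vertices[mesh.faces]  # (F, 3, 3)
    lo = tris.min(axis=1)
    hi = tris.max(axis=1)
    F = mesh.n_faces
    fsets = [set(f) for f in mesh.faces]
    for i in range(F):
        for j in range(i + 1, F):
            if fsets[i] & fsets[j]:
                continue
            if np.any(hi[i] < lo[j]) or np.any(hi[j] < lo[i]):
                continue
            if _triangles_intersect(tris[i], tris[j]):
                return True
    return False


def deform_to_structure(
    mesh: SurfaceMesh,
    shape_spec: ShapeSpec,
    seed: int = 0,
    *,
    check_intersections: bool = False,
) -> SurfaceMesh:
    """Deform a unit-sphere mesh into an ellipsoidal/banana-like structure.

    Topology (faces) is unchanged; vertices are scaled by the half-axes,
    optionally tapered and bent along the first axis, then translated to the
    structure center.  ``seed`` drives a deterministic random rotation of the
    structure about its center so that atlas structures are not all
    axis-aligned.  Deterministic given (mesh, shape_spec, seed).
    """
    ax, ay, az = shape_spec.axes
    v = mesh.vertices.copy()
    v[:, 0] *= ax
    v[:, 1] *= ay
    v[:, 2] *= az
    if shape_spec.taper:
        s = 1.0 + shape_spec.taper * v[:, 0] / ax
        if np.any(s <= 0):
            raise GeometryError("taper collapses the cross-section")
        v[:, 1] *= s
        v[:, 2] *= s
    if shape_spec.bend:
        v[:, 1] += shape_spec.bend * (v[:, 0] ** 2) / ax
    if shape_spec.rotate:
        rng = np.random.default_rng(seed)
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_quat(q).as_matrix()
        v = v @ R.T
    v += np.asarray(shape_spec.center, dtype=np.float64)
    out = SurfaceMesh(v, mesh.faces.copy(), mesh.structure_name, mesh.hemisphere)
    if check_intersections and check_self_intersection(out):
        raise GeometryError("deformation produced a self-intersecting mesh")
    return out


# ---------------------------------------------------------------------------
# atlas


@dataclass
class MeshAtlas:
    """Registered structures with blocked global vertex indexing."""

    meshes: list[SurfaceMesh]
    spheres: list[SphericalParam]
    vertex_offsets: dict[str, tuple[int, int]] = field(default_factory=dict)
    adjacency: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))

    @property
    def n_vertices(self) -> int:
        return sum(m.n_vertices for m in self.meshes)

    @property
    def structure_keys(self) -> list[str]:
        return [f"{m.structure_name}_{m.hemisphere}" for m in self.meshes]

    def structure_slice(self, key: str) -> slice:
        start, stop = self.vertex_offsets[key]
        return slice(start, stop)

    def mesh_for(self, key: str) -> SurfaceMesh:
        return self.meshes[self.structure_keys.index(key)]

    def sphere_for(self, key: str) -> SphericalParam:
        return self.spheres[self.structure_keys.index(key)]


# Default configuration: 7 bilateral structures, per-hemisphere uv-sphere
# vertex counts chosen with realistic relative sizes, summing to 27,120
# total.  Axes are rough mm half-axes for each structure; caudate and
# hippocampus get a bend to make the medial curve nontrivial.
DEFAULT_ATLAS_CONFIG: list[dict] = []
for _name, _rings, _cols, _axes, _bend, _taper, _cx in [
    ("thalamus", 54, 50, (15.0, 9.0, 8.0), 0.0, 0.0, 12.0),
    ("putamen", 48, 50, (16.0, 7.0, 6.0), 1.5, -0.2, 26.0),
    ("hippocampus", 45, 50, (18.0, 7.0, 6.0), 3.0, 0.3, 30.0),
    ("caudate", 42, 50, (17.0, 6.0, 5.0), 4.0, 0.4, 16.0),
    ("pallidum", 34, 44, (10.0, 6.0, 5.0), 0.0, 0.0, 21.0),
    ("amygdala", 35, 40, (9.0, 7.0, 6.0), 0.0, 0.2, 24.0),
    ("accumbens", 30, 40, (7.0, 5.0, 4.0), 0.0, 0.0, 10.0),
]:
    for _hemi, _sign in [("left", -1.0), ("right", 1.0)]:
        DEFAULT_ATLAS_CONFIG.append(
            {
                "name": _name,
                "hemisphere": _hemi,
                "kind": "uv",
                "rings": _rings,
                "cols": _cols,
                "axes": list(_axes),
                "bend": _bend,
                "taper": _taper,
                "center": [_sign * _cx, 0.0, 0.0],
            }
        )
del _name, _rings, _cols, _axes, _bend, _taper, _cx, _hemi, _sign


def build_atlas(config: list[dict] | None = None, seed: int = 0) -> MeshAtlas:
    """Assemble a :class:`MeshAtlas` from per-structure sphere + shape specs.

    The default configuration produces the full 14-structure atlas with
    27,120 vertices.  Adjacency is derived from shared face edges and never
    crosses structures.
    """
    if config is None:
        config = DEFAULT_ATLAS_CONFIG
    seen = set()
    meshes: list[SurfaceMesh] = []
    spheres: list[SphericalParam] = []
    offsets: dict[str, tuple[int, int]] = {}
    edge_blocks = []
    cursor = 0
    for i, entry in enumerate(config):
        key = (entry["name"], entry.get("hemisphere", ""))
        if key in seen:
            raise ConfigError(f"duplicate structure/hemisphere pair {key}")
        seen.add(key)
        kind = entry.get("kind", "uv")
        if kind == "uv":
            sphere = build_sphere_mesh("uv", rings=entry["rings"], cols=entry["cols"])
        else:
            sphere = build_sphere_mesh("icosphere", subdivisions=entry["subdivisions"])
        spec = ShapeSpec(
            axes=tuple(entry.get("axes", (1.0, 1.0, 1.0))),
            bend=entry.get("bend", 0.0),
            taper=entry.get("taper", 0.0),
            center=tuple(entry.get("center", (0.0, 0.0, 0.0))),
            rotate=entry.get("rotate", True),
        )
        mesh = deform_to_structure(sphere, spec, seed=seed + i)
        mesh.structure_name = entry["name"]
        mesh.hemisphere = entry.get("hemisphere", "")
        meshes.append(mesh)
        spheres.append(SphericalParam(sphere.vertices))
        skey = f"{mesh.structure_name}_{mesh.hemisphere}"
        offsets[skey] = (cursor, cursor + mesh.n_vertices)
        edge_blocks.append(mesh_edges(mesh.faces) + cursor)
        cursor += mesh.n_vertices
    adjacency = np.vstack(edge_blocks) if edge_blocks else np.empty((0, 2), np.int64)
    return MeshAtlas(meshes, spheres, offsets, adjacency)
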