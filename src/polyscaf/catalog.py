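"""Canonical polyhedron geometry and manufacturability screening.

The unit-cell candidates are the 18 convex solids that survive the
production-feasibility screen (Platonic and Archimedean solids, excluding
duals, prisms and antiprisms), labelled ``P-1`` through ``P-18``.  A small
set of nonconvex "spiky" fixtures (``F-*``) stands in for the stellated and
nonconvex forms that the screen eliminates.

All catalog solids are centered at the origin and scaled to unit
circumradius; downstream modules rescale.  Faces are recovered from the
vertex sets by convex-hull construction followed by coplanar-facet merging,
so the face tables are guaranteed consistent with the coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import trimesh
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull

__all__ = [
    "PolyhedronSpec",
    "ScreenReport",
    "ValidationReport",
    "CATALOG_IDS",
    "FIXTURE_IDS",
    "LIBRARY_IDS",
    "get_polyhedron",
    "list_polyhedra",
    "validate_polyhedron",
    "screen_criteria_A",
    "to_mesh",
    "export_mesh",
    "import_stl",
]

PHI = (1.0 + math.sqrt(5.0)) / 2.0
SQRT2 = math.sqrt(2.0)

#: geometric tolerance, relative to the (unit) circumradius
TOL = 1e-9


@dataclass(frozen=True)
class PolyhedronSpec:
    """One unit-cell polyhedron: identity plus canonical geometry."""

    id: str
    name: str
    vertices: np.ndarray  # (V, 3) float, unit circumradius
    faces: tuple[tuple[int, ...], ...]  # outward-oriented vertex cycles
    convex: bool
    isotropic_symmetry: bool  # full octahedral symmetry family

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        seen = set()
        for cycle in self.faces:
            n = len(cycle)
            for k in range(n):
                a, b = cycle[k], cycle[(k + 1) % n]
                seen.add((min(a, b), max(a, b)))
        return tuple(sorted(seen))

    @property
    def euler_characteristic(self) -> int:
        return len(self.vertices) - len(self.edges) + len(self.faces)

    def face_normal_offset(self, face_index: int) -> tuple[np.ndarray, float]:
        """Outward unit normal and plane offset d (plane is ``n·p = d``)."""
        cycle = self.faces[face_index]
        pts = self.vertices[list(cycle)]
        centroid = pts.mean(axis=0)
        n = np.zeros(3)
        for k in range(len(pts)):  # Newell's method: robust for any cycle
            a, b = pts[k], pts[(k + 1) % len(pts)]
            n += np.cross(a - centroid, b - centroid)
        n /= np.linalg.norm(n)
        return n, float(n @ centroid)


@dataclass(frozen=True)
class ValidationReport:
    id: str
    euler_characteristic: int
    watertight: bool
    convex: bool
    faces_planar: bool
    problems: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.problems


@dataclass(frozen=True)
class ScreenReport:
    """Production-feasibility screen: can the cell be printed at all?"""

    id: str
    convex: bool
    min_feature: float  # shortest edge / largest bounding-box edge
    passes_criteria_A: bool


# ---------------------------------------------------------------------------
# vertex generators


def _signs(base: Sequence[float], which: Sequence[int]) -> list[tuple[float, ...]]:
    """All sign flips of the coordinates listed in *which* (skip zeros)."""
    out = [tuple(base)]
    for i in which:
        if base[i] == 0:
            continue
        out = [v for v in out] + [
            tuple(-x if k == i else x for k, x in enumerate(v)) for v in out
        ]
    return out


def _all_signs(base):
    return _signs(base, (0, 1, 2))


def _perms(vals, even_only=False):
    idx = [(0, 1, 2), (1, 2, 0), (2, 0, 1), (0, 2, 1), (2, 1, 0), (1, 0, 2)]
    if even_only:
        idx = idx[:3]
    return [tuple(vals[i] for i in p) for p in idx]


def _dedupe(points, tol=1e-9):
    out = []
    for p in points:
        if not any(max(abs(p[k] - q[k]) for k in range(3)) < tol for q in out):
            out.append(p)
    return np.array(out, dtype=float)


def _orbit(bases, *, perms="all", sign_rule="all"):
    """Expand base points by coordinate permutations and sign changes."""
    pts = []
    for base in bases:
        for perm in _perms(base, even_only=(perms == "even")):
            if sign_rule == "all":
                pts.extend(_all_signs(perm))
            elif sign_rule == "even":
                for v in _all_signs(perm):
                    neg = sum(1 for x in v if x < 0)
                    if neg % 2 == 0:
                        pts.append(v)
            elif sign_rule == "none":
                pts.append(perm)
            else:  # pragma: no cover
                raise ValueError(sign_rule)
    return _dedupe(pts)


def _snub_cube_vertices() -> np.ndarray:
    # tribonacci constant
    t = (1 + (19 + 3 * math.sqrt(33)) ** (1 / 3) + (19 - 3 * math.sqrt(33)) ** (1 / 3)) / 3
    base = (1.0, 1.0 / t, t)
    pts = []
    for perm, parity in [((0, 1, 2), 0), ((1, 2, 0), 0), ((2, 0, 1), 0),
                         ((0, 2, 1), 1), ((2, 1, 0), 1), ((1, 0, 2), 1)]:
        v = tuple(base[i] for i in perm)
        for s in _all_signs(v):
            neg = sum(1 for x in s if x < 0)
            if neg % 2 == parity:
                pts.append(s)
    return _dedupe(pts)


def _icosahedral_rotations() -> np.ndarray:
    """The 60 rotation matrices of the icosahedral group, by closure."""

    def rot(axis, angle):
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)

    # 5-fold about an icosahedron vertex, 3-fold about a face center
    g1 = rot((0.0, 1.0, PHI), 2 * math.pi / 5)
    g2 = rot((1.0, 1.0, 1.0), 2 * math.pi / 3)
    group = [np.eye(3)]
    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for m in frontier:
            for g in (g1, g2):
                c = g @ m
                if not any(np.allclose(c, h, atol=1e-9) for h in group):
                    group.append(c)
                    nxt.append(c)
        frontier = nxt
    assert len(group) == 60
    return np.array(group)


def _snub_dodecahedron_vertices() -> np.ndarray:
    """Solve for the snub dodecahedron as a chiral orbit of one point.

    The vertex set is the orbit of a single generator point under the 60
    icosahedral rotations; the generator is fixed (up to symmetry) by
    requiring its five nearest orbit neighbours to be equidistant.
    """
    rots = _icosahedral_rotations()

    def orbit(p):
        return rots @ p

    def residual(uv):
        u, v = uv
        p = np.array([math.sin(u) * math.cos(v), math.sin(u) * math.sin(v), math.cos(u)])
        pts = orbit(p)
        d = np.linalg.norm(pts - p, axis=1)
        d = np.sort(d)[1:6]  # five nearest neighbours (skip self)
        return d[1:] - d[0]

    for seed in ((0.4092, 0.7233), (0.8547, 0.4644), (1.0336, 0.4753)):
        sol = least_squares(residual, x0=seed, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if np.max(np.abs(residual(sol.x))) < 1e-8:
            u, v = sol.x
            p = np.array([math.sin(u) * math.cos(v), math.sin(u) * math.sin(v), math.cos(u)])
            pts = orbit(p)
            # guard against degenerate orbits (coincident points)
            if min(np.linalg.norm(pts[0] - q) for q in pts[1:]) > 1e-6:
                return pts
    raise RuntimeError("snub dodecahedron orbit solve failed to converge")


_XI_TH = SQRT2 - 1.0  # truncated hexahedron parameter

_VERTEX_BUILDERS = {
    "P-1": lambda: np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], float),
    "P-2": lambda: _orbit([(1.0, 0.0, 0.0)]),
    "P-3": lambda: _dedupe(_all_signs((1.0, 1.0, 1.0))),
    "P-4": lambda: _orbit([(0.0, 1.0, PHI)], perms="even"),
    "P-5": lambda: np.vstack(
        [_dedupe(_all_signs((1.0, 1.0, 1.0))), _orbit([(0.0, 1 / PHI, PHI)], perms="even")]
    ),
    "P-6": lambda: _orbit([(1.0, 1.0, 3.0)], sign_rule="even"),
    "P-7": lambda: _orbit([(0.0, 1.0, 2.0)]),
    "P-8": lambda: _orbit([(_XI_TH, 1.0, 1.0)]),
    "P-9": lambda: np.vstack(
        [
            _orbit([(0.0, 1.0, 3.0 * PHI)], perms="even"),
            _orbit([(1.0, 2.0 + PHI, 2.0 * PHI)], perms="even"),
            _orbit([(2.0, 1.0 + 2.0 * PHI, PHI)], perms="even"),
        ]
    ),
    "P-10": lambda: np.vstack(
        [
            _orbit([(0.0, 1 / PHI, 2.0 + PHI)], perms="even"),
            _orbit([(1 / PHI, PHI, 2.0 * PHI)], perms="even"),
            _orbit([(PHI, 2.0, PHI + 1.0)], perms="even"),
        ]
    ),
    "P-11": lambda: _orbit([(1.0, 1.0, 0.0)]),
    "P-12": lambda: np.vstack(
        [_orbit([(0.0, 0.0, 2.0 * PHI)], perms="even"), _orbit([(1.0, PHI, PHI * PHI)], perms="even")]
    ),
    "P-13": lambda: _orbit([(1.0, 1.0, 1.0 + SQRT2)]),
    "P-14": lambda: np.vstack(
        [
            _orbit([(1.0, 1.0, PHI**3)], perms="even"),
            _orbit([(PHI**2, PHI, 2.0 * PHI)], perms="even"),
            _orbit([(2.0 + PHI, 0.0, PHI**2)], perms="even"),
        ]
    ),
    "P-15": lambda: _orbit([(1.0, 1.0 + SQRT2, 1.0 + 2.0 * SQRT2)]),
    "P-16": lambda: np.vstack(
        [
            _orbit([(1 / PHI, 1 / PHI, 3.0 + PHI)], perms="even"),
            _orbit([(2 / PHI, PHI, 1.0 + 2.0 * PHI)], perms="even"),
            _orbit([(1 / PHI, PHI**2, 3.0 * PHI - 1.0)], perms="even"),
            _orbit([(2.0 * PHI - 1.0, 2.0, 2.0 + PHI)], perms="even"),
            _orbit([(PHI, 3.0, 2.0 * PHI)], perms="even"),
        ]
    ),
    "P-17": _snub_cube_vertices,
    "P-18": _snub_dodecahedron_vertices,
}

_NAMES = {
    "P-1": "tetrahedron",
    "P-2": "octahedron",
    "P-3": "hexahedron",
    "P-4": "icosahedron",
    "P-5": "dodecahedron",
    "P-6": "truncated tetrahedron",
    "P-7": "truncated octahedron",
    "P-8": "truncated hexahedron",
    "P-9": "truncated icosahedron",
    "P-10": "truncated dodecahedron",
    "P-11": "cuboctahedron",
    "P-12": "icosidodecahedron",
    "P-13": "rhombicuboctahedron",
    "P-14": "rhombicosidodecahedron",
    "P-15": "rhombitruncated cuboctahedron",
    "P-16": "rhombitruncated icosidodecahedron",
    "P-17": "snub cube",
    "P-18": "snub dodecahedron",
}

#: solids with the full (reflective) octahedral symmetry; these are the ones
#: that tile along Cartesian axes with conforming axial faces
_ISOTROPIC = {"P-2", "P-3", "P-7", "P-8", "P-11", "P-13", "P-15"}

CATALOG_IDS: tuple[str, ...] = tuple(f"P-{k}" for k in range(1, 19))
FIXTURE_IDS: tuple[str, ...] = ("F-1", "F-2", "F-3")
#: the six open-cellular scaffold libraries
LIBRARY_IDS: tuple[str, ...] = ("P-3", "P-7", "P-8", "P-11", "P-13", "P-15")


# ---------------------------------------------------------------------------
# hull -> polygonal faces


def _faces_from_hull(vertices: np.ndarray) -> tuple[tuple[int, ...], ...]:
    """Recover outward-oriented polygonal faces of a convex vertex set."""
    hull = ConvexHull(vertices)
    # group hull simplices by their (rounded) supporting plane
    groups: dict[tuple, list[int]] = {}
    for simplex, eq in zip(hull.simplices, hull.equations):
        key = tuple(np.round(eq, 7))
        groups.setdefault(key, []).extend(simplex)
    faces = []
    for key, idx in groups.items():
        ids = sorted(set(idx))
        n = np.array(key[:3])
        n = n / np.linalg.norm(n)
        pts = vertices[ids]
        centroid = pts.mean(axis=0)
        # order around the face normal
        u = pts[0] - centroid
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        ang = np.arctan2((pts - centroid) @ v, (pts - centroid) @ u)
        order = np.argsort(ang)
        cycle = tuple(ids[k] for k in order)
        # enforce outward winding (counter-clockwise seen from outside)
        a, b, c = vertices[cycle[0]], vertices[cycle[1]], vertices[cycle[2]]
        if np.dot(np.cross(b - a, c - a), n) < 0:
            cycle = cycle[::-1]
        faces.append(cycle)
    return tuple(sorted(faces))


def _normalize(vertices: np.ndarray) -> np.ndarray:
    v = vertices - vertices.mean(axis=0)
    return v / np.max(np.linalg.norm(v, axis=1))


def _kleetope(base: PolyhedronSpec, height: float, id_: str, name: str) -> PolyhedronSpec:
    """Erect a pyramid on every face: watertight, deliberately nonconvex."""
    verts = [tuple(p) for p in base.vertices]
    faces: list[tuple[int, ...]] = []
    for fi, cycle in enumerate(base.faces):
        n, _ = base.face_normal_offset(fi)
        centroid = base.vertices[list(cycle)].mean(axis=0)
        apex = centroid + height * n
        verts.append(tuple(apex))
        ai = len(verts) - 1
        m = len(cycle)
        for k in range(m):
            faces.append((cycle[k], cycle[(k + 1) % m], ai))
    v = _normalize(np.array(verts))
    return PolyhedronSpec(id=id_, name=name, vertices=v, faces=tuple(faces),
                          convex=False, isotropic_symmetry=False)


@lru_cache(maxsize=None)
def _build(id_: str) -> PolyhedronSpec:
    if id_ in _VERTEX_BUILDERS:
        v = _normalize(_VERTEX_BUILDERS[id_]())
        faces = _faces_from_hull(v)
        return PolyhedronSpec(
            id=id_, name=_NAMES[id_], vertices=v, faces=faces,
            convex=True, isotropic_symmetry=id_ in _ISOTROPIC,
        )
    if id_ == "F-1":
        # stellated octahedron: regular tetrahedral spikes on the octahedron
        base = _build("P-2")
        # apex height that makes each spike a regular tetrahedron
        edge = np.linalg.norm(base.vertices[base.faces[0][0]] - base.vertices[base.faces[0][1]])
        h = edge * math.sqrt(2.0 / 3.0) - 0.0  # regular-tetrahedron height
        return _kleetope(base, h, "F-1", "stellated octahedron (fixture)")
    if id_ == "F-2":
        return _kleetope(_build("P-3"), 0.8, "F-2", "spiky hexahedron (fixture)")
    if id_ == "F-3":
        return _kleetope(_build("P-5"), 0.9, "F-3", "spiky dodecahedron (fixture)")
    raise KeyError(f"unknown polyhedron id: {id_!r}")


def get_polyhedron(id_: str) -> PolyhedronSpec:
    """Return the validated canonical geometry for a catalog or fixture id."""
    if id_ not in CATALOG_IDS and id_ not in FIXTURE_IDS:
        raise KeyError(f"unknown polyhedron id: {id_!r}")
    return _build(id_)


def list_polyhedra() -> tuple[str, ...]:
    return CATALOG_IDS + FIXTURE_IDS


# ---------------------------------------------------------------------------
# validation and screening


def _edge_face_count(faces) -> dict[tuple[int, int], int]:
    count: dict[tuple[int, int], int] = {}
    for cycle in faces:
        m = len(cycle)
        for k in range(m):
            a, b = cycle[k], cycle[(k + 1) % m]
            e = (min(a, b), max(a, b))
            count[e] = count.get(e, 0) + 1
    return count


def validate_polyhedron(spec: PolyhedronSpec, tol: float = TOL) -> ValidationReport:
    """Check Euler characteristic, watertightness, convexity, face planarity.

    Failures are reported, not raised.
    """
    if len(spec.vertices) < 4:
        raise ValueError("a polyhedron needs at least 4 vertices")
    problems = []

    counts = _edge_face_count(spec.faces)
    watertight = all(c == 2 for c in counts.values())
    if not watertight:
        problems.append("not watertight: some edges are not shared by exactly 2 faces")

    euler = len(spec.vertices) - len(counts) + len(spec.faces)
    if euler != 2:
        problems.append(f"Euler characteristic {euler} != 2")

    scale = np.max(np.linalg.norm(spec.vertices, axis=1))
    planar = True
    convex = True
    for fi, cycle in enumerate(spec.faces):
        n, d = spec.face_normal_offset(fi)
        dev = np.abs(spec.vertices[list(cycle)] @ n - d)
        if dev.max() > tol * scale * 1e3:  # planarity tolerance
            planar = False
        if (spec.vertices @ n - d).max() > tol * scale * 1e3:
            convex = False
    if not planar:
        problems.append("some faces are not planar")
    if spec.convex and not convex:
        problems.append("flagged convex but a vertex lies outside a face plane")

    return ValidationReport(
        id=spec.id, euler_characteristic=euler, watertight=watertight,
        convex=convex, faces_planar=planar, problems=tuple(problems),
    )


def screen_criteria_A(spec: PolyhedronSpec, min_feature_fraction: float = 0.05) -> ScreenReport:
    """Production-feasibility screen for laser-based additive manufacturing.

    Nonconvex (stellated, spiky) forms fail outright: their fine geometric
    details fall below the laser spot / particle size of SLM/SLS/SL devices.
    Convex forms fail if their shortest edge is smaller than
    ``min_feature_fraction`` of the largest bounding-box edge.
    """
    if min_feature_fraction <= 0:
        raise ValueError("min_feature_fraction must be positive")
    report = validate_polyhedron(spec)
    edges = spec.edges
    lengths = [np.linalg.norm(spec.vertices[a] - spec.vertices[b]) for a, b in edges]
    bbox = spec.vertices.max(axis=0) - spec.vertices.min(axis=0)
    min_feature = float(min(lengths) / bbox.max())
    passes = report.convex and spec.convex and min_feature >= min_feature_fraction
    return ScreenReport(id=spec.id, convex=report.convex and spec.convex,
                        min_feature=min_feature, passes_criteria_A=bool(passes))


# ---------------------------------------------------------------------------
# mesh I/O


def to_mesh(spec: PolyhedronSpec) -> trimesh.Trimesh:
    """Triangulated (fan) surface mesh of a polyhedron spec."""
    tris = []
    for cycle in spec.faces:
        for k in range(1, len(cycle) - 1):
            tris.append((cycle[0], cycle[k], cycle[k + 1]))
    mesh = trimesh.Trimesh(vertices=spec.vertices.copy(), faces=np.array(tris), process=False)
    return mesh


def export_mesh(spec: PolyhedronSpec, path: str) -> None:
    """Write a spec to STL (ascii for .stl via trimesh) or OBJ by extension."""
    to_mesh(spec).export(path)


def import_stl(path: str) -> trimesh.Trimesh:
    """Load a user-supplied unit-cell mesh."""
    mesh = trimesh.load(path, force="mesh")
    if not isinstance(mesh, trimesh.Trimesh):  # pragma: no cover
        raise ValueError(f"could not read a triangle mesh from {path}")
    return mesh
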