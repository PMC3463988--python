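"""Close- and open-cellular unit-cell construction.

A close cell is the solid polyhedron itself.  An open cell is the polyhedron
wireframe thickened into beams of thickness ``BT``: each edge carries a
prismatic beam whose cross-section is bounded by planes parallel to the two
adjacent polyhedron faces at perpendicular distance ``BT/2`` from the edge
axis, so one beam face lies flush in each adjacent polyhedron face plane.
For the hexahedron this reduces to axis-aligned square-section beams and
gives the closed-form tiled solid fraction ``(3x+1)/(x+1)**3`` with
``x = PO/BT``.

The pore size ``PO`` is the diameter of the largest inscribed circle over
all face windows after thickening (the largest face opening).  Cells are
sized so that this designated window measures exactly ``PO``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import trimesh
from scipy.optimize import brentq, linprog

from .catalog import PolyhedronSpec, get_polyhedron

__all__ = [
    "OpenCellSpec",
    "CellMesh",
    "Beam",
    "build_close_cell",
    "build_open_cell",
    "open_cell_frame",
    "face_windows",
    "cell_scale_for_ratio",
    "export_cell",
]


@dataclass(frozen=True)
class OpenCellSpec:
    """Open-cellular design point: which solid, pore size, beam thickness."""

    polyhedron: PolyhedronSpec
    PO: float
    BT: float
    beam_section: str = "square"  # or "circular"

    def __post_init__(self):
        if self.PO <= 0:
            raise ValueError("pore size PO must be positive")
        if self.BT <= 0:
            raise ValueError("beam thickness BT must be positive")
        if self.beam_section not in ("square", "circular"):
            raise ValueError(f"unknown beam section {self.beam_section!r}")

    @property
    def ratio(self) -> float:
        """The design parameter x = PO : BT."""
        return self.PO / self.BT


@dataclass(frozen=True)
class Beam:
    """One thickened wireframe edge.

    The cross-section is the parallelogram ``|q·n1| <= h`` and ``|q·n2| <= h``
    (``n1``/``n2`` the adjacent face normals), or a circle of radius ``h``
    for circular sections.  Beams extend ``ext`` beyond each edge endpoint so
    that junctions at shared vertices close under union.
    """

    a: np.ndarray
    b: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    h: float
    ext: float
    section: str = "square"

    @property
    def axis(self) -> np.ndarray:
        t = self.b - self.a
        return t / np.linalg.norm(t)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.b - self.a))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (N, 3) array of points."""
        rel = points - self.a
        t = self.axis
        s = rel @ t
        ok = (s >= -self.ext) & (s <= self.length + self.ext)
        if self.section == "square":
            ok &= np.abs(rel @ self.n1) <= self.h
            ok &= np.abs(rel @ self.n2) <= self.h
        else:
            perp = rel - np.outer(s, t)
            ok &= (perp * perp).sum(axis=1) <= self.h * self.h
        return ok

    def corners(self) -> np.ndarray:
        """The 8 corners of the (extended) beam parallelepiped."""
        t = self.axis
        if self.section == "square":
            M = np.array([self.n1, self.n2, t])
            q = [np.linalg.solve(M, np.array([s1 * self.h, s2 * self.h, 0.0]))
                 for s1 in (-1, 1) for s2 in (-1, 1)]
        else:  # bounding square of the circular section
            u = self.n1 - (self.n1 @ t) * t
            u /= np.linalg.norm(u)
            v = np.cross(t, u)
            q = [s1 * self.h * u + s2 * self.h * v for s1 in (-1, 1) for s2 in (-1, 1)]
        lo = self.a - self.ext * t
        hi = self.b + self.ext * t
        return np.array([lo + qq for qq in q] + [hi + qq for qq in q])

    def aabb(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.corners()
        return c.min(axis=0), c.max(axis=0)

    def translated(self, offset: np.ndarray) -> "Beam":
        return Beam(self.a + offset, self.b + offset, self.n1, self.n2,
                    self.h, self.ext, self.section)

    def dilated(self, eps: float) -> "Beam":
        """Minkowski-style inflation used for conservative connectivity."""
        return Beam(self.a, self.b, self.n1, self.n2,
                    self.h + eps, self.ext + eps, self.section)


@dataclass(frozen=True)
class Node:
    """Convex junction solid at a wireframe vertex.

    The convex hull of the end caps of all beams incident to the vertex;
    fills the sliver gaps that bare beam unions leave at junctions.  For the
    hexahedron this is exactly the corner cube of the beam frame.
    """

    planes_A: np.ndarray  # (K, 3) unit outward normals
    planes_b: np.ndarray  # (K,)
    points: np.ndarray  # hull points (for AABB)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.all(points @ self.planes_A.T <= self.planes_b + 1e-12, axis=1)

    def aabb(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points.min(axis=0), self.points.max(axis=0)

    def translated(self, offset: np.ndarray) -> "Node":
        return Node(self.planes_A, self.planes_b + self.planes_A @ offset,
                    self.points + offset)

    def dilated(self, eps: float) -> "Node":
        return Node(self.planes_A, self.planes_b + eps, self.points)


@dataclass
class CellMesh:
    """A built unit cell: surface mesh plus the analytic model behind it."""

    mesh: trimesh.Trimesh | None
    form: str  # "close" | "open"
    source: object  # OpenCellSpec for open cells, PolyhedronSpec for close
    repeat_length: float
    scale: float  # factor applied to the unit-circumradius catalog geometry
    frame: tuple[Beam, ...] | None = None
    nodes: tuple[Node, ...] | None = None
    volume_estimate: float | None = None  # voxel-count volume for open cells

    @property
    def solids(self) -> tuple:
        """All analytic primitives of an open cell (beams + junction nodes)."""
        return tuple(self.frame or ()) + tuple(self.nodes or ())

    @property
    def bounding_box(self) -> np.ndarray:
        if self.mesh is not None:
            return self.mesh.bounds[1] - self.mesh.bounds[0]
        lo = np.min([s.aabb()[0] for s in self.solids], axis=0)
        hi = np.max([s.aabb()[1] for s in self.solids], axis=0)
        return hi - lo

    @property
    def volume(self) -> float:
        if self.volume_estimate is not None:
            return self.volume_estimate
        return float(self.mesh.volume)

    @property
    def polyhedron(self) -> PolyhedronSpec:
        if self.form == "open":
            return self.source.polyhedron
        return self.source


# ---------------------------------------------------------------------------
# face windows and cell sizing


def _axial_face_offset(spec: PolyhedronSpec) -> float:
    """Plane offset of the +x contact face (unit-circumradius geometry)."""
    for fi in range(len(spec.faces)):
        n, d = spec.face_normal_offset(fi)
        if n[0] > 1.0 - 1e-9:
            return d
    raise ValueError(f"{spec.id} has no axis-normal contact face")


def _face_basis(spec: PolyhedronSpec, fi: int):
    n, d = spec.face_normal_offset(fi)
    cycle = spec.faces[fi]
    c = spec.vertices[list(cycle)].mean(axis=0)
    u = spec.vertices[cycle[0]] - c
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    return n, d, c, u, v


def _window_radius(spec: PolyhedronSpec, fi: int, scale: float, h: float) -> float:
    """Inscribed-circle radius of face ``fi``'s opening after thickening.

    The opening is the set of in-plane points at depth > ``h`` below every
    other face plane of the (scaled) polyhedron: exactly the face polygon
    minus the flush beam strips along its edges.  Returns 0 if the window is
    sealed.
    """
    n, d, c, u, v = _face_basis(spec, fi)
    A, bvec = [], []
    for gi in range(len(spec.faces)):
        if gi == fi:
            continue
        ng, dg = spec.face_normal_offset(gi)
        a2 = np.array([u @ ng, v @ ng])
        rhs = scale * dg - h - scale * (c @ ng)
        A.append(a2)
        bvec.append(rhs)
    A = np.array(A)
    bvec = np.array(bvec)
    norms = np.linalg.norm(A, axis=1)
    # Chebyshev center: max r s.t. A q + ||A_i|| r <= b
    res = linprog(
        c=[0.0, 0.0, -1.0],
        A_ub=np.column_stack([A, norms]),
        b_ub=bvec,
        bounds=[(None, None), (None, None), (0, None)],
        method="highs",
    )
    if not res.success or res.x is None:
        return 0.0
    return max(0.0, float(res.x[2]))


def face_windows(spec: PolyhedronSpec, scale: float, BT: float) -> list[float]:
    """Inscribed-circle diameters of every face opening after thickening."""
    h = BT / 2.0
    return [2.0 * _window_radius(spec, fi, scale, h) for fi in range(len(spec.faces))]


@lru_cache(maxsize=None)
def _scale_for_ratio_unit_bt(poly_id: str, ratio: float) -> float:
    """Scale of the unit-circumradius solid so max window = ratio, at BT=1."""
    spec = get_polyhedron(poly_id)
    h = 0.5

    def g(s):
        return max(_window_radius(spec, fi, s, h) for fi in range(len(spec.faces))) * 2.0 - ratio

    lo, hi = 1e-3, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover
            raise RuntimeError("window size failed to bracket")
    return float(brentq(g, lo, hi, xtol=1e-12 * hi))


def cell_scale_for_ratio(spec: PolyhedronSpec, PO: float, BT: float) -> float:
    """Scale factor for the catalog geometry so the largest window is PO."""
    return _scale_for_ratio_unit_bt(spec.id, PO / BT) * BT


# ---------------------------------------------------------------------------
# construction


def build_close_cell(spec: PolyhedronSpec, scale: float) -> CellMesh:
    """Solid (close-cellular) unit cell with lattice repeat length *scale*."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not spec.convex:
        raise ValueError(f"{spec.id} is not convex; close cells must be convex")
    d_ax = _axial_face_offset(spec)
    s = scale / (2.0 * d_ax)
    tris = []
    for cycle in spec.faces:
        for k in range(1, len(cycle) - 1):
            tris.append((cycle[0], cycle[k], cycle[k + 1]))
    mesh = trimesh.Trimesh(vertices=spec.vertices * s, faces=np.array(tris), process=False)
    return CellMesh(mesh=mesh, form="close", source=spec,
                    repeat_length=scale, scale=s)


def _section_corners(beam: Beam) -> np.ndarray:
    """The 4 cross-section corner offsets of a beam."""
    t = beam.axis
    if beam.section == "square":
        M = np.array([beam.n1, beam.n2, t])
        return np.array([
            np.linalg.solve(M, np.array([s1 * beam.h, s2 * beam.h, 0.0]))
            for s1 in (-1, 1) for s2 in (-1, 1)
        ])
    u = beam.n1 - (beam.n1 @ t) * t
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return np.array([s1 * beam.h * u + s2 * beam.h * v
                     for s1 in (-1, 1) for s2 in (-1, 1)])


def _junction_nodes(beams: tuple[Beam, ...], vertices: np.ndarray) -> tuple[Node, ...]:
    """Convex hull node at each vertex from the incident beam end caps."""
    from scipy.spatial import ConvexHull

    incident: dict[int, list[np.ndarray]] = {}
    for beam in beams:
        q = _section_corners(beam)
        t = beam.axis
        for endpoint, cap in ((beam.a, beam.a - beam.ext * t),
                              (beam.b, beam.b + beam.ext * t)):
            vi = int(np.argmin(np.linalg.norm(vertices - endpoint, axis=1)))
            incident.setdefault(vi, []).extend(cap + qq for qq in q)
    nodes = []
    for vi, pts in incident.items():
        pts = np.array(pts)
        hull = ConvexHull(pts, qhull_options="QJ")  # joggle: caps may be coplanar
        A = hull.equations[:, :3]
        b = -hull.equations[:, 3]
        nodes.append(Node(planes_A=A, planes_b=b, points=pts))
    return tuple(nodes)


def open_cell_frame(cell: OpenCellSpec) -> tuple[tuple[Beam, ...], float]:
    """Beam frame of an open cell and its lattice repeat length."""
    spec = cell.polyhedron
    s = cell_scale_for_ratio(spec, cell.PO, cell.BT)
    h = cell.BT / 2.0
    verts = spec.vertices * s
    # adjacent faces per edge
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, cycle in enumerate(spec.faces):
        m = len(cycle)
        for k in range(m):
            e = (min(cycle[k], cycle[(k + 1) % m]), max(cycle[k], cycle[(k + 1) % m]))
            edge_faces.setdefault(e, []).append(fi)
    beams = []
    for (i, j), fis in sorted(edge_faces.items()):
        if len(fis) != 2:
            raise ValueError(
                f"{spec.id}: edge {(i, j)} shared by {len(fis)} faces; cannot build beams"
            )
        n1, _ = spec.face_normal_offset(fis[0])
        n2, _ = spec.face_normal_offset(fis[1])
        beams.append(Beam(a=verts[i], b=verts[j], n1=n1, n2=n2, h=h, ext=h,
                          section=cell.beam_section))
    L = 2.0 * _axial_face_offset(spec) * s
    return tuple(beams), L


def _rasterize_solids(solids, origin, shape, pitch) -> np.ndarray:
    """OR each convex solid (beam or node) into a fresh occupancy grid
    (center-sampling rule)."""
    occ = np.zeros(shape, dtype=bool)
    for beam in solids:
        lo, hi = beam.aabb()
        i0 = np.maximum(0, np.floor((lo - origin) / pitch - 0.5).astype(int))
        i1 = np.minimum(shape, np.ceil((hi - origin) / pitch + 0.5).astype(int))
        if np.any(i0 >= i1):
            continue
        xs = origin[0] + (np.arange(i0[0], i1[0]) + 0.5) * pitch
        ys = origin[1] + (np.arange(i0[1], i1[1]) + 0.5) * pitch
        zs = origin[2] + (np.arange(i0[2], i1[2]) + 0.5) * pitch
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        mask = beam.contains(pts).reshape(X.shape)
        occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= mask
    return occ


def build_open_cell(cell: OpenCellSpec, pitch: float | None = None) -> CellMesh:
    """Open-cellular unit cell: union of edge beams, realized on a voxel grid.

    The surface mesh is extracted with marching cubes from the occupancy
    grid (watertight by construction); the beam frame is kept alongside for
    exact downstream geometry.  Default voxel pitch is ``BT/4``.
    """
    from skimage.measure import marching_cubes

    beams, L = open_cell_frame(cell)
    spec = cell.polyhedron
    s = cell_scale_for_ratio(spec, cell.PO, cell.BT)
    nodes = _junction_nodes(beams, spec.vertices * s)
    solids = beams + nodes
    if pitch is None:
        pitch = cell.BT / 4.0
    if pitch > cell.BT / 2.0:
        raise ValueError(f"pitch {pitch} too coarse: must be <= BT/2 = {cell.BT / 2.0}")
    lo = np.min([b.aabb()[0] for b in solids], axis=0) - pitch
    hi = np.max([b.aabb()[1] for b in solids], axis=0) + pitch
    shape = tuple(np.ceil((hi - lo) / pitch).astype(int))
    occ = _rasterize_solids(solids, lo, shape, pitch)
    if not occ.any():  # pragma: no cover
        raise RuntimeError("open-cell rasterization produced an empty grid")
    padded = np.pad(occ, 1)
    verts, faces, _, _ = marching_cubes(padded.astype(np.float32), level=0.5)
    verts = (verts - 1.0 + 0.5) * pitch + lo  # voxel index -> world
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # marching cubes may orient inward
        mesh.invert()
    return CellMesh(mesh=mesh, form="open", source=cell, repeat_length=L,
                    scale=s, frame=beams, nodes=nodes,
                    volume_estimate=float(occ.sum()) * pitch**3)


def export_cell(cell: CellMesh, path: str) -> None:
    """Export a cell mesh (STL/OBJ by extension) with a JSON sidecar."""
    cell.mesh.export(path)
    meta = {
        "form": cell.form,
        "repeat_length": cell.repeat_length,
        "polyhedron": cell.polyhedron.id,
    }
    if cell.form == "open":
        meta.update(PO=cell.source.PO, BT=cell.source.BT,
                    beam_section=cell.source.beam_section)
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)
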