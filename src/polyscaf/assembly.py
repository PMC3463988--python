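"""Tiling unit cells into scaffold blocks and rasterizing to voxel grids.

Cells are duplicated along the Cartesian axes (simple-cubic translations)
with axial faces in contact, the convention used for every library solid.
Space between tiled cells (gap polyhedra, as in cuboctahedron packings) is
allowed and is exactly what produces the "pore between polyhedrons".

All bulk analyses work on the periodic repeat box ``[-L/2, L/2]^3``: the
occupancy of one repeat with contributions from all neighbouring cells,
which equals the central repeat of a 3x3x3 tiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .catalog import LIBRARY_IDS, PolyhedronSpec
from .unitcell import Beam, CellMesh, OpenCellSpec, _rasterize_solids

__all__ = [
    "LatticeVectors",
    "VoxelGrid",
    "UnsupportedSolidError",
    "lattice_vectors",
    "voxelize",
    "periodic_unit_occupancy",
    "tile",
    "block_mesh",
]


class UnsupportedSolidError(ValueError):
    """Raised for solids outside the six-library tiling conventions."""


@dataclass(frozen=True)
class LatticeVectors:
    """Cartesian translation vectors of the scaffold lattice."""

    vectors: np.ndarray  # (3, 3); rows are the translations

    @property
    def repeat_length(self) -> float:
        return float(self.vectors[0, 0])


@dataclass
class VoxelGrid:
    """Axis-aligned occupancy grid (center-sampling: a voxel is occupied
    iff its center lies inside the solid)."""

    occupancy: np.ndarray  # 3D bool
    pitch: float
    origin: np.ndarray  # world position of the grid corner (not center)

    @property
    def fraction(self) -> float:
        return float(self.occupancy.mean())

    @property
    def volume(self) -> float:
        return float(self.occupancy.sum()) * self.pitch**3

    def centers_axis(self, axis: int) -> np.ndarray:
        n = self.occupancy.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.pitch


def lattice_vectors(spec: PolyhedronSpec, form: str = "open", scale: float = 1.0) -> LatticeVectors:
    """Axis-aligned translations tiling the given library solid.

    ``scale`` multiplies the unit-circumradius catalog geometry; pass the
    built cell's ``.scale`` to get translations in cell units.
    """
    if spec.id not in LIBRARY_IDS:
        raise UnsupportedSolidError(
            f"{spec.id} ({spec.name}) is not one of the six library solids"
        )
    from .unitcell import _axial_face_offset

    L = 2.0 * _axial_face_offset(spec) * scale
    return LatticeVectors(vectors=np.eye(3) * L)


def _rasterize_convex(spec: PolyhedronSpec, scale: float, origin, shape, pitch,
                      offset=np.zeros(3)) -> np.ndarray:
    """Occupancy of a convex solid by face-plane tests at voxel centers."""
    xs = origin[0] + (np.arange(shape[0]) + 0.5) * pitch
    ys = origin[1] + (np.arange(shape[1]) + 0.5) * pitch
    zs = origin[2] + (np.arange(shape[2]) + 0.5) * pitch
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]) - offset
    inside = np.ones(len(pts), dtype=bool)
    for fi in range(len(spec.faces)):
        n, d = spec.face_normal_offset(fi)
        inside &= pts @ n <= d * scale + 1e-12
    return inside.reshape(shape)


def voxelize(cell, pitch: float) -> VoxelGrid:
    """Rasterize a cell (or any trimesh) over its bounding box.

    For open cells a pitch coarser than ``BT/2`` under-resolves the beams and
    is refused; ``BT/4`` or finer is the working rule.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if isinstance(cell, CellMesh):
        if cell.form == "open":
            bt = cell.source.BT
            if pitch > bt / 2.0:
                raise ValueError(
                    f"pitch {pitch} too coarse for beam thickness {bt}: use <= BT/2"
                )
            lo = np.min([b.aabb()[0] for b in cell.solids], axis=0) - pitch
            hi = np.max([b.aabb()[1] for b in cell.solids], axis=0) + pitch
            shape = tuple(np.ceil((hi - lo) / pitch).astype(int))
            occ = _rasterize_solids(cell.solids, lo, shape, pitch)
            return VoxelGrid(occ, pitch, lo)
        spec = cell.source
        lo = cell.mesh.bounds[0] - pitch
        hi = cell.mesh.bounds[1] + pitch
        shape = tuple(np.ceil((hi - lo) / pitch).astype(int))
        occ = _rasterize_convex(spec, cell.scale, lo, shape, pitch)
        return VoxelGrid(occ, pitch, lo)
    mesh = cell
    if mesh.is_empty or len(mesh.faces) == 0:
        return VoxelGrid(np.zeros((1, 1, 1), dtype=bool), pitch, np.zeros(3))
    lo = mesh.bounds[0] - pitch
    hi = mesh.bounds[1] + pitch
    shape = tuple(np.ceil((hi - lo) / pitch).astype(int))
    xs = [lo[k] + (np.arange(shape[k]) + 0.5) * pitch for k in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    occ = mesh.contains(pts).reshape(shape)
    return VoxelGrid(occ, pitch, lo)


def periodic_unit_occupancy(cell: CellMesh, pitch: float | None = None,
                            conservative: bool = False) -> VoxelGrid:
    """Occupancy of one lattice repeat ``[-L/2, L/2]^3`` in the bulk.

    Includes material contributed by all neighbouring cells, so tiling this
    grid periodically reproduces the infinite scaffold; it equals the
    central repeat of a 3x3x3 block.  The grid dimension is snapped so an
    integer number of voxels spans the repeat.

    With ``conservative=True`` the material is inflated by half a voxel
    before sampling, so void passages narrower than the grid resolution are
    not reported as connected.  Use it for enclosure/connectivity analysis;
    leave it off for (unbiased) porosity estimates.
    """
    L = cell.repeat_length
    if pitch is None:
        pitch = (cell.source.BT / 4.0) if cell.form == "open" else L / 64.0
    n = max(2, int(round(L / pitch)))
    pitch_eff = L / n
    origin = np.full(3, -L / 2.0)
    shape = (n, n, n)
    if cell.form == "open":
        bt = cell.source.BT
        if pitch > bt / 2.0:
            raise ValueError(f"pitch {pitch} too coarse: must be <= BT/2 = {bt / 2}")
        eps = pitch_eff / 2.0 if conservative else 0.0
        solids = []
        box_lo, box_hi = origin, origin + L
        for ix in (-1, 0, 1):
            for iy in (-1, 0, 1):
                for iz in (-1, 0, 1):
                    off = np.array([ix, iy, iz], float) * L
                    for b in cell.solids:
                        lo, hi = b.aabb()
                        if np.all(lo + off <= box_hi + eps) and np.all(hi + off >= box_lo - eps):
                            s2 = b.translated(off)
                            solids.append(s2.dilated(eps) if eps else s2)
        occ = _rasterize_solids(solids, origin, shape, pitch_eff)
    else:
        # convex close cells never cross their own repeat box, so the
        # center cell alone defines the periodic occupancy
        occ = _rasterize_convex(cell.source, cell.scale, origin, shape, pitch_eff)
    return VoxelGrid(occ, pitch_eff, origin)


def tile(cell: CellMesh, counts=(3, 3, 3), pitch: float | None = None,
         with_mesh: bool = False) -> VoxelGrid | tuple[VoxelGrid, trimesh.Trimesh]:
    """Tile a unit cell into an ``nx x ny x nz`` block (voxel realization).

    Returns the block occupancy grid; with ``with_mesh=True`` also a
    watertight marching-cubes surface of the block.
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 1 for c in counts):
        raise ValueError(f"counts must all be >= 1, got {counts}")
    unit = periodic_unit_occupancy(cell, pitch)
    occ = np.tile(unit.occupancy, counts)
    grid = VoxelGrid(occ, unit.pitch, unit.origin.copy())
    if not with_mesh:
        return grid
    return grid, block_mesh(grid)


def block_mesh(grid: VoxelGrid) -> trimesh.Trimesh:
    """Watertight surface mesh of an occupancy grid (marching cubes)."""
    from skimage.measure import marching_cubes

    padded = np.pad(grid.occupancy, 1)
    verts, faces, _, _ = marching_cubes(padded.astype(np.float32), level=0.5)
    verts = (verts - 0.5) * grid.pitch + grid.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # marching cubes may orient inward
        mesh.invert()
    return mesh
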