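"""Linear-elastic voxel FE screening of unit-cell assemblies.

A light structural screen, not a replacement for production FE: trilinear
8-node hexahedral (voxel) elements on the occupancy grid, titanium elastic
constants (E = 110 GPa, nu = 0.33), compression between frictionless rigid
plates.  Absolute stresses depend on unprintable protocol details (cell
size, load magnitude), so only *relative* peak von Mises (EQV) stresses are
meaningful: the screen reproduces orderings and group memberships, never
MPa values.

Vertex- and edge-contact assemblies (the high-stress group) are regularized
with a one-voxel contact pad so the linear system is solvable; this
preserves the stress concentration the small interface produces.

Peak EQV is the 99.5th percentile of element von Mises stress, damping
voxel-corner singularities; every report records this.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import VoxelGrid
from .catalog import get_polyhedron
from .unitcell import OpenCellSpec, _rasterize_solids
from .voids import _frame_cell

__all__ = [
    "MaterialModel",
    "FEResult",
    "solve_compression",
    "rank_polyhedra",
    "couple_stress",
    "LOW_STRESS_GROUP",
    "MODERATE_STRESS_GROUP",
    "VERY_HIGH_STRESS_GROUP",
]

#: stress-level groups of the combinability screen
LOW_STRESS_GROUP = ("P-3", "P-7", "P-8", "P-11", "P-13", "P-15", "P-17")
MODERATE_STRESS_GROUP = ("P-2", "P-4", "P-10", "P-12", "P-14", "P-16", "P-18")
VERY_HIGH_STRESS_GROUP = ("P-1", "P-5", "P-6", "P-9")

PEAK_PERCENTILE = 99.5


@dataclass(frozen=True)
class MaterialModel:
    """Homogeneous isotropic linear-elastic material (titanium defaults)."""

    elastic_modulus: float = 110000.0  # MPa
    poisson_ratio: float = 0.33

    def __post_init__(self):
        if self.elastic_modulus <= 0:
            raise ValueError("elastic modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


@dataclass
class FEResult:
    displacement: np.ndarray  # (n_nodes, 3)
    von_mises: np.ndarray  # per occupied element
    peak_eqv: float  # PEAK_PERCENTILE percentile of von Mises
    peak_location: tuple[int, int, int]  # voxel index of the max element
    element_index: np.ndarray  # (n_elements, 3) voxel indices


def _elasticity_matrix(material: MaterialModel) -> np.ndarray:
    E, nu = material.elastic_modulus, material.poisson_ratio
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_CORNERS = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]])


def _shape_gradients(xi, eta, zeta, h):
    """d/dx of the 8 trilinear shape functions on a cube of edge h."""
    g = np.zeros((8, 3))
    for a, (i, j, k) in enumerate(_CORNERS):
        sx, sy, sz = 2 * i - 1, 2 * j - 1, 2 * k - 1
        g[a, 0] = sx * (1 + sy * eta) * (1 + sz * zeta) / 8.0
        g[a, 1] = (1 + sx * xi) * sy * (1 + sz * zeta) / 8.0
        g[a, 2] = (1 + sx * xi) * (1 + sy * eta) * sz / 8.0
    return g * (2.0 / h)  # Jacobian of the cube mapping


def _b_matrix(grad):
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


@lru_cache(maxsize=8)
def _element_stiffness(E: float, nu: float, h: float):
    D = _elasticity_matrix(MaterialModel(E, nu))
    KE = np.zeros((24, 24))
    for xi in _GP:
        for eta in _GP:
            for zeta in _GP:
                B = _b_matrix(_shape_gradients(xi, eta, zeta, h))
                KE += B.T @ D @ B * (h / 2.0) ** 3
    B0 = _b_matrix(_shape_gradients(0.0, 0.0, 0.0, h))
    return KE, D, B0


def _von_mises(sig: np.ndarray) -> np.ndarray:
    sx, sy, sz, txy, tyz, tzx = sig.T
    return np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                   + 3.0 * (txy**2 + tyz**2 + tzx**2))


def solve_compression(grid: VoxelGrid, material: MaterialModel | None = None,
                      strain: float | None = None,
                      load: float | None = None) -> FEResult:
    """Compress an occupancy grid between rigid frictionless plates.

    The bottom plate is fixed axially, the top plate displaced (strain
    mode) or loaded (force mode, converted to the equivalent displacement of
    a rigid plate via a unit-strain solve).  Lateral expansion is free, so a
    solid block reproduces the uniaxial patch test exactly.
    """
    material = material or MaterialModel()
    if (strain is None) == (load is None):
        raise ValueError("give exactly one of strain= or load=")
    occ = grid.occupancy
    if not occ.any():
        raise ValueError("empty grid: nothing to analyse")

    # keep only the component(s) connecting bottom to top
    from scipy import ndimage

    labels, _ = ndimage.label(occ)
    spanning = set(np.unique(labels[:, :, 0])) & set(np.unique(labels[:, :, -1]))
    spanning.discard(0)
    if not spanning:
        raise ValueError(
            "disconnected load path: no solid component spans bottom to top plate")
    occ = np.isin(labels, sorted(spanning))

    nx, ny, nz = occ.shape
    h = grid.pitch
    KE, D, B0 = _element_stiffness(material.elastic_modulus,
                                   material.poisson_ratio, h)

    eidx = np.argwhere(occ)
    nnx, nny, nnz = nx + 1, ny + 1, nz + 1

    def nid(i, j, k):
        return (i * nny + j) * nnz + k

    conn = np.stack([nid(eidx[:, 0] + ci, eidx[:, 1] + cj, eidx[:, 2] + ck)
                     for ci, cj, ck in _CORNERS], axis=1)
    edofs = (conn[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(-1, 24)

    ndof = nnx * nny * nnz * 3
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    data = np.tile(KE.ravel(), len(eidx))
    K = sp.coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()

    used_nodes = np.unique(conn)
    kk = used_nodes % nnz
    bottom = used_nodes[kk == 0]
    top = used_nodes[kk == nnz - 1]

    height = nz * h
    if strain is None:
        # unit-strain solve, then scale the plate displacement to match load
        res = solve_compression(VoxelGrid(occ, h, grid.origin), material,
                                strain=1e-4)
        area = occ[:, :, -1].sum() * h * h
        # reaction under 1e-4 strain
        f = K @ res.displacement.ravel()
        reaction = -f[top * 3 + 2].sum()
        strain = 1e-4 * load / reaction if reaction else 1e-4
    delta = -strain * height

    prescribed = {}
    for n in bottom:
        prescribed[n * 3 + 2] = 0.0
    for n in top:
        prescribed[n * 3 + 2] = delta
    # pin lateral rigid-body modes on two bottom nodes
    b0 = bottom[0]
    prescribed[b0 * 3] = 0.0
    prescribed[b0 * 3 + 1] = 0.0
    ij = np.column_stack(((bottom // nnz) // nny, (bottom // nnz) % nny))
    far = bottom[int(np.argmax(np.abs(ij[:, 0] - ij[0, 0])))]
    if far != b0:
        prescribed[far * 3 + 1] = 0.0

    pd = np.array(sorted(prescribed))
    pv = np.array([prescribed[d] for d in pd])
    active = np.unique(edofs)
    free = np.setdiff1d(active, pd, assume_unique=False)

    u = np.zeros(ndof)
    u[pd] = pv
    rhs = -K[free][:, pd] @ pv
    Kff = K[free][:, free]
    if len(free) <= 40000:
        u[free] = spla.spsolve(Kff.tocsc(), rhs)
    else:
        M = sp.diags(1.0 / Kff.diagonal())
        x, info = spla.cg(Kff, rhs, rtol=1e-8, maxiter=40000, M=M)
        if info != 0:  # pragma: no cover
            raise RuntimeError(f"CG failed to converge (info={info})")
        u[free] = x

    ue = u[edofs]
    sig = ue @ (D @ B0).T
    vm = _von_mises(sig)
    peak = float(np.percentile(vm, PEAK_PERCENTILE))
    loc = tuple(int(v) for v in eidx[int(np.argmax(vm))])
    return FEResult(displacement=u.reshape(-1, 3), von_mises=vm,
                    peak_eqv=peak, peak_location=loc, element_index=eidx)


# ---------------------------------------------------------------------------
# screening protocols


def _rasterize_convex_at(spec, scale, origin, shape, pitch, offset):
    from .assembly import _rasterize_convex

    return _rasterize_convex(spec, scale, origin, shape, pitch, offset=offset)


def _stacked_pair_grid(spec, resolution: int = 16) -> VoxelGrid:
    """Two unit-circumradius solids stacked along z (touching), voxelized.

    Columns at the minimal vertical gap get a contact pad so vertex- and
    edge-contact stacks keep their (singular but solvable) load path.
    """
    v = spec.vertices
    zmin, zmax = v[:, 2].min(), v[:, 2].max()
    height = zmax - zmin
    pitch = height / resolution
    lo = np.array([v[:, 0].min() - pitch, v[:, 1].min() - pitch, zmin])
    hi = np.array([v[:, 0].max() + pitch, v[:, 1].max() + pitch, zmax + height])
    shape = tuple(np.ceil((hi - lo) / pitch - 1e-9).astype(int))
    occ_a = _rasterize_convex_at(spec, 1.0, lo, shape, pitch, np.zeros(3))
    occ_b = _rasterize_convex_at(spec, 1.0, lo, shape, pitch,
                                 np.array([0.0, 0.0, height]))
    occ = occ_a | occ_b
    # minimal-gap contact pad
    cols = np.argwhere(occ_a.any(axis=2) & occ_b.any(axis=2))
    gaps = {}
    for i, j in cols:
        za = np.nonzero(occ_a[i, j])[0].max()
        zb = np.nonzero(occ_b[i, j])[0].min()
        gaps[(i, j)] = (za, zb, zb - za - 1)
    if gaps:
        gmin = min(g for _, _, g in gaps.values())
        if gmin > 0:
            for (i, j), (za, zb, g) in gaps.items():
                if g == gmin:
                    occ[i, j, za + 1:zb] = True
    return VoxelGrid(occ, pitch, lo)


def rank_polyhedra(ids, resolution: int = 16, strain: float = 2e-4,
                   material: MaterialModel | None = None):
    """Peak EQV stress of each solid's two-cell stacked assembly.

    One fixed protocol for every candidate: unit circumradius, identical
    strain, identical resolution.  Returns ``(ordered, peaks)`` where
    ``ordered`` lists ids from lowest to highest peak EQV and ``peaks`` maps
    id -> peak stress (or ``None`` on a per-solid failure).
    """
    peaks: dict[str, float | None] = {}
    for pid in ids:
        try:
            spec = get_polyhedron(pid)
            grid = _stacked_pair_grid(spec, resolution)
            res = solve_compression(grid, material, strain=strain)
            # combinability is judged at the junction between the two cells:
            # peak within a band of one-sixth cell height around the interface
            nz = grid.occupancy.shape[2]
            zc = res.element_index[:, 2]
            band = np.abs(zc - nz // 2) <= max(1, resolution // 6)
            vm = res.von_mises[band] if band.any() else res.von_mises
            peaks[pid] = float(np.percentile(vm, PEAK_PERCENTILE))
        except Exception:
            peaks[pid] = None
    ordered = sorted((p for p in peaks if peaks[p] is not None),
                     key=lambda p: peaks[p])
    return ordered, peaks


def couple_stress(poly_a: str, poly_b: str, ratio: float = 5.0,
                  strain: float = 2e-4, resolution: int = 40,
                  material: MaterialModel | None = None,
                  full_result: bool = False):
    """Peak junction EQV stress of a two-library couple under compression.

    Open cells of both libraries are built at the same repeat length and the
    given PO:BT ratio, stacked along z, and compressed by the given strain
    (0.02 percent by default).  The peak is taken in a band of one quarter
    repeat around the interface plane.  Only couples with a shared interface
    (Groups II/III) carry load; Group I couples raise the disconnection
    error from the solver.
    """
    cells = {}
    for pid in (poly_a, poly_b):
        cell = _frame_cell(OpenCellSpec(get_polyhedron(pid), PO=float(ratio), BT=1.0))
        cells[pid] = cell
    La, Lb = (cells[p].repeat_length for p in (poly_a, poly_b))
    # common repeat length 1: rescale each frame by 1/L
    pitch = 1.0 / resolution
    n = resolution
    shape = (n, n, 2 * n)
    origin = np.array([-0.5, -0.5, 0.0])
    occ = np.zeros(shape, dtype=bool)
    for pid, z0, L in ((poly_a, 0.5, La), (poly_b, 1.5, Lb)):
        # world = solid_coords / L + cell center (0, 0, z0): rasterize in the
        # solid's own frame by mapping the grid there
        origin_solid = (origin - np.array([0.0, 0.0, z0])) * L
        occ |= _rasterize_solids(cells[pid].solids, origin_solid, shape, pitch * L)
    grid = VoxelGrid(occ, pitch, origin)
    res = solve_compression(grid, material, strain=strain)
    zc = res.element_index[:, 2]
    band = (zc >= n - n // 4) & (zc <= n + n // 4)
    peak = (float(np.percentile(res.von_mises[band], PEAK_PERCENTILE))
            if band.any() else res.peak_eqv)
    return (peak, res) if full_result else peak
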