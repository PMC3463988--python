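"""Interface mismatch analysis for merged scaffold libraries.

When two different libraries are placed contiguously along a Cartesian axis,
load can only transfer through the overlap of their contact areas on the
shared interface plane.  The intersection index quantifies the match:

    index = area(patch_A ∩ patch_B) / max(area_A, area_B) * 100

where a patch is the solid cross-section of a cell on its outer boundary
plane.  100 means a perfect match (identical cells), 0 means no shared
contact at all.  Couples are grouped I (index 0: not possible), II
(moderately compatible) and III (index >= 50: highly compatible).

Patches are computed exactly in 2D (shapely) from the analytic beam/node
model, never from voxel grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

from .catalog import LIBRARY_IDS, get_polyhedron
from .unitcell import CellMesh, OpenCellSpec, build_close_cell
from .voids import _frame_cell

__all__ = [
    "ContactPatch",
    "CoupleReport",
    "DEFAULT_RATIO",
    "contact_patch",
    "intersection_index",
    "classify_couple",
    "couple_table",
    "library_cell",
]

_AXES = {"+x": (0, +1), "-x": (0, -1), "+y": (1, +1), "-y": (1, -1),
         "+z": (2, +1), "-z": (2, -1)}

#: PO:BT ratio used for couple analysis: the smallest printed ratio at which
#: every library is classed Group A by the manufacturability screen
DEFAULT_RATIO = 10.0

_AREA_TOL = 1e-9


@dataclass(frozen=True)
class ContactPatch:
    plane: str
    regions: MultiPolygon  # in-plane coordinates, normalized by repeat length
    total_area: float  # of the unit (L=1) interface window


@dataclass(frozen=True)
class CoupleReport:
    library_A: str
    library_B: str
    intersection_index: float
    group: str
    peak_junction_stress: float | None = None


def _section_polygon(points: np.ndarray, axis: int, plane_pos: float,
                     keep: tuple[int, int]) -> Polygon | None:
    """Cross-section of a convex point cloud with an axis-normal plane."""
    d = points[:, axis] - plane_pos
    tol = 1e-12 + 1e-9 * np.abs(points).max()
    on = np.abs(d) <= tol
    cross = []
    cross.extend(points[on][:, keep])
    pos, neg = points[d > tol], points[d < -tol]
    for p in pos:
        for q in neg:
            t = (plane_pos - p[axis]) / (q[axis] - p[axis])
            cross.append((p + t * (q - p))[list(keep)])
    if len(cross) < 3:
        return None
    pts = np.unique(np.round(np.asarray(cross, float), 12), axis=0)
    if len(pts) < 3:
        return None
    from scipy.spatial import ConvexHull

    try:
        hull = ConvexHull(pts)
    except Exception:
        return None
    poly = Polygon(pts[hull.vertices])
    return poly if poly.area > 0 else None


def contact_patch(cell: CellMesh, face_direction: str = "+x") -> ContactPatch:
    """Solid cross-section of a cell on its outer boundary plane.

    Coordinates are normalized by the repeat length, so patches of cells
    built at different absolute sizes live on a common unit interface
    window centered at the origin.
    """
    if face_direction not in _AXES:
        raise ValueError(f"face_direction must be one of {sorted(_AXES)}")
    axis, sign = _AXES[face_direction]
    keep = tuple(k for k in range(3) if k != axis)
    L = cell.repeat_length
    plane_pos = sign * L / 2.0
    # the bare contact-face polygon: the area the polyhedron itself presents
    # at the interface; beam material outside it is junction bulge, not
    # contact area ("lack of common faces" is judged on the faces)
    face = _section_polygon(cell.polyhedron.vertices * cell.scale, axis,
                            plane_pos, keep)
    polys = []
    if cell.form == "open":
        for solid in cell.solids:
            lo, hi = solid.aabb()
            if lo[axis] > plane_pos + 1e-12 or hi[axis] < plane_pos - 1e-12:
                continue
            pts = solid.corners() if hasattr(solid, "corners") else solid.points
            poly = _section_polygon(np.asarray(pts), axis, plane_pos, keep)
            if poly is not None:
                polys.append(poly)
    elif face is not None:
        polys.append(face)
    window = box(-0.5, -0.5, 0.5, 0.5)
    merged = unary_union([
        Polygon(np.asarray(p.exterior.coords) / L) for p in polys
    ]).intersection(window)
    if cell.form == "open" and face is not None:
        merged = merged.intersection(
            Polygon(np.asarray(face.exterior.coords) / L))
    if merged.is_empty:
        regions = MultiPolygon([])
    elif isinstance(merged, Polygon):
        regions = MultiPolygon([merged])
    else:
        regions = MultiPolygon([g for g in merged.geoms if isinstance(g, Polygon)])
    return ContactPatch(plane=face_direction, regions=regions,
                        total_area=float(regions.area))


def intersection_index(cell_A: CellMesh, cell_B: CellMesh,
                       face_direction: str = "+x") -> float:
    """Eq-style intersection index (percent) for two contiguous cells.

    The denominator (possible maximum interface area) is the larger of the
    two patch areas, which anchors identical cells at 100 and disjoint
    patches at 0.
    """
    pa = contact_patch(cell_A, face_direction)
    pb = contact_patch(cell_B, face_direction)
    denom = max(pa.total_area, pb.total_area)
    if denom <= _AREA_TOL:
        return 0.0
    inter = pa.regions.intersection(pb.regions).area
    if inter <= _AREA_TOL:
        return 0.0
    return float(100.0 * inter / denom)


def classify_couple(index: float) -> str:
    """Group I (impossible), II (moderate) or III (highly compatible)."""
    if not 0.0 <= index <= 100.0:
        raise ValueError("intersection index must be in [0, 100]")
    if index == 0.0:
        return "I"
    return "III" if index >= 50.0 else "II"


@lru_cache(maxsize=None)
def library_cell(poly_id: str, ratio: float = DEFAULT_RATIO,
                 form: str = "open") -> CellMesh:
    """Analytic unit cell of a library at a PO:BT ratio (open) or scale 1."""
    spec = get_polyhedron(poly_id)
    if form == "close":
        return build_close_cell(spec, 1.0)
    return _frame_cell(OpenCellSpec(spec, PO=float(ratio), BT=1.0))


def couple_table(ratio: float = DEFAULT_RATIO, form: str = "open") -> pd.DataFrame:
    """Intersection index and group for all 15 library couples (C-1...C-15).

    Couples follow the printed order: all pairs of the six libraries sorted
    by (first, second) in catalog order.
    """
    order = ["P-3", "P-11", "P-7", "P-8", "P-13", "P-15"]
    # printed couple order: P-3 with P-11,P-8,P-7,P-13,P-15; then P-11...
    printed = [
        ("P-3", "P-11"), ("P-3", "P-8"), ("P-3", "P-7"), ("P-3", "P-13"),
        ("P-3", "P-15"), ("P-11", "P-8"), ("P-11", "P-7"), ("P-11", "P-13"),
        ("P-11", "P-15"), ("P-8", "P-7"), ("P-8", "P-13"), ("P-8", "P-15"),
        ("P-7", "P-13"), ("P-7", "P-15"), ("P-13", "P-15"),
    ]
    rows = []
    for k, (a, b) in enumerate(printed, start=1):
        idx = intersection_index(library_cell(a, ratio, form),
                                 library_cell(b, ratio, form))
        rows.append({
            "couple": f"C-{k}", "library_A": a, "library_B": b,
            "intersection_index": round(idx, 1), "group": classify_couple(idx),
        })
    return pd.DataFrame(rows).set_index("couple")
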