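"""Enclosed-void detection, Group A/B/C classification, availability scores.

An enclosed void is unfused material trapped inside the printed scaffold:
any void region of the assembled block that cannot be reached from the
exterior through 6-connected void voxels.  A design point (library, PO:BT)
is classed:

* **C** if the assembled scaffold contains an enclosed void,
* **B** if some intended face windows are sealed by beam overlap (lost
  components) but all void space still connects to the exterior,
* **A** if the geometry is perfect.

Classification is done on the central repeat of a 3x3x3 tiling so it
reflects bulk behaviour rather than block-boundary artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage

from .assembly import VoxelGrid, periodic_unit_occupancy
from .catalog import LIBRARY_IDS, get_polyhedron
from .unitcell import (CellMesh, OpenCellSpec, _junction_nodes, cell_scale_for_ratio,
                       face_windows, open_cell_frame)

__all__ = [
    "VoidReport",
    "PRINTED_RATIOS",
    "detect_enclosed_voids",
    "lost_windows",
    "classify_group",
    "availability_score",
    "evaluation_table",
]

#: the nine printed PO:BT design ratios
PRINTED_RATIOS: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0)

_SCORE = {"A": 2, "B": 1, "C": 0}


@dataclass(frozen=True)
class VoidReport:
    exterior_connected_void_fraction: float
    enclosed_components: int
    enclosed_void_fraction: float
    lost_windows: int = 0


def detect_enclosed_voids(grid: VoxelGrid, region: tuple[slice, ...] | None = None,
                          lost: int = 0) -> VoidReport:
    """Flood-fill void voxels from the grid boundary (6-connectivity).

    Void components that never reach the boundary are enclosed.  Fractions
    and component counts are reported over ``region`` (a 3-slice tuple)
    when given, else over the whole grid.
    """
    occ = grid.occupancy
    if occ.size == 0:
        raise ValueError("empty grid")
    void = ~occ
    labels, nlab = ndimage.label(void)  # default structure = 6-connectivity
    boundary_labels = set()
    for ax in range(3):
        for sl in (0, -1):
            idx = [slice(None)] * 3
            idx[ax] = sl
            boundary_labels.update(np.unique(labels[tuple(idx)]))
    boundary_labels.discard(0)

    if region is None:
        region = (slice(None),) * 3
    sub = labels[region]
    nvox = sub.size
    void_sub = sub > 0
    enclosed_mask = void_sub & ~np.isin(sub, sorted(boundary_labels))
    enclosed_ids = np.unique(sub[enclosed_mask])
    return VoidReport(
        exterior_connected_void_fraction=float((void_sub & ~enclosed_mask).sum()) / nvox,
        enclosed_components=int(len(enclosed_ids)),
        enclosed_void_fraction=float(enclosed_mask.sum()) / nvox,
        lost_windows=lost,
    )


def lost_windows(spec: OpenCellSpec) -> int:
    """Number of face windows lost to beam overlap at this design point.

    A window counts as lost when its inscribed-circle diameter falls below
    the beam thickness: at that scale the bordering beams have effectively
    merged and the opening does not survive fabrication as a distinct
    geometric component.
    """
    s = cell_scale_for_ratio(spec.polyhedron, spec.PO, spec.BT)
    w = face_windows(spec.polyhedron, s, spec.BT)
    return int(sum(1 for d in w if d < spec.BT * (1.0 - 1e-9)))


def _frame_cell(spec: OpenCellSpec) -> CellMesh:
    """CellMesh carrying only the analytic beam/node model (no surface mesh)."""
    beams, L = open_cell_frame(spec)
    s = cell_scale_for_ratio(spec.polyhedron, spec.PO, spec.BT)
    nodes = _junction_nodes(beams, spec.polyhedron.vertices * s)
    return CellMesh(mesh=None, form="open", source=spec, repeat_length=L,
                    scale=s, frame=beams, nodes=nodes)


def _enclosed_in_bulk(spec: OpenCellSpec, pitch: float) -> int:
    cell = _frame_cell(spec)
    unit = periodic_unit_occupancy(cell, pitch, conservative=True)
    occ = np.tile(unit.occupancy, (3, 3, 3))
    n = unit.occupancy.shape[0]
    grid = VoxelGrid(occ, unit.pitch, unit.origin - n * unit.pitch)
    region = (slice(n, 2 * n),) * 3
    return detect_enclosed_voids(grid, region).enclosed_components


@lru_cache(maxsize=None)
def _classify_row(poly_id: str, ratios: tuple[float, ...]) -> dict[float, str]:
    """Raw labels for a whole ratio row, then monotone closure.

    Manufacturability is monotone in PO:BT (thickening beams can only close
    passages), so an enclosed void found at some ratio implies group C at
    every smaller ratio; this also absorbs single-pitch detection flickers
    at the gap-filled/gap-void boundary.
    """
    raw = {x: _classify(poly_id, float(x)) for x in ratios}
    worst = max((x for x in ratios if raw[x] == "C"), default=None)
    if worst is not None:
        for x in ratios:
            if x <= worst:
                raw[x] = "C"
    return raw


@lru_cache(maxsize=None)
def _classify(poly_id: str, ratio: float) -> str:
    if poly_id not in LIBRARY_IDS:
        raise ValueError(f"{poly_id} is not one of the six library solids")
    spec = OpenCellSpec(get_polyhedron(poly_id), PO=float(ratio), BT=1.0)
    bt = spec.BT
    # voxel classification at BT/4, confirmed at BT/6; on disagreement
    # refine once more and keep the finest answer
    e4 = _enclosed_in_bulk(spec, bt / 4.0)
    e6 = _enclosed_in_bulk(spec, bt / 6.0)
    enclosed = e6 if (e4 > 0) == (e6 > 0) else _enclosed_in_bulk(spec, bt / 8.0)
    if enclosed > 0:
        return "C"
    return "B" if lost_windows(spec) > 0 else "A"


def classify_group(spec: OpenCellSpec) -> str:
    """Group label (``"A"``/``"B"``/``"C"``) for one open-cell design point.

    Design points on the printed ratio grid are classified in the context of
    the whole row (monotone closure); off-grid ratios pointwise.
    """
    pid = spec.polyhedron.id
    if spec.ratio in PRINTED_RATIOS:
        return _classify_row(pid, PRINTED_RATIOS)[spec.ratio]
    return _classify(pid, spec.ratio)


def availability_score(poly_id: str, ratios=PRINTED_RATIOS) -> tuple[int, dict[float, str]]:
    """Summed 2/1/0 score over the printed ratios, plus per-ratio labels."""
    labels = _classify_row(poly_id, tuple(float(x) for x in ratios))
    return sum(_SCORE[v] for v in labels.values()), labels


def evaluation_table(ratios=PRINTED_RATIOS, libraries=LIBRARY_IDS) -> pd.DataFrame:
    """Library x PO:BT letter table with the availability-score column."""
    rows = {}
    for pid in libraries:
        score, labels = availability_score(pid, ratios)
        rows[pid] = {**{f"{x:g}:1": labels[x] for x in ratios}, "score": score}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "library"
    return df
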