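"""Porosity curves and Logistic Power regression.

Porosity is ``phi = 1 - V_material / V_apparent`` evaluated over the bulk
lattice repeat (the central repeat of a 3x3x3 tiling).  The porosity of an
open-cellular library as a function of the design ratio ``x = PO:BT`` is
summarized by the Logistic Power model

    y(x) = a / (1 + (x / b)**c)

fitted by unconstrained nonlinear least squares; the quality measure ``r``
is the Pearson correlation between observed and fitted porosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .assembly import VoxelGrid, periodic_unit_occupancy
from .catalog import LIBRARY_IDS, PolyhedronSpec, get_polyhedron
from .unitcell import OpenCellSpec, build_close_cell
from .voids import PRINTED_RATIOS, availability_score, _frame_cell

__all__ = [
    "PorosityResult",
    "PorosityCurve",
    "LogisticPowerFit",
    "compute_porosity",
    "hexahedron_porosity_closed_form",
    "library_porosity",
    "porosity_curve",
    "fit_logistic_power",
    "logistic_power",
    "close_cell_porosity",
]


@dataclass(frozen=True)
class PorosityResult:
    phi: float
    material_volume: float
    apparent_volume: float


@dataclass(frozen=True)
class PorosityCurve:
    library: str
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValueError("ratios must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in self.y):
            raise ValueError("porosity values must lie in [0, 1]")


@dataclass(frozen=True)
class LogisticPowerFit:
    a: float
    b: float
    c: float
    r: float

    def __call__(self, x):
        return logistic_power(np.asarray(x, float), self.a, self.b, self.c)


def logistic_power(x, a, b, c):
    """The Logistic Power model y = a / (1 + (x/b)^c)."""
    return a / (1.0 + (x / b) ** c)


def compute_porosity(grid: VoxelGrid, region: tuple[slice, ...] | None = None) -> PorosityResult:
    """Porosity of (a region of) an occupancy grid."""
    occ = grid.occupancy if region is None else grid.occupancy[region]
    if occ.size == 0:
        raise ValueError("empty apparent region")
    apparent = occ.size * grid.pitch**3
    material = float(occ.sum()) * grid.pitch**3
    return PorosityResult(phi=1.0 - material / apparent,
                          material_volume=material, apparent_volume=apparent)


def hexahedron_porosity_closed_form(x: float) -> float:
    """Analytic bulk porosity of the open-cellular hexahedron library.

    The tiled frame has repeat length ``PO + BT`` and axis-aligned square
    beams, so the solid fraction is ``(3x+1)/(x+1)^3`` exactly.
    """
    if x <= 0:
        raise ValueError("PO:BT ratio must be positive")
    return 1.0 - (3.0 * x + 1.0) / (x + 1.0) ** 3


@lru_cache(maxsize=None)
def _library_porosity_cached(poly_id: str, ratio: float, pitch_frac: float) -> float:
    spec = OpenCellSpec(get_polyhedron(poly_id), PO=ratio, BT=1.0)
    cell = _frame_cell(spec)
    grid = periodic_unit_occupancy(cell, spec.BT * pitch_frac)
    return compute_porosity(grid).phi


def library_porosity(poly_id: str, ratio: float, pitch_frac: float = 0.25) -> float:
    """Bulk porosity of one open-cellular library at one PO:BT ratio."""
    return _library_porosity_cached(poly_id, float(ratio), float(pitch_frac))


def porosity_curve(poly_id: str, ratios=None, pitch_frac: float = 0.25,
                   skip_enclosed: bool = True) -> PorosityCurve:
    """Porosity vs PO:BT for one library over the printed ratios.

    Ratios classified as containing an enclosed void (group C) are excluded
    by default: those designs are unmanufacturable, and the printed curves
    cover groups A and B only.
    """
    if poly_id not in LIBRARY_IDS:
        raise ValueError(f"{poly_id} is not one of the six library solids")
    if ratios is None:
        ratios = PRINTED_RATIOS
        if skip_enclosed:
            _, labels = availability_score(poly_id)
            kept = tuple(x for x in PRINTED_RATIOS if labels[x] != "C")
            # porosity is a purely geometric quantity; if too few design
            # points survive the manufacturability screen, curve the full grid
            if len(kept) >= 4:
                ratios = kept
    xs = tuple(float(x) for x in ratios)
    ys = tuple(library_porosity(poly_id, x, pitch_frac) for x in xs)
    return PorosityCurve(library=poly_id, x=xs, y=ys)


def fit_logistic_power(curve: PorosityCurve, seed: int = 0) -> LogisticPowerFit:
    """Least-squares Logistic Power fit of a porosity curve.

    Starts from ``a=1, b=median(x), c=-1.5`` with up to 5 seeded random
    restarts on failure; ``a`` is bounded in (0, 2].
    """
    x = np.asarray(curve.x, float)
    y = np.asarray(curve.y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit the 3-parameter model")
    p0 = (1.0, float(np.median(x)), -1.5)
    bounds = ([1e-9, 1e-9, -np.inf], [2.0, np.inf, np.inf])
    rng = np.random.default_rng(seed)
    last_err = None
    for attempt in range(6):
        try:
            start = p0 if attempt == 0 else (
                rng.uniform(0.5, 1.5),
                float(rng.uniform(0.5, 2.0) * np.median(x)),
                float(rng.uniform(-3.0, -0.5)),
            )
            popt, _ = curve_fit(logistic_power, x, y, p0=start, bounds=bounds,
                                maxfev=20000)
            yf = logistic_power(x, *popt)
            r = float(pearsonr(y, yf)[0])
            return LogisticPowerFit(a=float(popt[0]), b=float(popt[1]),
                                    c=float(popt[2]), r=r)
        except RuntimeError as err:  # pragma: no cover - needs a pathological curve
            last_err = err
    raise RuntimeError(f"Logistic Power fit failed after restarts: {last_err}")


def close_cell_porosity(spec: PolyhedronSpec, scale: float = 1.0,
                        pitch_frac: float = 1.0 / 64.0) -> PorosityResult:
    """Bulk porosity of a tiled close-cellular library.

    Scale-free by construction: the voxel pitch follows the repeat length,
    so any two scales give identical occupancy fractions.
    """
    if spec.id not in LIBRARY_IDS:
        raise ValueError(f"{spec.id} is not one of the six library solids")
    cell = build_close_cell(spec, scale)
    grid = periodic_unit_occupancy(cell, scale * pitch_frac)
    return compute_porosity(grid)
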