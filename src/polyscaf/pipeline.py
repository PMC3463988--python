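"""End-to-end evaluation pipeline and report bundle.

Runs the whole geometric evaluation for a configured set of libraries and
design ratios and writes a small report bundle:

* ``evaluation.csv``   — group letters per (library, PO:BT) + availability score
* ``porosity_fits.csv``— porosity curves and Logistic Power constants
* ``couples.csv``      — intersection index and group per library couple
* ``fe_ranking.json``  — peak EQV stress screen (optional, slowest stage)
* ``pipeline.json``    — config, conventions, per-stage status

Outputs are deterministic for a fixed config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import LIBRARY_IDS
from .voids import PRINTED_RATIOS, evaluation_table
from .porosity import porosity_curve, fit_logistic_power
from .mismatch import DEFAULT_RATIO, couple_table
from .fescreen import rank_polyhedra, LOW_STRESS_GROUP, VERY_HIGH_STRESS_GROUP

__all__ = ["PipelineConfig", "run_pipeline", "CONVENTIONS"]

log = logging.getLogger("polyscaf")

#: geometric conventions stamped into every report
CONVENTIONS = {
    "pore_size": "inscribed-circle diameter of the largest face window after thickening",
    "beam_section": "square (parallelogram flush to adjacent face planes), junction nodes filled",
    "lattice": "simple-cubic axis-aligned translations, axial-face contact",
    "void_connectivity": "6-connected flood fill, conservative half-voxel dilation",
    "lost_window": "inscribed diameter below beam thickness",
    "peak_stress": "99.5th percentile of element von Mises",
}


@dataclass
class PipelineConfig:
    libraries: tuple[str, ...] = LIBRARY_IDS
    ratios: tuple[float, ...] = PRINTED_RATIOS
    pitch_fraction: float = 0.25  # of beam thickness
    beam_section: str = "square"
    couple_ratio: float = DEFAULT_RATIO
    include_fe: bool = True
    fe_resolution: int = 16
    seed: int = 0
    output_dir: str = "polyscaf-report"

    def validate(self) -> None:
        unknown = [p for p in self.libraries if p not in LIBRARY_IDS]
        if unknown:
            raise ValueError(f"unknown or unsupported libraries: {unknown}")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive")
        if not 0 < self.pitch_fraction <= 0.25:
            raise ValueError("pitch_fraction must be in (0, 1/4]")
        if self.beam_section not in ("square", "circular"):
            raise ValueError(f"unknown beam section {self.beam_section!r}")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for key, val in CONVENTIONS.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh)


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run every stage and write the report bundle; returns per-stage status."""
    config = config or PipelineConfig()
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}

    log.info("polyscaf %s pipeline -> %s", __version__, out)

    try:
        df = evaluation_table(tuple(config.ratios), tuple(config.libraries))
        _write_csv(df, out / "evaluation.csv")
        status["evaluation"] = "ok"
    except Exception as err:  # pragma: no cover
        log.exception("evaluation stage failed")
        status["evaluation"] = f"failed: {err}"

    try:
        rows = []
        for pid in config.libraries:
            curve = porosity_curve(pid, pitch_frac=config.pitch_fraction)
            fit = fit_logistic_power(curve, seed=config.seed)
            for x, y in zip(curve.x, curve.y):
                rows.append({"library": pid, "x": x, "porosity": y,
                             "a": fit.a, "b": fit.b, "c": fit.c, "r": fit.r})
        _write_csv(pd.DataFrame(rows).set_index("library"),
                   out / "porosity_fits.csv")
        status["porosity"] = "ok"
    except Exception as err:  # pragma: no cover
        log.exception("porosity stage failed")
        status["porosity"] = f"failed: {err}"

    try:
        _write_csv(couple_table(ratio=config.couple_ratio), out / "couples.csv")
        status["mismatch"] = "ok"
    except Exception as err:  # pragma: no cover
        log.exception("mismatch stage failed")
        status["mismatch"] = f"failed: {err}"

    if config.include_fe:
        try:
            ids = tuple(dict.fromkeys(LOW_STRESS_GROUP + VERY_HIGH_STRESS_GROUP))
            ordered, peaks = rank_polyhedra(ids, resolution=config.fe_resolution)
            with open(out / "fe_ranking.json", "w") as fh:
                json.dump({"ordered_low_to_high": ordered,
                           "peak_eqv": peaks,
                           "note": "relative stresses only; protocol units"},
                          fh, indent=1)
            status["fescreen"] = "ok"
        except Exception as err:  # pragma: no cover
            log.exception("fescreen stage failed")
            status["fescreen"] = f"failed: {err}"
    else:
        status["fescreen"] = "skipped"

    with open(out / "pipeline.json", "w") as fh:
        json.dump({"version": __version__, "config": asdict(config),
                   "conventions": CONVENTIONS, "status": status}, fh, indent=1)
    return status
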