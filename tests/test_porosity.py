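import numpy as np
import pytest

from polyscaf.assembly import VoxelGrid, periodic_unit_occupancy
from polyscaf.catalog import get_polyhedron
from polyscaf.porosity import (
    PorosityCurve,
    close_cell_porosity,
    compute_porosity,
    fit_logistic_power,
    hexahedron_porosity_closed_form,
    library_porosity,
    logistic_power,
)
from polyscaf.unitcell import OpenCellSpec, build_open_cell


def test_closed_form_values_and_limits():
    assert hexahedron_porosity_closed_form(1.0) == pytest.approx(0.5)
    assert hexahedron_porosity_closed_form(3.0) == pytest.approx(1 - 10 / 64)
    assert hexahedron_porosity_closed_form(1e9) == pytest.approx(1.0, abs=1e-8)
    assert hexahedron_porosity_closed_form(1e-9) == pytest.approx(0.0, abs=1e-8)
    with pytest.raises(ValueError):
        hexahedron_porosity_closed_form(0.0)


def test_compute_porosity_extremes():
    solid = VoxelGrid(np.ones((4, 4, 4), dtype=bool), 1.0, np.zeros(3))
    empty = VoxelGrid(np.zeros((4, 4, 4), dtype=bool), 1.0, np.zeros(3))
    assert compute_porosity(solid).phi == 0.0
    assert compute_porosity(empty).phi == 1.0
    with pytest.raises(ValueError):
        compute_porosity(solid, (slice(0, 0), slice(None), slice(None)))


@pytest.mark.parametrize("x", [1.0, 3.0, 5.0, 12.0])
def test_voxel_porosity_matches_closed_form(x):
    phi = library_porosity("P-3", x, pitch_frac=0.25)
    assert abs(phi - hexahedron_porosity_closed_form(x)) <= 2 * 0.25


def test_voxel_porosity_tight_for_hexahedron():
    # beams are voxel-aligned for the cubic frame, so BT/4 is already exact
    for x in (1.0, 3.0):
        phi = library_porosity("P-3", x)
        assert phi == pytest.approx(hexahedron_porosity_closed_form(x), abs=1e-12)


def test_exact_model_recovery():
    x = np.array([1, 2, 3, 4, 5, 6, 8, 10, 12], float)
    y = logistic_power(x, 0.97, 3.13, -2.15)
    fit = fit_logistic_power(PorosityCurve("synthetic", tuple(x), tuple(y)))
    assert fit.a == pytest.approx(0.97, abs=1e-6)
    assert fit.b == pytest.approx(3.13, abs=1e-6)
    assert fit.c == pytest.approx(-2.15, abs=1e-6)
    assert fit.r == pytest.approx(1.0, abs=1e-9)


def test_fit_needs_four_points():
    with pytest.raises(ValueError):
        fit_logistic_power(PorosityCurve("tiny", (1.0, 2.0, 3.0), (0.5, 0.7, 0.8)))


def test_curve_invariants_enforced():
    with pytest.raises(ValueError):
        PorosityCurve("bad", (2.0, 1.0), (0.5, 0.6))
    with pytest.raises(ValueError):
        PorosityCurve("bad", (1.0, 2.0), (0.5, 1.3))


def test_porosity_monotone_in_ratio(porosity_fits):
    for pid, (curve, _) in porosity_fits.items():
        assert all(b > a for a, b in zip(curve.y, curve.y[1:])), pid


def test_fits_describe_curves_well(porosity_fits):
    for pid, (_, fit) in porosity_fits.items():
        assert fit.r > 0.99, pid
        assert 0 < fit.a <= 2.0 and fit.b > 0 and fit.c < 0


def test_close_cell_porosity_scale_invariant():
    p7 = get_polyhedron("P-7")
    phi1 = close_cell_porosity(p7, 1.0).phi
    phi2 = close_cell_porosity(p7, 2.0).phi
    assert abs(phi1 - phi2) < 1e-3
    assert phi1 == pytest.approx(0.5, abs=0.01)


def test_close_cell_porosity_ordering():
    # truncated octahedron most porous, rhombitruncated cuboctahedron least
    phis = {pid: close_cell_porosity(get_polyhedron(pid)).phi
            for pid in ("P-7", "P-13", "P-15")}
    assert phis["P-7"] > phis["P-13"] > phis["P-15"]


def test_close_hexahedron_is_dense():
    assert close_cell_porosity(get_polyhedron("P-3")).phi == 0.0


def test_close_cell_rejects_unknown_library():
    with pytest.raises(ValueError):
        close_cell_porosity(get_polyhedron("P-1"))
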