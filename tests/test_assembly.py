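import numpy as np
import pytest

from polyscaf.assembly import (
    UnsupportedSolidError,
    block_mesh,
    lattice_vectors,
    periodic_unit_occupancy,
    tile,
    voxelize,
)
from polyscaf.catalog import get_polyhedron
from polyscaf.porosity import hexahedron_porosity_closed_form
from polyscaf.unitcell import OpenCellSpec, build_close_cell, build_open_cell


def test_hexahedron_lattice_vectors():
    lv = lattice_vectors(get_polyhedron("P-3"), scale=2.0)
    # cube contact faces sit at +-circumradius/sqrt(3)
    expected = 2.0 * 2.0 / np.sqrt(3.0)
    assert np.allclose(lv.vectors, np.eye(3) * expected)


def test_unsupported_solid():
    with pytest.raises(UnsupportedSolidError):
        lattice_vectors(get_polyhedron("P-1"))


def test_voxelize_unit_cube():
    cell = build_close_cell(get_polyhedron("P-3"), 1.0)
    grid = voxelize(cell, pitch=0.25)
    assert int(grid.occupancy.sum()) == 64


def test_voxelize_coarse_pitch_refused():
    cell = build_open_cell(OpenCellSpec(get_polyhedron("P-3"), PO=2.0, BT=1.0))
    with pytest.raises(ValueError):
        voxelize(cell, pitch=0.8)


def test_voxelize_generic_empty_mesh():
    import trimesh

    grid = voxelize(trimesh.Trimesh(), pitch=0.5)
    assert grid.occupancy.sum() == 0


def test_periodic_occupancy_matches_closed_form():
    # open hexahedron at x = 1: tiled solid fraction is exactly 1/2
    cell = build_open_cell(OpenCellSpec(get_polyhedron("P-3"), PO=1.0, BT=1.0))
    grid = periodic_unit_occupancy(cell)
    assert np.isclose(1.0 - grid.fraction, hexahedron_porosity_closed_form(1.0),
                      atol=1e-12)


def test_space_filling_close_cell_fraction():
    # the close truncated octahedron fills exactly half its repeat cube;
    # the close hexahedron fills all of it
    g7 = periodic_unit_occupancy(build_close_cell(get_polyhedron("P-7"), 1.0))
    assert np.isclose(g7.fraction, 0.5, atol=1e-12)
    g3 = periodic_unit_occupancy(build_close_cell(get_polyhedron("P-3"), 1.0))
    assert g3.fraction == 1.0


def test_voxel_volume_converges_with_pitch():
    # analytic cuboctahedron volume vs voxel estimate: halving the pitch
    # reduces the error
    spec = get_polyhedron("P-11")
    cell = build_close_cell(spec, 1.0)
    exact = cell.mesh.volume
    errs = []
    for n in (16, 32):
        grid = periodic_unit_occupancy(cell, pitch=1.0 / n)
        errs.append(abs(grid.volume - exact))
    assert errs[1] < errs[0]


def test_tile_counts_and_volume():
    cell = build_open_cell(OpenCellSpec(get_polyhedron("P-3"), PO=2.0, BT=1.0))
    unit = periodic_unit_occupancy(cell)
    grid = tile(cell, (2, 3, 1))
    assert grid.occupancy.shape == tuple(
        n * c for n, c in zip(unit.occupancy.shape, (2, 3, 1)))
    # shared beams mean the block volume never exceeds count x cell volume
    assert grid.volume <= 6 * cell.volume + 1e-9
    with pytest.raises(ValueError):
        tile(cell, (0, 1, 1))


def test_block_mesh_watertight():
    cell = build_open_cell(OpenCellSpec(get_polyhedron("P-3"), PO=2.0, BT=1.0))
    grid, mesh = tile(cell, (2, 2, 2), with_mesh=True)
    assert mesh.is_watertight
    assert np.isclose(mesh.volume, grid.volume, rtol=0.35)
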