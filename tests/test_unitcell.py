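import numpy as np
import pytest

from polyscaf.catalog import get_polyhedron
from polyscaf.unitcell import (
    OpenCellSpec,
    build_close_cell,
    build_open_cell,
    cell_scale_for_ratio,
    face_windows,
    open_cell_frame,
)


def test_close_cell_cube_volume():
    cell = build_close_cell(get_polyhedron("P-3"), 1.0)
    assert np.isclose(cell.mesh.volume, 1.0, rtol=1e-9)
    assert np.isclose(cell.repeat_length, 1.0)


def test_close_cell_truncated_octahedron_volume():
    # the truncated octahedron fills half of its axis-aligned repeat cube
    # (exact: V = 8 sqrt(2) a^3 with a = sqrt(2) L / 4 gives L^3 / 2)
    cell = build_close_cell(get_polyhedron("P-7"), 1.0)
    assert np.isclose(cell.mesh.volume, 0.5, rtol=1e-9)


@pytest.mark.parametrize("scale", [0.0, -1.0])
def test_close_cell_bad_scale(scale):
    with pytest.raises(ValueError):
        build_close_cell(get_polyhedron("P-3"), scale)


def test_close_cell_rejects_nonconvex():
    with pytest.raises(ValueError):
        build_close_cell(get_polyhedron("F-1"), 1.0)


def test_open_cell_spec_validation():
    hexa = get_polyhedron("P-3")
    with pytest.raises(ValueError):
        OpenCellSpec(hexa, PO=0.0, BT=1.0)
    with pytest.raises(ValueError):
        OpenCellSpec(hexa, PO=1.0, BT=-1.0)
    with pytest.raises(ValueError):
        OpenCellSpec(hexa, PO=1.0, BT=1.0, beam_section="hexagonal")


def test_hexahedron_frame_geometry():
    # cube frame: repeat length is PO + BT and every window measures PO
    spec = OpenCellSpec(get_polyhedron("P-3"), PO=3.0, BT=1.0)
    beams, L = open_cell_frame(spec)
    assert len(beams) == 12
    assert np.isclose(L, 4.0, atol=1e-9)
    s = cell_scale_for_ratio(spec.polyhedron, spec.PO, spec.BT)
    windows = face_windows(spec.polyhedron, s, spec.BT)
    assert np.allclose(windows, 3.0, atol=1e-9)


def test_open_cell_mesh_watertight_and_volume():
    spec = OpenCellSpec(get_polyhedron("P-3"), PO=1.0, BT=1.0)
    cell = build_open_cell(spec)
    assert cell.mesh.is_watertight
    # frame of 12 unit beams + 8 corner nodes on a cube of edge 2: exactly 20
    assert np.isclose(cell.volume, 20.0, rtol=1e-12)
    # divergence-theorem volume of the marching-cubes surface agrees with the
    # voxel count to within discretization error O(pitch)
    assert abs(cell.mesh.volume - cell.volume) / cell.volume < 0.3


def test_open_cell_volume_increases_with_beam_thickness():
    hexa = get_polyhedron("P-7")
    volumes = []
    for bt in (0.5, 1.0, 2.0):
        cell = build_open_cell(OpenCellSpec(hexa, PO=4.0, BT=bt), pitch=bt / 4)
        volumes.append(cell.volume)
    assert volumes[0] < volumes[1] < volumes[2]


def test_open_cell_volume_below_close_cell():
    hexa = get_polyhedron("P-7")
    open_cell = build_open_cell(OpenCellSpec(hexa, PO=5.0, BT=1.0))
    close_cell = build_close_cell(hexa, open_cell.repeat_length)
    assert open_cell.volume < close_cell.mesh.volume


def test_window_shrinks_with_thicker_beams():
    p7 = get_polyhedron("P-7")
    s = cell_scale_for_ratio(p7, 5.0, 1.0)
    thin = min(face_windows(p7, s, 0.5))
    thick = min(face_windows(p7, s, 1.5))
    assert thick < thin


def test_pitch_refusal():
    spec = OpenCellSpec(get_polyhedron("P-3"), PO=2.0, BT=1.0)
    with pytest.raises(ValueError):
        build_open_cell(spec, pitch=0.75)  # coarser than BT/2
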