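import numpy as np
import pytest

from polyscaf.catalog import (
    CATALOG_IDS,
    FIXTURE_IDS,
    get_polyhedron,
    import_stl,
    export_mesh,
    screen_criteria_A,
    to_mesh,
    validate_polyhedron,
)

# V, E, F of every catalog solid (standard combinatorics of the Platonic and
# Archimedean solids)
COUNTS = {
    "P-1": (4, 6, 4), "P-2": (6, 12, 8), "P-3": (8, 12, 6),
    "P-4": (12, 30, 20), "P-5": (20, 30, 12), "P-6": (12, 18, 8),
    "P-7": (24, 36, 14), "P-8": (24, 36, 14), "P-9": (60, 90, 32),
    "P-10": (60, 90, 32), "P-11": (12, 24, 14), "P-12": (30, 60, 32),
    "P-13": (24, 48, 26), "P-14": (60, 120, 62), "P-15": (48, 72, 26),
    "P-16": (120, 180, 62), "P-17": (24, 60, 38), "P-18": (60, 150, 92),
}


@pytest.mark.parametrize("pid", CATALOG_IDS)
def test_catalog_combinatorics_and_validity(pid):
    spec = get_polyhedron(pid)
    assert (len(spec.vertices), len(spec.edges), len(spec.faces)) == COUNTS[pid]
    rep = validate_polyhedron(spec)
    assert rep.ok, rep.problems
    assert rep.euler_characteristic == 2
    assert rep.watertight and rep.convex and rep.faces_planar
    # unit circumradius, centered
    assert np.isclose(np.max(np.linalg.norm(spec.vertices, axis=1)), 1.0)


def test_truncated_octahedron_face_mix():
    spec = get_polyhedron("P-7")
    sizes = sorted(len(c) for c in spec.faces)
    assert sizes == [4] * 6 + [6] * 8


def test_unknown_id_raises():
    with pytest.raises(KeyError):
        get_polyhedron("P-99")


def test_repeated_calls_identical():
    a, b = get_polyhedron("P-7"), get_polyhedron("P-7")
    assert np.array_equal(a.vertices, b.vertices) and a.faces == b.faces


@pytest.mark.parametrize("fid", FIXTURE_IDS)
def test_nonconvex_fixtures_fail_screen(fid):
    spec = get_polyhedron(fid)
    rep = validate_polyhedron(spec)
    # watertight, valid meshes that are genuinely nonconvex
    assert rep.watertight and rep.euler_characteristic == 2
    assert not rep.convex
    assert not screen_criteria_A(spec).passes_criteria_A


@pytest.mark.parametrize("pid", CATALOG_IDS)
def test_convex_catalog_passes_screen(pid):
    assert screen_criteria_A(get_polyhedron(pid)).passes_criteria_A


def test_screen_threshold_behaviour():
    hexa = get_polyhedron("P-3")
    assert screen_criteria_A(hexa, min_feature_fraction=0.05).passes_criteria_A
    assert not screen_criteria_A(hexa, min_feature_fraction=2.0).passes_criteria_A
    with pytest.raises(ValueError):
        screen_criteria_A(hexa, min_feature_fraction=0.0)


def test_validation_flags_open_mesh():
    spec = get_polyhedron("P-3")
    broken = type(spec)(id="broken", name="cube minus a face",
                        vertices=spec.vertices, faces=spec.faces[:-1],
                        convex=True, isotropic_symmetry=False)
    rep = validate_polyhedron(broken)
    assert not rep.watertight and not rep.ok


def test_stl_roundtrip(tmp_path):
    spec = get_polyhedron("P-7")
    path = str(tmp_path / "p7.stl")
    export_mesh(spec, path)
    mesh = import_stl(path)
    assert np.isclose(mesh.volume, to_mesh(spec).volume, rtol=1e-6)
    export_mesh(spec, str(tmp_path / "p7.obj"))  # OBJ export also supported
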