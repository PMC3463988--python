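import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyscaf.assembly import VoxelGrid
from polyscaf.catalog import get_polyhedron
from polyscaf.unitcell import OpenCellSpec
from polyscaf.voids import (
    PRINTED_RATIOS,
    classify_group,
    detect_enclosed_voids,
    lost_windows,
)


def _grid(occ):
    return VoxelGrid(np.asarray(occ, dtype=bool), 1.0, np.zeros(3))


def _brute_enclosed(occ):
    """Oracle: exhaustive BFS component labeling of the void phase."""
    from collections import deque

    occ = np.asarray(occ, bool)
    seen = np.zeros_like(occ)
    shape = occ.shape
    enclosed = 0
    for start in np.argwhere(~occ):
        start = tuple(start)
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        touches = False
        while queue:
            p = queue.popleft()
            for ax in range(3):
                if p[ax] in (0, shape[ax] - 1):
                    touches = True
            for d in (-1, 1):
                for ax in range(3):
                    q = list(p)
                    q[ax] += d
                    if 0 <= q[ax] < shape[ax]:
                        q = tuple(q)
                        if not occ[q] and not seen[q]:
                            seen[q] = True
                            queue.append(q)
        enclosed += 0 if touches else 1
    return enclosed


def test_hollow_cube_has_one_enclosed_void():
    occ = np.zeros((7, 7, 7), dtype=bool)
    occ[1:6, 1:6, 1:6] = True
    occ[2:5, 2:5, 2:5] = False  # sealed cavity
    rep = detect_enclosed_voids(_grid(occ))
    assert rep.enclosed_components == 1
    assert rep.enclosed_void_fraction == pytest.approx(27 / 343)


def test_fully_solid_grid_reports_zero_void():
    rep = detect_enclosed_voids(_grid(np.ones((4, 4, 4))))
    assert rep.enclosed_components == 0
    assert rep.exterior_connected_void_fraction == 0.0


def test_corner_diagonal_void_counts_as_enclosed():
    # 6-connectivity: a cavity reachable only through an edge diagonal stays
    # enclosed (conservative for powder removal)
    occ = np.ones((5, 5, 5), dtype=bool)
    occ[2, 2, 2] = False
    occ[0, :, :] = False  # exterior void slab
    rep = detect_enclosed_voids(_grid(occ))
    assert rep.enclosed_components == 1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_flood_fill_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    occ = rng.random((8, 8, 8)) < rng.uniform(0.3, 0.7)
    rep = detect_enclosed_voids(_grid(occ))
    assert rep.enclosed_components == _brute_enclosed(occ)


def test_random_20cube_grids_match_oracle(rng):
    for _ in range(3):
        occ = rng.random((20, 20, 20)) < 0.55
        rep = detect_enclosed_voids(_grid(occ))
        assert rep.enclosed_components == _brute_enclosed(occ)


def test_hexahedron_never_loses_windows():
    hexa = get_polyhedron("P-3")
    for x in (1.0, 4.0, 12.0):
        assert lost_windows(OpenCellSpec(hexa, PO=x, BT=1.0)) == 0


def test_lost_windows_appear_at_thick_beams():
    p8 = get_polyhedron("P-8")
    assert lost_windows(OpenCellSpec(p8, PO=2.0, BT=1.0)) > 0
    assert lost_windows(OpenCellSpec(p8, PO=12.0, BT=1.0)) == 0


def test_classify_rejects_non_library_solid():
    with pytest.raises(ValueError):
        classify_group(OpenCellSpec(get_polyhedron("P-2"), PO=2.0, BT=1.0))


class TestEvaluationTable:
    """Bulk classification of the six libraries (session-cached)."""

    def test_hexahedron_all_perfect(self, evaluation_rows):
        score, labels = evaluation_rows["P-3"]
        assert all(v == "A" for v in labels.values())
        assert score == 18

    def test_truncated_octahedron_anchors(self, evaluation_rows):
        _, labels = evaluation_rows["P-7"]
        assert labels[1.0] == "C"  # enclosed void at the thickest beams
        assert all(labels[x] == "A" for x in (4.0, 5.0, 6.0, 8.0, 10.0, 12.0))

    def test_truncated_octahedron_score(self, evaluation_rows):
        score, _ = evaluation_rows["P-7"]
        assert score == 14

    def test_labels_monotone_in_ratio(self, evaluation_rows):
        rank = {"C": 0, "B": 1, "A": 2}
        for pid, (_, labels) in evaluation_rows.items():
            vals = [rank[labels[x]] for x in PRINTED_RATIOS]
            assert vals == sorted(vals), f"{pid}: {vals}"

    def test_truncated_hexahedron_least_available(self, evaluation_rows):
        scores = {pid: s for pid, (s, _) in evaluation_rows.items()}
        assert min(scores, key=scores.get) == "P-8"
        assert max(scores, key=scores.get) == "P-3"
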