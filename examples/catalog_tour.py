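"""Tour the polyhedron catalog and the AM-feasibility screen.

Builds every catalog solid plus the nonconvex fixtures, validates the
geometry, and runs the production-feasibility screen.  The printed line per
solid shows vertex/edge/face counts (V - E + F = 2 for every closed
polyhedron) and whether the solid survives as a scaffold candidate:
stellated/spiky forms are rejected because their fine details fall below
the resolution of laser-based additive manufacturing.
"""

from polyscaf import get_polyhedron, list_polyhedra, screen_criteria_A, validate_polyhedron

for pid in list_polyhedra():
    spec = get_polyhedron(pid)
    rep = validate_polyhedron(spec)
    screen = screen_criteria_A(spec, min_feature_fraction=0.05)
    print(f"{pid:5s} {spec.name:42s} V={len(spec.vertices):3d} "
          f"E={len(spec.edges):3d} F={len(spec.faces):3d} "
          f"euler={rep.euler_characteristic} "
          f"{'convex' if screen.convex else 'NONCONVEX':9s} "
          f"{'pass' if screen.passes_criteria_A else 'FAIL'}")

print("\nA 'FAIL' under the screen means the solid cannot be printed as a"
      " unit cell; the F-* fixtures stand in for the eliminated stellations.")
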