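"""Relative strength screen: stacked unit cells under compression.

Stacks two copies of each candidate solid along the load axis and solves a
voxel linear-elastic compression between rigid plates.  Solids that meet
face-to-face spread the load (low peak von Mises stress); solids that meet
only at vertices or edges concentrate it.  Only the relative ordering is
meaningful — the protocol's absolute units are arbitrary.

This is the slowest example (a few minutes of sparse solves).
"""

from polyscaf import rank_polyhedra
from polyscaf.fescreen import LOW_STRESS_GROUP, VERY_HIGH_STRESS_GROUP

ids = ("P-3", "P-7", "P-13", "P-1", "P-5")  # three face-contact, two edge/vertex
ordered, peaks = rank_polyhedra(ids, resolution=16)
print("peak EQV stress, lowest first (protocol units):")
for pid in ordered:
    group = ("face-contact" if pid in LOW_STRESS_GROUP else
             "edge/vertex-contact" if pid in VERY_HIGH_STRESS_GROUP else "other")
    print(f"  {pid:5s} {peaks[pid]:10.1f}   ({group})")
print("\nFace-contact solids should rank strictly below edge/vertex-contact ones.")
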