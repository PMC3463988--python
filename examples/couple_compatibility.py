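"""Interface compatibility of merged scaffold libraries.

Places every pair of the six open-cellular libraries contiguously and
computes the intersection index: the percentage of the larger contact patch
shared by both cells on the interface plane.  Group I couples (index 0)
cannot transfer load at all — their contact faces have no common geometry —
while higher indices mean better load transfer when mixing libraries in one
graded scaffold.
"""

from polyscaf import couple_table

df = couple_table()
print(df.to_string())
zeros = df[df["intersection_index"] == 0.0]
print(f"\n{len(zeros)} of {len(df)} couples are geometrically impossible (Group I).")
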