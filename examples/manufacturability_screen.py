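"""Group A/B/C manufacturability screen for one open-cellular library.

For the truncated octahedron, classifies each printed PO:BT ratio:
  A - perfect geometry,
  B - some face windows lost to beam overlap but all void still reachable,
  C - enclosed voids (unfused material could never be removed: unprintable).
The availability score sums 2/1/0 over the nine ratios; higher means the
library is printable over a wider design range.
"""

from polyscaf import availability_score

score, labels = availability_score("P-7")
for x, label in labels.items():
    note = {"A": "perfect", "B": "windows lost", "C": "ENCLOSED VOID"}[label]
    print(f"PO:BT = {x:>4g}:1   group {label}   ({note})")
print(f"\navailability score: {score} (max 18)")
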