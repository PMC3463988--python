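"""Porosity of the open-cellular hexahedron library, exact vs voxel.

The hexahedron (cubic frame) lattice has an exact bulk porosity
phi(x) = 1 - (3x+1)/(x+1)^3 with x = PO:BT.  This script compares the voxel
pipeline against the closed form at the nine printed design ratios and fits
the Logistic Power model y = a/(1+(x/b)^c).  The fitted constants
(a ~ 1.01, b ~ 1.01, c ~ -1.51) summarize how porosity saturates toward 1
as pores grow relative to the beams; r is the correlation between computed
and fitted porosity.
"""

from polyscaf import (
    PRINTED_RATIOS,
    fit_logistic_power,
    hexahedron_porosity_closed_form,
    porosity_curve,
)

curve = porosity_curve("P-3")
print(" x    voxel phi   exact phi")
for x, y in zip(curve.x, curve.y):
    print(f"{x:4g}   {y:.6f}   {hexahedron_porosity_closed_form(x):.6f}")

fit = fit_logistic_power(curve)
print(f"\nLogistic Power fit: y = {fit.a:.2f} / (1 + (x/{fit.b:.2f})^{fit.c:.2f})")
print(f"correlation r = {fit.r:.4f}")
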