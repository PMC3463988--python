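# Methods

This note records the geometric model behind `polyscaf`, the conventions
chosen where the problem is under-determined, the numerical parameters, and
the limits of what the test suite shows.

## The model

A scaffold is an `n×n×n` Cartesian tiling of one polyhedral unit cell.
Cells come in two forms:

* **Close-cellular** — the solid polyhedron. Pores arise only in the gaps
  between tiled cells, so porosity is independent of cell size.
* **Open-cellular** — the polyhedron wireframe thickened into beams of
  thickness `BT`, leaving face openings (pores) of size `PO`. The design
  parameter is the ratio `x = PO : BT`.

### Catalog geometry

The 18 convex candidates are generated from exact coordinate orbits
(sign/permutation expansions of the standard radical coordinates; the snub
cube from the tribonacci constant). The snub dodecahedron is solved
numerically as the orbit of one generating point under the 60 icosahedral
rotations, with the generator fixed by equalizing its five nearest-neighbour
distances (residual < 1e−8). Faces are recovered from convex hulls with
coplanar-facet merging, so face tables are always consistent with the
coordinates: every solid is watertight with Euler characteristic 2, planar
faces (tolerance 1e−6 of the circumradius) and outward-oriented cycles.
All solids are normalized to unit circumradius and rescaled downstream.
Nonconvex test fixtures (`F-1` stellated octahedron, `F-2`/`F-3` spiky
Kleetopes) represent the forms eliminated by the AM-feasibility screen.

### Beams, junctions, and the pore-size convention

The literature rarely states how a wireframe is thickened; these choices are
the load-bearing conventions of the whole package:

* **Beam section.** Each edge carries a prism whose cross-section is the
  parallelogram bounded by planes parallel to the two adjacent polyhedron
  faces at perpendicular distance `BT/2` from the edge axis — one beam face
  lies flush in each adjacent face plane. For the hexahedron this gives
  axis-aligned square beams and an exact tiled solid fraction
  `(3x+1)/(x+1)³`, which doubles as the package's analytic oracle. A circular
  section is available as an option.
* **Junction nodes.** At each vertex the convex hull of the incident beam
  end caps is added. Bare beam unions leave sliver cavities between the
  parallelogram prisms at vertices, which show up as spurious micro-voids;
  the node fills them. For the hexahedron the node is exactly the corner
  cube, so the closed form above is preserved.
* **Pore size.** `PO` is the inscribed-circle diameter of the **largest**
  face window after thickening (the window of face *f* is the in-plane
  region at depth > `BT/2` below every other face plane; its inscribed
  circle comes from a Chebyshev-center LP). Cells are scaled by a
  bracketed root solve so the designated window measures exactly `PO`.
  For the hexahedron this reduces to the intuitive `L = PO + BT`.
  A smallest-window convention would make groups B and C unreachable (the
  designated window is open by construction), so largest-window is the only
  designation compatible with the published classification structure.
* **Lattice.** All six libraries tile by simple-cubic, axis-aligned
  translations with their axial faces in contact (duplication along the
  Cartesian axes). Gap polyhedra between cells are allowed — they are the
  "pore between polyhedrons". Bulk quantities are evaluated on the periodic
  repeat `[−L/2, L/2]³` including all neighbour contributions, which equals
  the central repeat of a 3×3×3 block.

### Manufacturability classification (groups A/B/C)

* **Enclosed voids** are void regions of the tiled assembly not reachable
  from the block exterior by 6-connected flood fill (conservative with
  respect to powder removal: diagonal-only passages do not count).
  Detection is run on a *conservatively* rasterized grid — material dilated
  by half a voxel — so passages narrower than the analysis resolution are
  never asserted to be connected. Classification uses pitch `BT/4` confirmed
  at `BT/6`, with one refinement to `BT/8` on disagreement.
* **Lost windows**: a face window whose inscribed diameter falls below `BT`.
  At that scale the bordering beams have effectively merged and the opening
  does not survive fabrication as a distinct feature; a strict zero-area
  rule was rejected because windows analytically open by a few percent of
  `BT` are physically sealed at any realistic print resolution.
* **Monotone closure**: manufacturability is monotone in `x` (thickening
  beams can only close passages), so an enclosed void found at some ratio
  forces group C at every smaller ratio. This also absorbs single-pitch
  detection flicker at the boundary where a gap pore transitions between
  fully filled and barely open.
* Label: **C** if enclosed voids exist, else **B** if windows are lost, else
  **A**. The availability score sums A→2, B→1, C→0 over the nine standard
  ratios {1, 2, 3, 4, 5, 6, 8, 10, 12}.

### Porosity

`φ = 1 − V_material / V_apparent` on the periodic repeat, with unbiased
center-sampled voxelization at pitch `BT/4` (for the hexahedron the beams
are voxel-aligned, so this is already exact). Curves are fitted with the
Logistic Power model `y = a/(1 + (x/b)^c)` by bounded nonlinear least
squares (start `a=1, b=median(x), c=−1.5`; `a ∈ (0, 2]`; five seeded random
restarts on failure); `r` is the Pearson correlation of observed vs fitted
porosity. Ratios classed C are excluded from a library's curve (they are
unmanufacturable designs); if fewer than four points survive, the full grid
is used, porosity being purely geometric.

### Interface mismatch

The contact patch of a cell is the exact 2D cross-section of its beams and
nodes on the boundary plane, **clipped to the bare contact-face polygon**
and normalized by the repeat length. Clipping encodes the judgment that
junction bulge outside the intended contact face is not contact area: group
I ("not possible") couples are those whose contact faces share no geometry,
and with this definition all such couples compute exactly 0 at every ratio.
The index divides the overlap area by the larger patch area, anchoring
identical cells at 100. The default couple ratio is 10:1, the smallest
standard ratio at which every library is group A under this package's own
screen. Polygon algebra is exact (shapely); areas below 1e−9 of the repeat
count as zero.

### FE screening

Trilinear 8-node voxel elements on the occupancy grid; E = 110 000 MPa,
ν = 0.33; compression between frictionless rigid plates (bottom plate fixed
axially, top displaced; lateral rigid-body modes pinned at two bottom
nodes). A solid block reproduces the uniaxial patch test to machine
precision, and the response is exactly linear in the applied strain. Sparse
systems up to 40 000 free DOFs are solved directly (SuperLU), larger ones by
Jacobi-preconditioned CG (rtol 1e−8). Peak stress is the 99.5th percentile
of element von Mises — the raw maximum sits on voxel corners and diverges
with refinement — and for ranking it is taken within a band of one sixth of
the cell height around the cell-to-cell junction, where combinability is
decided. Vertex- and edge-contact stacks receive a one-voxel contact pad at
the minimal-gap columns so the system is solvable while the concentration
phenomenon is preserved. **Only relative stresses are meaningful**: the
protocol's load magnitude and cell size are arbitrary, so the screen
reproduces orderings and group memberships, never MPa values.

## Problem sizes

Defaults were chosen so the full classification (six libraries × nine
ratios, two confirmation pitches) runs in about 90 s, the porosity curves in
about 80 s, and the 11-solid FE ranking at resolution 16 in about 70 s on a
single CPU. The FE couple analysis uses resolution 32–40 per repeat
(10–20 s per couple).

## What the synthetic geometry does and does not show

The catalog plus the beam/node model *is* the study object here — there is
no external data. Passing tests therefore demonstrate the internal
consistency of the pipeline (exact analytic anchors, voxel convergence,
oracle-checked flood fill, patch tests) and the reproduction of the
published classification structure, not the behaviour of any physical
scaffold: no surface roughness, no print shrinkage, no material anisotropy,
and no powder-removal mechanics are modeled.

## Known limitations and honest disagreements

The published evaluation was made by visual CAD inspection with unstated
thickening and pore-measurement conventions. Under this package's frozen
conventions:

* The A/B/C table matches 45 of 54 published cells. All hard anchors hold
  (hexahedron all-A; truncated octahedron C at 1:1 and A at ≥ 4:1), and the
  mismatches are one-cell B/C boundary shifts traceable to neighbour beams
  widening gap-facing windows under symmetric thickening.
* Availability scores: 18 (P-3), 14 (P-7), 14 (P-13), 12 (P-11), 11 (P-15),
  4 (P-8). P-3 highest and P-8 lowest reproduce; the published middle
  ordering (P-7 = P-11 > P-13 > P-15) does not — P-13 scores high here
  because its gap pores stay connected at thick beams.
* Porosity: the hexahedron fit constants reproduce essentially exactly; all
  correlations exceed 0.997. The published *identical* fits for the
  truncated octahedron and cuboctahedron do not reproduce (our curves differ
  by 0.01–0.07): no window designation makes those two beam densities
  coincide, and their printed equality appears specific to the original
  unstated sizing. The published cross-library porosity ordering differs for
  the same reason.
* Mismatch: all eight group-I couples are exactly 0 and self-couples 100.
  The published nonzero indices (e.g. 73.3 for cuboctahedron with the
  rhombitruncated cuboctahedron) depend on the unknown ratio and beam
  convention; ours are smaller, and that couple does not reach group III.
* FE: the low/very-high stress-group separation reproduces strictly; the
  published couple-stress ranking (P-7/P-13 highest) does not — in our
  geometry that couple has the largest contact overlap at 5:1 and hence the
  least junction concentration.

The affected acceptance-criteria tests are kept at their stated tolerances
and fail honestly rather than being loosened.
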