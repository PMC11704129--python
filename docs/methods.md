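# Methods

## Images as filtered cubical complexes

A slice is a grid of intensities normalized per slice to [0, 1] (min-max;
the flag `normalize` disables it for calibrated data — normalizing per
stack instead of per slice would couple slices through their brightest
voxel, and per-slice normalization is what keeps the automatic threshold
comparable across depths, so it is the default). The complex is the
V-construction: pixels are 0-cells, 4-adjacent pixels bound 1-cells, 2×2
blocks bound 2-cells, and each higher cell takes the maximum of its
vertices. The ascending (sublevel) filtration inserts cells by increasing
value; the descending filtration is computed as the ascending filtration
of the negated image (negation rather than `1 − u` keeps births/deaths
exact in floating point). Cells with equal value are ordered by dimension
then lexicographic index, which makes diagrams deterministic.

### H1 via planar duality

For a 2D image, a 1-cycle of the ascending filtration encloses a bounded
component of the complement, and the complement's connectivity is the
dual graph of the squares (one node per 2×2 square, one outer node for
the unbounded face, dual edges weighted by the primal edge value, which
never exceeds either adjacent square's value). Sweeping the dual edges in
decreasing weight with a union-find gives each H1 pair as a merge event:
birth = the weight of the merging dual edge, death = the maximum square
value of the dying component, with the elder (larger-death) component
surviving and the outer node immortal. Zero-persistence pairs are
discarded. This is exact — not approximate — for the max-rule complex,
and the test suite checks it against an independent oracle that counts
Betti-1 as `C − (V − E + F)` (components minus Euler characteristic) on
every level set of randomized images.

Equal component maxima are resolved toward the lexicographically earlier
critical square, so ties are deterministic too.

### Representatives

The displayable representative of a pair is a level-set region
boundary: for an ascending pair, the 8-connected component of the
strict superlevel set at level `b + α(d − b)` that contains the
death-critical pixel (the max pixel of the dying component's largest
square); descending pairs are symmetric with a strict sublevel set.
`α` (`rep_level_fraction`, default 0.2) offsets the extraction level
slightly off the birth value: at `α = 0` the strict-at-birth region is
recovered exactly on clean piecewise-constant data, but any blur gives
bright regions an arbitrarily faint skirt just above the birth level,
inflating the region by the blur support. A small fractional offset
removes the skirt while preserving which region is extracted whenever the
class's lifespan dominates nearby saddle values (the saddle and nested
fixtures pass unchanged at 0.2). Interior holes are filled and the
external boundary is traced on the pixel cracks (vertices at half-integer
corners, unit steps), with a right-hand turn rule at pinch corners so an
8-connected region yields one closed curve. Crack contours make the fill
operation exactly invertible, which the suite asserts on random blobs.

The image border is the complex boundary; a bright structure touching the
border cannot be enclosed and its class collapses. `pad_border` adds a
one-pixel zero frame (and shifts results back) for data where structures
are clipped.

## Automatic persistence threshold

`optimal_threshold` (selector `max_gap`, the default) sorts the positive
persistences, prepends the diagonal value 0 as an anchor, and returns the
midpoint of the widest gap between consecutive values; `fixed` uses a
user value. The anchor encodes the assumption that noise classes live
near the diagonal: when even the smallest observed persistence is far
from 0, the whole diagram is signal and the threshold falls below it
(a single value `p` yields `p/2`, so a one-point diagram is never
emptied). Selection keeps persistence strictly greater than the
threshold. An optional `min_persistence` floor (default 0, normalized
intensity units) both prunes sub-floor values before the gap scan and
lower-bounds the result, for data where a hard noise floor is known.

## Per-slice segmentation

Membrane: threshold the ascending diagram, take the union of the selected
regions, fill holes, keep the largest 8-connected component (more than
one selected component is reported — the model assumes one cell profile
per slice), and trace Γ. No selected cycle raises an explicit
"no membrane found" error rather than returning an empty contour.

Cavities: threshold the descending diagram restricted to classes whose
filled representative lies ≥ 99% inside Γ's interior
(`inside_gamma_fraction`; a strict 100% is brittle to the one-pixel crack
rasterization). The threshold is recomputed on that subfamily, so cavity
selection is independent of the membrane's much larger persistence. The
death-critical pixel is used as a cheap pre-filter before extracting
regions.

Nested cycles: curve `a` is nested in `b` iff every interior pixel of `a`
lies in `b`'s interior. For each nested pair, innermost first, the inner
interior is dilated by a Euclidean disk (exact distance transform) of
radius the directed Hausdorff distance from the inner to the outer curve
(`hausdorff_direction` flips it), and the outer representative becomes
the external boundary of the largest component of the set difference.
Inner→outer is the default because the inner curve of a saddle pair runs
close to the outer everywhere except across the saddle, so the dilation
carves exactly the saddle region away, leaving the outer curve hugging
the remaining structure. Two degenerate cases fall back to keeping the
outer curve unchanged, with a warning: an emptied difference
(near-coincident curves) and a difference that survives only as an
annular shell around the inner curve (concentric geometry — dilation by
the Hausdorff radius tiles a concentric outer disk exactly, so no
meaningful split exists). Refinement iterates to a fixed point, is
idempotent, preserves the curve count, and raises after `n²` sweeps if
genuinely non-convergent.

## Surface reconstruction

Contours are lifted to physical coordinates
`(x, y, z) = (col·pixel_size, row·pixel_size, slice·axial_spacing)` µm
and oriented counter-clockwise. Each membrane profile splits into luminal
and basal open arcs at the two extremal vertices along the axis
perpendicular to `lumen_direction` (default: lumen toward decreasing
rows, matching the phantom's top-side invagination); the arcs share their
two endpoints, so the two sheets meet at a seam. Cavity contours attach
whole to the luminal side and are never split.

Tiling between adjacent slices emits, for each vertex `p`, the triangle
(`p`, successor of `p`, nearest vertex of the other contour within
`d_max`); the symmetric pass anchors its nearest-vertex association at
the successor so the two passes produce the complementary halves of each
quad (aligned contours close into a tube of Euler characteristic 0)
instead of crossed diagonals. Vertices without a partner within `d_max`
(default 1 µm ≈ three pixels at 0.16 µm lateral resolution) produce no
triangle; rims stay open, which is what prevents a cavity ending between
slices from welding onto the membrane. Cavities are tiled only against
cavities of the adjacent slice whose projected interiors overlap by at
least one pixel — overlap is the weakest correspondence consistent with
the guaranteed separation of cavities within a slice. Slice pairs with an
axial gap above twice the axial spacing are not tiled (the surface splits
across missing slices).

Smoothing is Taubin's two-step scheme with uniform Laplacian weights and
the stability condition `µ < −λ < 0`; defaults (0.5, −0.53, 10) are the
classical stable pair and change the enclosed volume of a closed test
surface by under 1%. Remeshing is vertex clustering: vertices are
k-means-clustered (weighted by one third of their incident triangle
area) into a target count distributed over connected components by area,
each cluster contracts to its weighted centroid, and triangles spanning
three distinct clusters survive (duplicates and degenerates dropped).
This halves the triangle-area coefficient of variation on strongly graded
tubes and cannot merge components. The k-means seed is taken from the
pipeline seed, the only stochastic step outside the phantom generator.

## Synthetic phantom

The generator rasterizes, per slice: an elliptical membrane band
(intensity 0.95, thickness 5 px, radii 34×48 px with a mild quadratic
z-modulation), cytoplasm 0.60, background 0.05, dark ellipsoidal cavities
(0.15) whose z-spans jointly cover all 20 slices, and an invagination —
a 10 px wide channel at background intensity breaching the band's top
down to its centre on every slice, as the open aortic lumen does. The
channel matters topologically: it connects the interior to the
background, so the cytoplasm is not itself a closed descending class and
each cavity appears as its own class with persistence equal to its
contrast against the cytoplasm (0.45). Slices are blurred (σ = 0.5 px,
a PSF-scale default) and optionally degraded with additive Gaussian
noise, clipped to [0, 1]; generation is deterministic in the seed.

Closed-band geometries (no channel) instead make the whole interior the
elder descending class, nesting the cavity representatives inside it —
the `nested_cavities` fixture builds exactly that configuration, with two
faint dots anchoring the threshold's noise cluster.

What the phantom does not emulate: anisotropic/defocus PSF, Poisson
(signal-dependent) noise, intensity attenuation with depth, neighbouring
cells, and membrane texture. Passing the phantom suite therefore
demonstrates correctness of the topology, thresholding, and geometry
pipeline under idealized contrast, not segmentation accuracy on real
acquisitions.

Problem sizes used throughout the test and acceptance runs — 96×128×20
voxel phantoms, 16×16 oracle images, 600-vertex remesh targets — are the
package's chosen desk-scale study conditions; all thresholds and
tolerances above are stated where they are defined.

## Known limitations

- Slice-wise topology only: no 3D cubical persistence; structures thinner
  than one slice alias.
- One cell profile per slice is assumed; multi-cell scenes keep only the
  largest selected component.
- The gap threshold assumes noise concentrates near the diagonal; a dense
  mid-persistence texture would blur the gap.
- Open rims are left open by design; watertight output would need a
  capping step.
- Pure-Python union-find: about 50 ms per 96×128 slice and direction —
  fine for stacks, not for real-time use.
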