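# Methods

This note documents the models, conventions and numerical choices behind
`cbflat`, and what the synthetic fixtures do and do not establish about
behavior on real data.

## Geometry model and conventions

Volumes are NIfTI-style voxel grids with a 4×4 affine mapping 0-based voxel
*centers* to world mm; 4D volumes are stacks of 3D frames sharing one
affine.  Surfaces are triangle meshes with consistent counter-clockwise
winding; in the flat plane, counter-clockwise faces have positive signed
area, so a negative signed area marks a fold-over.  Vertex areas use
one-third incidence weighting (each vertex takes a third of every incident
triangle) rather than Voronoi weights, which can go negative on obtuse
triangles; the weighting conserves total area exactly.

Grey/white masks derived from probability volumes use strict inequalities:
the white-matter body is `p_white > 0.4`, and remaining voxels are grey
where `p_grey > 0.5`.  The two masks are disjoint by construction.

## Vertex correspondence

The outer and inner surfaces are reconstructed independently, so a
correspondence must be built.  Given landmark pairs (an outer vertex and
its matching inner point — in practice placed at the base and superficial
aspect of major fissures), the displacement vectors at the landmarks are
interpolated across all outer vertices with a thin-plate-spline RBF
(`scipy.interpolate.RBFInterpolator`, smoothing 0, hence exact at the
landmarks), and each displaced vertex is projected to the closest point on
the inner surface.  The projection uses exact point-to-triangle distances
over candidate faces found by a KD-tree on face centroids (plus all faces
incident to the nearest vertex), with ties resolved to the lowest face
index.  The closest-point step guarantees the result lies on the inner
surface; the RBF only decides *where along* it.  The interpolation law
between landmarks is this package's choice — any smooth,
landmark-exact interpolant is admissible, and thin-plate splines are the
standard minimal-bending choice.  At least 4 non-coplanar pairs are
required; the projection residual is stored per vertex so poorly guided
regions can be audited.

## Sampling and integration

The sample point at vertex `v`, depth `d` is the convex combination of the
outer and inner positions, pushed through the inverse affine.  Trilinear
interpolation is the default for continuous data; nearest-neighbor for
labels (labels must never blend).  Depth endpoints (0 and 1, i.e. exactly
on the surfaces) are included by default; spacing and range are caller
adjustable.  Mask membership is decided at the nearest voxel, not by
interpolating the mask.  Samples outside the volume's voxel-center hull or
outside the mask are NaN; statistics ignore NaN, and a vertex with no
valid sample yields NaN (scalar statistics) or 0 / unassigned (labels) —
never an error, since surface fringes legitimately leave the mask.

Tie-breaks are deterministic everywhere: the mode prefers the smallest
label, winner-take-all the lowest compartment index, and the somatotopy
composite the first condition in list order.  Activation thresholds are
strict (`> threshold`); the threshold's units are those of the input map
and are left to the user.  The second-level map is a voxelwise one-sample
t-test (`t = mean / (sd/√n)`, `df = n − 1`, sd with ddof 1); zero-variance
voxels are flagged and produce ±inf (0 when the mean is also 0).
Multiple-comparison thresholds (e.g. random-field FWE) are deliberately not
computed here — statistical inference belongs in the original 3D space,
and the t-map is thresholded at a caller-supplied value.

## Cuts

To flatten a closed surface it is slit open along user-supplied vertex
paths (in the cerebellar map: along major fissures).  Only strictly
interior path vertices are duplicated; endpoints are left intact, so a slit
terminating inside the surface stays closed at its tip.  Faces are
classified to the two sides of the path by their winding relative to the
directed path edges and by fan connectivity around the interior vertices.
Cutting never changes face count or total area, and a provenance array maps
every cut-surface vertex back to its original, so vertex data computed on
the uncut surface can be carried across (duplicated vertices split any
per-vertex volume equally between copies, keeping partitions exact).
Automatic placement of cut paths is out of scope; paths are given as vertex
index lists.

## Represented volume and distortion

The rule assigning grey volume to flatmap triangles: each in-mask voxel
center is assigned to the vertex whose correspondence segment is nearest
(point-to-segment distance, ties to the lowest vertex index), and each
vertex's tally is split equally among its incident faces.  This is
deterministic and partitions the mask exactly — summed per-triangle volumes
equal voxel count × voxel volume to machine precision, which the tests
assert as an identity.  Distortion is reported as log base 2 of
(area share / volume share); the base affects only display since band
statistics are computed on the raw ratio.  Band fractions are per-vertex
(using the area-weighted geometric mean of incident face ratios), for the
bands [1/2, 2] and [1/1.5, 1.5]; the narrow band is a subset of the wide
band by construction.  The per-compartment table compares percent of total
vertex area against percent of labeled in-mask voxels, with a Pearson
correlation across compartments; with fewer than two compartments or zero
variance the correlation is degenerate and is reported as 1 for exact
agreement, with a flag in the table's metadata.

## Flatmap relaxation

The optimizer moves interior vertices of an initial 2D layout, outline
fixed, to minimize `E = Σ_f t_f · log²(a_f / (A·t_f))` — the
target-weighted squared log of each face's area share over its target
share.  The log form penalizes over- and under-representation
symmetrically and matches the displayed distortion measure; `E = 0` iff
every share matches.  The gradient is analytic (signed-area derivatives);
descent uses normalized gradient direction with a backtracking line search
starting at 0.1× the layout's bounding-box span, doubling after each
accepted step.  Any trial step that inverts a face has infinite objective
and is halved away — a barrier, chosen because the published map must have
no fold-overs.  Termination: relative objective decrease below `tol`
(default 1e-6), gradient exactly zero, no descent step found at any scale,
or `max_iter` (default 2000).  The optimizer is deterministic.  Because
the boundary is fixed, the total signed area of the triangulated disk is
constant, so the objective depends on shares only; this gives exact scale
equivariance (scaling the input layout scales the output), which is
tested.  Plain gradient descent converges slowly near the optimum but its
monotone, inversion-free trajectory is the property that matters for map
construction; runs in the examples use a few hundred iterations.

## Synthetic fixtures

The generator emulates the projection-relevant structure of the real data
with a sinusoidally folded open sheet: outer surface
`z = z₀ + (fold_depth/2)·sin(2π·n_folds·x/L)` over an `L × 2L/3` mm domain,
inner surface offset inward by `thickness` mm along local normals, grey
mask = voxels between them.  Folding along one axis keeps every ground
truth analytic: the exact flat layout is `(arc length(x), y)`, segment
lengths all equal `thickness`, and the band volume approaches
`arc length × width × thickness`.  Defaults — 72×48×40 grid at 1 mm, 60 mm
sheet, 3 folds of 6 mm depth, 2 mm thickness, 49×25 vertices — put several
grey layers into a vertical voxel column, the regime the line-sampling
projection exists for, while keeping full runs in seconds.  The offset
surface must not self-intersect: construction fails if
`thickness × max curvature ≥ 0.9`.

True per-face volume shares are computed by brute-force sub-voxel counting
(each grey voxel split 2³-fold, each subpoint assigned to its nearest
segment) with the generator's own independent assignment code.  Compartment
fixtures partition the sheet into contiguous slabs along x with widths
proportional to 1:2:…:K by default — deliberately unequal, like real
lobular compartments, so area-versus-volume comparisons have dynamic
range; probability volumes are smoothed slab indicators renormalized to
per-voxel sums ≤ 1.  Blobs are isotropic Gaussians restricted to the mask,
with the ground-truth peak vertex defined by the nearest correspondence
segment to the blob center.

What the fixtures do *not* emulate: closed cerebellum-like topology (the
sheet is open, so cutting is exercised on grid meshes instead), folding in
two directions, normalization-algorithm differences between template
spaces, partial-volume and noise structure of real MRI, and hand-edited
masks.  Passing tests therefore establish the correctness of the
geometric/statistical machinery, not the anatomical fidelity of any
particular cerebellar surface set.

## Problem sizes and tolerances

Tests run the generator mostly at a reduced 25×13 mesh (seconds per
session); the acceptance script uses the full default spec, 100 synthetic
subjects for the t-map, and 300 relaxation iterations, completing in well
under a minute.  Identities (partition, conservation, boundary
classification) are asserted at machine precision; analytic comparisons
use the tolerance their discretization supports (e.g. mask volume within
5% of the continuum formula at 1 mm voxels; sphere correspondence within
5% of the radius at icosphere subdivision 2).  The mode statistic accepts
values within 1e-6 of an integer to absorb interpolation round-off on
integer-valued volumes.

## Known limitations

- The optimizer is first-order; for very large meshes a quasi-Newton or
  multigrid scheme would converge faster.  No step is taken toward global
  optimality — like any descent method it finds the basin of its start.
- Voxel-to-vertex assignment uses exhaustive chunked distance computation
  (O(voxels × vertices)); adequate at atlas sizes, but a spatial index
  would be needed for much denser meshes.
- `build_correspondence` assumes the guide landmarks are sensibly placed;
  with degenerate (coplanar, clustered) landmarks the RBF extrapolates
  poorly, and only the projection residual reveals it.
- Boundary extraction draws raw mesh edges; no smoothing of the dotted
  compartment boundaries is attempted.
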