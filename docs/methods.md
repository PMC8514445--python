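# Methods

This note documents the models and procedures implemented in `mesomap`,
the parameters that matter, what the synthetic phantoms do and do not
emulate, and the numerical choices made where the design was open.

## Coordinate conventions

Pixel coordinates are `(row, col)`, 0-based, rows increasing toward
posterior.  The anatomical frame has x lateral (right positive) and y
anterior positive, in millimetres, with bregma at (0, 0) mm.  The
conversion is linear and isotropic: `row = bregma_row − y / s`,
`col = bregma_col + x / s` with `s` the pixel pitch in mm/px.  Every
warp is a map on `(row, col)` points; an affine map is stored as a 2×3
matrix `[A | t]` acting as `p' = A p + t`.

## Reference atlas and landmarks

The atlas is a 2D top-view integer-labeled parcellation plus a region
table (id, acronym, name, hemisphere) and a boundary image (labeled
pixels adjacent to a differing label).  Users supply their own label
image and table; the package also bundles a programmatically drawn test
atlas: two mirrored half-ellipse hemispheres partitioned into 10
angular/radial sectors each plus olfactory bulbs (22 regions), with
exact left/right mirror symmetry about the midline column.  Its default
pixel pitch makes the cortex 8 mm wide, i.e. ~0.04 mm/px at 256 px.

Nine landmarks anchor registration: the anterior midline point, left and
right frontal poles, left and right posterior retrosplenial tips, left
and right lateral tips, bregma, and lambda.  Their millimetre
coordinates default to values derived from the bundled atlas geometry
(e.g. lateral tips at (±S, 0), lambda at (0, −0.85 S) for hemisphere
semi-axis S = 4 mm); a user CSV overrides them.  Three landmarks are
midline, three left, three right; midline landmarks are shared by both
hemispheres during fitting.

## Registration

**Strategy ladder.**  Each hemisphere is fitted independently from its
own plus the midline landmarks, using the strategy the available count
allows:

- ≥ 3 usable landmarks → an exact three-point affine on a selected
  triple.  The default triple is (lateral tip, anterior midline point,
  lambda); `confidence` mode instead maximizes summed detector
  confidence over all non-degenerate triples, preferring the default on
  ties.  A triple is degenerate if its observed points *or* its
  atlas-side anchors are collinear (the three midline landmarks are
  exactly collinear in the atlas, so e.g. {top-center, bregma, lambda}
  is never used).  A degenerate triple degrades to a least-squares
  affine over all side landmarks, then to a similarity fit on the two
  most distant ones.
- exactly 2 → similarity transform (rotation + uniform scale +
  translation; closed form via the complex plane, no reflection).
- one hemisphere empty → the other hemisphere's transform; both empty →
  one whole-brain transform from every available landmark.

"Usable" means detector confidence ≥ a threshold (default 0.5,
configurable).  If the cut leaves fewer than two landmarks, the two
most-confident observations are used regardless, since an approximate
registration is more useful than none.

**Hemisphere split and seam.**  The brain midline passes through the
bregma and lambda observations when both exist, else vertically through
the best available midline landmark, else vertically through the mean
observed column.  During atlas-to-brain warping each output pixel is
assigned by exactly one hemisphere transform according to its side of
that midline, and label pixels sampled from the wrong atlas half are
discarded; the resulting one-to-two-pixel seam gaps are closed by a
single nearest-neighbor dilation pass, performed per side so the two
hemispheres never contaminate each other.  Brain-to-atlas applies each
hemisphere's inverse transform over its entire atlas half-plane, which
automatically carries any disconnected anterior mask component
(olfactory bulb) along with its hemisphere.

**Resampling.**  Intensity images are interpolated bilinearly, label and
mask images by nearest neighbor (labels must remain integral).

**Piecewise-affine and deformation fields.**  Sensory activation peaks
(≥ 3 matched control points) define a piecewise-affine map: a Delaunay
triangulation of the source points with one exact affine per triangle;
outside the convex hull the nearest triangle's affine (by centroid
distance) is extended, so the map is total.  Dense deformation fields
(2×H×W arrays of row/col displacements) are consumed, not estimated:
`out(p) = in(p + field(p))` with the same interpolation rules.

## Boundary segmentation and metrics

The Otsu baseline min-max scales the image to [0, 255], thresholds a
256-bin histogram at the between-class-variance maximizer
(scikit-image), then keeps the largest 8-connected component and fills
enclosed holes.  A constant image is an error.  Quality metrics follow
the standard definitions: area difference = 100 × |pred XOR truth| /
frame pixels (frame-normalized so values are comparable across crops);
SSIM in the Wang et al. form with an 11×11 Gaussian window (σ = 1.5,
k1 = 0.01, k2 = 0.03, dynamic range 255); PSNR = 10·log10(max²/MSE),
reported as +inf for identical inputs.  Mask pairs are compared as
0/255 images so MSE is on the squared 8-bit intensity scale.

Vessel masks flag pixels darker than their local mean (uniform filter of
odd block size, default 15) minus an offset (default 10).  Inpainting is
a fast-marching fill: hole pixels are visited in order of geodesic
distance from the known region (8-connected front, binary-heap
priority), each replaced by an inverse-square-distance weighted average
of known or already-filled pixels within a radius (default 3 px), with
every neighbor contribution extrapolated along its local image gradient
so smooth intensity ramps continue into the hole.  The weighted mean is
accumulated relative to the first neighbor value, which makes the fill
bit-exact on constant images.  Non-hole pixels are never modified.

## ROI extraction

One 3×3 dilation pass denoises the warped label image: background pixels
adjacent to a region take the smallest adjacent region ID (the
deterministic tie rule); labeled pixels never change.  Region contours
are the outer boundary of each connected component (subpixel marching
squares at level 0.5 on a padded binary image), oriented
counter-clockwise; holes are ignored.  The ROI center is the pole of
inaccessibility — the interior point farthest from the polygon edges —
found by quadtree refinement: cells over the bounding box are processed
in priority order of their potential maximum clearance
(center distance + half-diagonal) and subdivided until the best
potential is within the precision (default 0.5 px) of the best found;
the polygon centroid seeds the search.  Signed point-to-boundary
distances come from shapely.

Numbering method 1 assigns one ROI per region ID present under the mask
(one per connected component if the mask splits a region).  Method 2
renumbers spatially: within each hemisphere (ROI center column versus
the bregma column), ROIs sort by (column, row), except that any maximal
chain of centers whose successive columns differ by less than 5 px
(transitivity resolved by chaining) counts as vertically aligned and is
re-sorted top to bottom.  The result is independent of input order.

## Functional maps and motifs

ΔF/F is `(F − F0)/F0` with F0 the per-pixel mean over a baseline window
— the full recording for spontaneous data, the pre-stimulus window for
evoked data.  Non-positive F0 anywhere is an error naming the pixel
count (the fix is an intensity offset).  Stimulus-triggered averaging
collects (pre+post)-frame epochs; the sensory peak map is the per-pixel
maximum over frames strictly after the stimulus frame, the peak pixel
the argmax (ties resolve to the smallest row, then column), and the
activation centroid the intensity-weighted centroid of pixels at or
above 75 % of the peak.

**Convolutional NMF.**  The masked movie, reshaped to pixels × time, is
factorized as `X ≈ Σ_k W_k ∗ h_k` with K motifs of lag length L, by
multiplicative updates on W (N×K×L) and H (K×T).  An optional
cross-factor orthogonality penalty λ·‖(1−I)(W⊛X)S Hᵀ‖ (S a boxcar of
width 2L−1) discourages two factors from explaining the same data
within ±L frames; λ defaults to 0 and is exposed as a knob because an
appropriate weight is data-dependent.  Negative input entries are
clipped at zero with a warning.  Initialization is uniform random
(seeded); the squared reconstruction error is recorded every iteration
and is non-increasing in practice (the tests allow a 1e-6 relative
slack per step).  Typical problem sizes used by the tests and the
acceptance script: ~2000 masked pixels, T = 200–300 frames, L = 8,
K ≤ 3, 80–100 iterations, which keeps a factorization under ~5 s.

Motif images are per-motif maximum temporal projections, zeroed outside
the brain mask and min-max normalized to [0, 1] (all-zero motifs map to
zero, no division).  An MBFM is the pointwise maximum of a set of
normalized motif images.  Template construction averages each cluster's
"center motifs" — members whose mean correlation to the rest of their
cluster is at or above the median (quantile configurable) — and keeps
the n most common clusters (default 6).  Matching assigns each new
motif to its best-correlated template iff Pearson r ≥ a threshold
(default 0.5, configurable; ties go to the lower template index);
zero-variance images are left unassigned with a warning.  Correlations
are computed on masked pixels when a mask is given.

## Clustering

Motif images flatten to vectors (masked pixels).  The k-nearest-neighbor
sets (Euclidean, self excluded, default k = 15 truncated to n−1) are
tie-inclusive: every point at the k-th neighbor distance belongs to the
set, so duplicate points share identical neighborhoods and cluster
together rather than splitting on arbitrary tie-breaks.  Edges connect
points with overlapping neighbor sets, weighted by the Jaccard index of
the sets.  Louvain community detection (networkx, seeded) maximizes
modularity; labels are renumbered by descending community size.
Silhouette scores use Euclidean distances; singleton clusters score 0,
and a single-community partition has no silhouette (error).

## Evaluation statistics

Landmark error reports give per-landmark Euclidean distances in mm
(pixel distance × pixel pitch) over shared indices, with mean,
SEM = sd/√n, and RMSE (both aggregations are reported because either
may be wanted).  The midline angle is the unsigned acute angle between
a registered midline segment and the atlas vertical, in [0°, 90°].
Alignment point error measures the mm distance at two named midline
anchors — lambda and the anterior midline point in the bundled
geometry; users of real data supply their own mapping.  ROI centroids
for sensory-map comparisons are mask-pixel means, not poles of
inaccessibility.

## Synthetic phantoms: what they emulate and what they do not

A phantom frame is the bundled atlas geometry rendered as a two-level
image (bright cortex 160, background 16 on a 0–255 scale) with dark
quadratic-Bezier vessel curves (intensity ×0.45, default 4 vessels of
width 2) and additive Gaussian noise (default σ = 3).  Misalignment is
a similarity transform — rotation ±30°, scale 0.8–1.2, translation
±20 px by default — matching how acquisition-time variation is usually
modeled; shear and perspective are excluded.  Mock landmark detections
add isotropic Gaussian jitter and Bernoulli dropout (at least two
landmarks always survive) with confidence `exp(−d²/2σ²)` for jitter
displacement d.  Activity movies plant K motifs, each sweeping a
Gaussian-smoothed group of atlas regions over L frames, convolved with
random onset trains plus Gaussian noise, clipped at zero.

All generators are pure functions of their spec including the seed.
What they do **not** emulate: hemodynamic contamination and its
green-reflectance correction, photon shot noise (noise is additive
Gaussian), realistic vascular trees, non-rigid tissue deformation, and
detector failure modes beyond jitter/dropout.  Passing tests therefore
demonstrate the correctness and stability of the computational stages
under controlled geometry, not detection accuracy on real fluorescence
images — landmark detection and boundary segmentation on real data are
pluggable providers outside this package's scope (trained-network
inference is a plug-in point, not implemented here).

## Degenerate inputs and tie rules (summary)

- Collinearity test for triples: triangle area below 1e-9 × squared
  point-spread scale.
- Flat sensory epoch: peak pixel (0, 0) by the row-then-column tie rule.
- Dilation ties: lower region ID wins.
- Equal-confidence triples: the prescribed default triple wins.
- Motif-template correlation ties: lower template index wins.
- Zero-area polygons, constant images for Otsu, holes covering a whole
  image, empty graphs, single-cluster silhouettes: errors, not guesses.

## Known limitations

- The seam reconciliation at the midline (one dilation pass per side) is
  a design choice; other reconstructions of the one-to-two-pixel gap are
  defensible.
- Multiplicative-update convolutional NMF has no formal monotonicity
  guarantee with the penalty active; with λ = 0 the objective decreases
  monotonically in all tested conditions.
- The quadtree pole-of-inaccessibility is exact only to its precision
  parameter (default 0.5 px).
- Louvain is a greedy local optimizer; partitions depend on the seed for
  near-degenerate graphs.
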