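# Methods

## The morphological gradient

Let `M` be a triangle mesh (vertex positions in mm) and `f : M -> [0, 1]`
a scoring function — any deterministic map from a surface to a class
belief, e.g. a classifier's P(female) for a cranial surface. The
morphological gradient asks a counterfactual question at every vertex:
*if the surface here were pushed outward, how would the score change?*

The probe is a smooth local bump. With falloff

    sigma(r; R) = max{0, (R - r) / R}

the transformation centered at vertex `p0` moves every vertex `p` along
its own normal `N(p)` of the *undeformed* mesh:

    T(p; p0, delta) = p + delta * sigma(||p - p0||) * N(p)

and the gradient at `p0` is the score difference

    grad_{p0; delta} f(M) = f[T(M; p0, delta)] - f[M].

`delta > 0` is a bump, `delta < 0` a dent. Because `f` is in general
nonlinear, the dent map is a separate evaluation with negative `delta`,
never the negated bump map. The linear falloff is used because it
produces natural-looking, surgically plausible bumps and is trivial to
evaluate; any monotone falloff with `sigma(0) = 1` and compact support
would fit the same framework.

Distances inside `sigma` are Euclidean by default (the literal reading of
`||p - p0||`); a geodesic mode computes graph shortest-path distances
instead, which prevents a bump on one sheet of a thin double-walled
structure (outer vs inner skull table) from dragging the spatially close
but geodesically distant other sheet. Normals are those of the input
mesh and are not recomputed during the deformation.

### Sparsification: geodesic point cover

Dense evaluation costs one full scorer call per vertex. Assuming the
gradient varies continuously over the surface, it is evaluated only on a
vertex point cover `C(M; rho)`: a subset such that every vertex lies
within graph-geodesic distance `rho` of the cover. The cover is built
greedily in breadth-first vertex order from vertex 0 (per connected
component): a vertex joins iff no existing cover vertex is within `rho`.
This yields both coverage (< `rho` to the cover everywhere) and packing
(no two cover vertices within `rho`), and is deterministic. Geodesics are
approximated by Dijkstra shortest paths on the edge graph with Euclidean
edge weights; a hop-count mode (plain BFS distance) is available and
coincides with the weighted mode on uniform meshes.

Cover values are spread to all vertices by inverse-graph-distance
weighting (exponent 1) over the 3 nearest cover vertices — exact at
cover vertices, bounded by the range of the cover values, and cheap.
The total scorer budget for one field is exactly `|cover| + 1` calls
(one baseline), which the tests audit with an instrumented scorer.

Choosing `rho`: the field inherits the spatial scale of the probe, so
structure finer than the falloff radius `R` cannot exist in it.
`rho <~ R` resolves the field faithfully; `rho` much beyond `1.5 R`
undersamples sign boundaries. On very coarse meshes (edge length
comparable to `R`) the cover is necessarily close to dense; the
162-vertex benchmark proxy uses `rho = 24 mm` with `R = 20 mm` (cover of
103, 36% of calls saved, 94% sign agreement with dense evaluation).

### Symmetrization

A scorer trained on finite data need not be mirror-symmetric even when
the anatomy is. `symmetrized_field` computes the field on the mesh and on
its sagittal mirror image (winding flipped so normals stay outward),
carries the mirrored values back through nearest-vertex correspondence,
and averages. For an exactly symmetric mesh and a symmetric scorer this
is a no-op up to interpolation error.

### Heat-map output

Fields export as binary little-endian PLY with per-vertex RGB from a
diverging map (red = positive = outward push raises P(female), blue =
negative, near-white at zero) plus the raw value as a float vertex
property `gradient`, so no information is lost to quantization. The map
is hand-specified with a strictly monotone red channel; stock diverging
colormaps saturate at the ends, which destroys rank information in the
rendered color.

## Supporting pipeline

**STL I/O.** STL stores an unindexed triangle soup; reading welds
duplicates by exact bitwise coordinate equality (STL exporters emit
identical bits for shared vertices; an epsilon weld risks merging
genuinely close anatomy — a tolerance flag exists for meshes that need
it). Winding is preserved; file normals are ignored and recomputed from
winding. Binary files are validated against the 84 + 50·n size identity
before parsing, so truncation errors name the offending byte offset.

**Augmentation.** Random rotation (uniform axis, angle uniform within
±10° about the centroid — axis-angle, not composed Euler angles, so the
bound is exact), random per-axis shift within ±5% of the bounding-box
extent, and sagittal mirroring with probability 1/2 including the winding
flip. One `numpy` generator threads through all three; everything is
reproducible from one seed. These are the standard rigid augmentations
for anatomy whose pose in the scanner is only approximately standardized.

**Voxelization.** A mesh becomes a dense binary volume on a cubical grid
spanning the largest bounding-box extent. Occupancy is conservative: a
voxel is occupied iff its cube intersects a triangle, decided by the
13-axis separating-axis test. Conservative voxelization guarantees the
shell of a watertight mesh is gap-free at any resolution, so
`fill_solid` (exterior flood fill from the grid boundary; unreached empty
space becomes interior) can produce solid bone-mask-like volumes.
Geometry exactly on an interior voxel-face plane belongs to the lower
voxel; geometry on the outermost grid planes is clamped inward. Both
hollow shells and solid fills are provided since either convention is
defensible for CT-derived bone.

**Evaluation.** Stratified k-fold: shuffle within class, deal round-robin
with a per-class starting offset so overall fold sizes stay within one.
AUC is the Mann–Whitney pair statistic (computed via scikit-learn,
cross-checked in tests against exhaustive pair enumeration and
trapezoidal ROC integration). AUC is preferred over thresholded accuracy
because scorer outputs can carry an arbitrary fluctuating bias toward 0
or 1 while the ranking stays informative; per-fold values are always
reported individually because small test folds make the spread large.

## Synthetic skull proxies

Real cranial CT collections are private, so the benchmark is a generator
with known ground truth. A subdivided icosphere is scaled to a head-like
ellipsoid (semi-axes 0.8 : 1.0 : 0.9 · base radius; x lateral, y
anterior, z vertical) and given three interpretable dimorphic features:

* **size** — `base_radius`; male 95 ± 4 mm vs female 90 ± 4 mm;
* **brow ridge** — a raised-cosine radial bump (angular radius 0.45 rad)
  centered on the upper-front direction (0, 0.8, 0.6)/|·|, height
  `brow_amplitude`: male 3 ± 1 mm vs female 1 ± 1 mm (clamped at 0),
  scaled by `sex_effect`;
* **jaw width** — lateral coordinates of the lower third scaled by
  `jaw_width_factor` (smoothstep ramp below z = −1/3 on the unit
  sphere): male 1.06 ± 0.02 vs female 1.00 ± 0.02;

plus i.i.d. Gaussian radial noise (default SD 0.5 mm, the scale of
segmentation jitter). The distribution parameters are invented but chosen
to reproduce the statistical regime of real cranial data: strongly
bimodal yet overlapping, with size alone giving AUC ≈ 0.8 and all
features together ≈ 0.93 at default settings (≈ 0.98 at `sex_effect`
10, ≈ 0.5 when all class differences are switched off). Populations of
100 at icosphere subdivision 2 (162 vertices) keep the full
cross-validation suite in seconds; gradient benchmarks use subdivision 3
(642 vertices).

What the generator does **not** emulate: real cranial anatomy (no
mandible, orbits, or inner table), partial-scan truncation, pose
variability beyond what augmentation adds, and age/ancestry covariates.
Passing tests demonstrate that the gradient method recovers known
localized signal under realistic statistical overlap — not that any
particular trained model is anatomically right.

### The analytic scorer

Gradient maps need a scorer with known ground truth, so the built-in
scorer is analytic rather than trained (a trained-model adapter is just a
registered callable). It measures three geometric features from the mesh
alone and combines them with a fixed logistic model:

    P(female) = expit(44.85 - 1.0·brow - 20.0·jaw - 0.3·size)

* pose is normalized by PCA of the vertex positions (the three ellipsoid
  semi-axes are well separated, so the axes are stable). Axis *signs* are
  ambiguous; third-moment skews are fragile near symmetry, so the
  orientation is chosen as the sign combination under which the brow
  patch protrudes most — i.e. the brow is defined as the most protruding
  of the four candidate patches — with skew as tie-break;
* **brow** (mm): mean radial excess over the best-fit axis-aligned
  ellipsoid (radii from second moments, `a = sqrt(3·E[x²])`) inside the
  brow patch;
* **jaw** (ratio): lateral half-width of the lower third relative to the
  whole, each width an order-8 power mean of |lateral coordinate|;
* **size** (mm): order-8 power mean of vertex radii — a smooth surrogate
  for the bounding-sphere radius.

Power means matter: hard maxima would hang the entire size/width
sensitivity on single extreme vertices, so a probe bump landing there
would swamp the map with spurious saliency. The order-8 mean tracks the
extreme (within a few percent) while spreading sensitivity over many
vertices. Weights are per-mm (brow, size) and per-unit-ratio (jaw),
scaled so each feature contributes on the order of one logit across the
class gap; the bias centers the mid-population shape (radius 92.5 mm,
brow 2 mm, jaw 1.03) near score 0.5. All features are masculine when
large, hence the negative signs; by construction the scorer is invariant
under rigid motion to ~1e-3.

On a noise-free masculine proxy the resulting gradient map is negative
and concentrated in the brow patch (pushing the brow outward makes the
shape more male-like), with mean |gradient| inside the patch an order of
magnitude above the outside mean — the ground-truth localization the
whole method is judged by.

## Numerical choices and edge cases

* Tie-breaks everywhere are by lowest vertex index (BFS order, k-nearest
  selection, interpolation neighbor choice).
* Degenerate (zero-area) faces contribute nothing to vertex normals; a
  vertex whose whole star is degenerate is an error, isolated vertices
  get a zero normal.
* Disconnected meshes are covered per connected component; vertices
  unreachable from any cover vertex interpolate to NaN and are zeroed in
  the assembled field.
* The scorer contract (output in [0, 1], finite) is enforced at every
  call; violations raise instead of propagating silently.
* Zero-extent axes get zero shift in augmentation; mirroring always
  flips winding so signed volume is preserved.
* Voxelization resolution must be ≥ 2; a zero-extent mesh is rejected.
  Leaky shells (not closed at grid resolution) fill less and warn when no
  interior is found at all.

## Known limitations

* Graph geodesics overestimate true surface geodesics on coarse meshes
  (path zig-zag); exact polyhedral geodesics are out of scope.
* The gradient is a finite difference at one probe scale `(delta, R)`;
  features smaller than `R` are blurred, and strongly nonlinear scorers
  can give bump and dent maps that disagree in magnitude.
* Interpolation cannot reconstruct sign structure finer than the cover
  spacing; on meshes whose edge length is comparable to `R`, meaningful
  sparsification saves at most ~40% of scorer calls.
* The synthetic benchmark validates the machinery, not anatomical truth;
  conclusions about real crania require a trained scorer and real data.
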