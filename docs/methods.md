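# Methods

## Scope and model

The package segments individual plant leaves from a single aligned
RGB-D frame. It assumes (i) leaves sit well in front of the background
(decimetres of separation), (ii) the depth image over a leaf surface is
smooth while leaf boundaries — including boundaries between overlapping
leaves — produce depth steps of at least a few millimetres, and
(iii) foliage is distinguishably green against a non-green background.
Nothing is assumed about leaf shape: the boundary model is a free-form
closed contour, not a template.

## Depth mean shift

Clustering runs on the depth raster in the joint spatial/range domain
with a flat (uniform) kernel: for pixel i, the mode estimate starts at
its own depth and is repeatedly replaced by the mean depth of the valid
pixels inside the fixed (2·sp+1)² spatial window whose depth lies
within sr of the current estimate, until the shift is ≤ eps (1e−3) or
max_iter (50) is reached. Pixels whose converged modes differ by ≤ sr
and are 4-connected share a segment; connectivity is applied after mode
grouping so equal-depth plateaus that are spatially separate become
separate segments. Zero-depth (unmeasured) pixels are excluded from all
window averages and never labelled — sensor dropout must not drag modes
toward zero.

Two details are configuration rather than doctrine, because the
method's formulation leaves them open:

* **depth_norm** — by default valid depths are min–max scaled to 0–255
  (`scale_8bit`) so that sr = 6 keeps its conventional gray-level
  meaning; `raw_mm` clusters metric depth directly.
* **min_region_px** (default 50) — segments smaller than this are
  folded into the adjacent segment with the nearest mean mode depth.
  This removes noise speckle without punching holes into leaves; it
  deliberately ignores the 2·sr depth-band bound that pure mode
  grouping obeys.

The production implementation vectorizes the iteration with cumulative
windowed depth histograms (exact, since the window contents are fixed
and integer-valued — only the mode estimate moves) and processes row
strips to bound memory. The test suite re-derives the same recurrence
with a literal per-pixel loop and requires identical partitions.

Vegetation filtering keeps a segment when its mean color passes either
the green-dominance rule (mean G ≥ g_min = 100 and mean G ≥
max(mean R, mean B) + 20) or, in `excess_green` mode, mean(2G − R − B)
≥ 40. The thresholds were chosen on the synthetic scenes; on real
imagery they are site-specific configuration, not constants of the
method.

## Edge map and gradient vector flow

The filtered depth is presmoothed (Gaussian, σ = 1.5 px), its gradient
magnitude is computed by central differences, saturated at grad_clip
(default 6 mm/px) and scaled to [0, 1]. Saturation is essential: the
leaf/background step is ~600 mm while the inter-leaf step is ~30 mm;
without clipping, normalization would erase the inter-leaf boundary
that occlusion splitting depends on. Dropout holes interior to the
foreground are filled from their nearest valid pixel before smoothing
so they do not read as boundaries, and the map is zeroed only outside a
small dilation of the foreground: zeroing at the exact silhouette would
amputate the rim ridge's outer slope and bias the contour equilibrium
inward by ~2–3 px (measured on noiseless single-leaf scenes).

GVF diffuses ∇f by explicit iterations of
u ← u + dt·(µ∇²u − |∇f|²(u − f_x)) (and likewise v), initialized at
(u, v) = ∇f. Defaults µ = 0.2, n_iter = 320, dt = 0.75. The scheme is
stable for dt ≤ 1/(4µ) and, for edge maps in [0, 1] (so |∇f|² ≤ ½), is
a strict descent of the discrete GVF energy for dt ≤ 1/(4µ + ½); the
default sits inside the descent regime and the energy decrease is
asserted every iteration in tests. Gradients and the 5-point Laplacian
use replicated borders with pairwise-grouped sums, which makes the
field exactly (bitwise) equivariant under 90° image rotation — the
anchor for the symmetry tests.

## Centers of divergence

The scatter-point rule marks p(i, j) when the field's x-component is
non-decreasing toward the right neighbour with signs not both strictly
positive/negative, and analogously downward for the y-component; the
intersection of the two sets contains the field sources. Pixels where
the field magnitude at p and both forward neighbours is below
min_field_mag (1e−6) are ignored, otherwise an exactly-zero background
field would satisfy the ≤-tests everywhere. The sign tests are applied
to per-pixel field values; averaging each 2×2 block first is a possible
alternative reading of the construction that we did not adopt.

Pruning is proximity *merging*: candidates are scanned in raster order,
each joining the first cluster whose seed lies within dist_threshold
(default 15 px at 640 × 480) and otherwise seeding a new cluster; each
cluster is replaced by its centroid, rounded half-even per coordinate
for cross-platform determinism. The inverse reading
(remove one of any pair *farther* apart than the threshold) would keep
duplicates and discard well-separated centers — the opposite of
limiting model count — and is retained only behind
`cod.prune_mode: literal` for comparison. One circle of radius
init_radius (5 px, 40 vertices) is seeded per retained center, clamped
to the image bounds.

## Active contours

Each snake iterates x ← (A + γI)⁻¹(γx + F), where A is the circulant
pentadiagonal operator assembled from elasticity α = 0.1 and rigidity
β = 0.1, γ = 1 is the viscosity step, and F is the external force at
the vertices (bilinear field samples). Vertices are redistributed to
2 px arc-length spacing every 10 iterations; evolution stops at
n_iter = 600 or when the mean per-step displacement falls below
0.05 px. A contour that collapses below 8 vertices is discarded with a
warning.

Two choices depart from the plain GVF snake and are this package's own:

* **Tapered force normalization** — F uses the field direction scaled
  by |v|/(|v| + 0.15·max|v|): near-unit speed away from boundaries,
  tapering to zero at the field reversal, so the contour settles on the
  edge ridge instead of oscillating across it at amplitude κ.
* **Default balloon term** (0.5, vs κ = 2) — with a bounded diffusion
  budget the GVF magnitude ~40 px inside a large leaf is ~1e−3, where
  elasticity would collapse the seed circle. A small outward pressure
  carries the contour through the flat interior and is easily
  overpowered by the edge force at the rim. On the synthetic benchmark
  it eliminates large-leaf failures (83–90% → 95%+ correct) without
  raising the unseparated rate. Set `snake.balloon: 0` to recover the
  pure-GVF behaviour.

There is no Lyapunov functional for a GVF snake (the external force is
not a potential gradient), so "snake energy" is not asserted
end-to-end; instead tests verify that the zero-force implicit step
monotonically decreases the internal bending energy, and that on a
circular edge ridge the contour converges to the rim within 1 px and
stays there when re-initialized at its own equilibrium.

Final contours are rasterized (even–odd interior), intersected with the
valid foreground mask, and contested pixels are assigned to the contour
whose seed center is nearest (ties to the lower contour index), making
the instance masks a partition of the claimed foreground. Segments are
never merged post hoc: if two seeds land in one leaf, the resulting
over-segmentation is measured, not hidden.

## Synthetic scenes

The generator emulates a fixed greenhouse rig (~1 m working distance):
leaves are perturbed superellipses (random axis ratio 0.55–0.9,
exponent 1.7–3, rotation, ≤ 8% radial boundary modulation) of 40–90 px
extent on depth planes tilted ≤ 0.15 mm/px within a 700–1000 mm band;
the background plane sits at 1600 mm. A configurable fraction of leaves
(default 75%, typical of a dense canopy where most
leaves overlap a neighbour) is placed in occlusion groups: the occluding leaf
overlaps 20–60% of its partner's silhouette and sits nearer the camera
by at least inter_leaf_offset_mm (default 30; a stress value of 5 and
the degenerate 0 emulate the tiny-depth-difference failure mode).
Depth gets i.i.d. Gaussian noise (σ = 3 mm) on valid pixels plus
dropout (p = 0.3) within 2 px of any ≥ 15 mm depth step — a
simplification of structured-light disparity artefacts that preserves
what the algorithm relies on: smooth surfaces, stepped boundaries,
unreliable edges. Ground truth records each leaf's pre-occlusion
silhouette, its visible (z-buffered, valid-depth) mask, and an occluded
flag (silhouette intersects another).

What the generator does **not** model — specular sunlight, leaf
venation and wrinkles, stems, side-view leaves at grazing angles,
correlated (disparity-quantized) depth noise — bounds what the
benchmark shows: passing it demonstrates the pipeline's mechanics
(background separation, seed placement, occlusion splitting,
evaluation bookkeeping) under controlled difficulty, not field
performance on real crops.

## Evaluation

A ground-truth leaf (≥ 100 visible px; smaller leaves are excluded, as
leaves near the sensor's resolution limit cannot be judged) is
classified in this order: *failure* if no prediction covers ≥ 20% of
it; *unseparated* if its best-IoU prediction also covers ≥ 20% of an
occluding partner; *correct* if that best IoU ≥ 0.5; *oversegmented*
if several predictions each cover ≥ 20%; otherwise *failure*. The
order makes the four categories mutually exclusive and exhaustive, so
per-stratum counts always sum to the stratum total. Rates are
100·count/total rounded half-up to two decimals. The IoU and coverage
thresholds replace a human judgment call with a fixed objective rule;
they were chosen so the four categories discriminate the error modes
the method is known for (over-segmentation on wrinkled surfaces,
unseparated occlusions at tiny depth offsets).

## Problem sizes and determinism

The benchmark in `scripts/acceptance.py` uses 20 scenes at 640 × 480
with 8 leaves each (~160 scored leaves); the unit suite exercises the
same code paths on 320 × 240 scenes and ≤ 64 × 64 oracle fields. Every
stage is deterministic; the only randomness is the scene seed, and
batch scene k uses seed base + k.

## Known limitations

* Mean-shift segment boundaries are depth-driven; a leaf whose depth
  band overlaps the background's (beyond ~sr after normalization) will
  not separate.
* One seed per divergence-center cluster: two seeds in one leaf split
  it (counted as over-segmentation); zero seeds in a small crescent of
  a heavily occluded leaf lose it (counted as failure).
* The balloon term assumes leaf interiors are edge-free after
  presmoothing; strong interior depth texture (deep wrinkles) would be
  fenced off and read as over-segmentation.
* The evaluation thresholds (IoU 0.5, coverage 0.2) are conventions;
  reported rates move with them and are comparable only at fixed
  settings.
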