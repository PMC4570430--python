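# leafseg3d

3D instance segmentation of individual plant leaves from aligned RGB-D
frames, for greenhouse monitoring and agricultural automation. Given an
8-bit color image and a 16-bit depth image (millimetres, Kinect-style,
640 × 480), the pipeline extracts every leaf as its own instance mask —
including leaves that partially occlude each other — and scores results
against ground truth with occlusion-aware outcome categories.

Color-only leaf segmentation struggles in the field: soil and foliage
share hues, illumination varies, and occluded leaf boundaries are often
invisible in RGB. Depth fixes both problems: leaves sit well in front of
the background, and even a few millimetres of separation between
overlapping leaves leaves a visible step in the depth image.

## Pipeline

1. **Background removal** — mean shift clustering of the depth image in
   the joint spatial/range domain. Each pixel iterates a depth mode
   estimate *y* ← mean{ d(q) : q in the (2·sp+1)² spatial window,
   |d(q) − y| ≤ sr } until the shift is below a threshold; pixels whose
   converged modes agree within sr and are spatially connected form one
   segment (defaults sp = 12 px, sr = 6 gray levels). Segments are kept
   only if their mean color passes a green-vegetation rule
   (G̅ ≥ g_min and G̅ ≥ max(R̅, B̅) + margin, or an excess-green
   threshold 2G̅ − R̅ − B̅).
2. **Gradient vector flow (GVF)** — the filtered depth image is turned
   into an edge map f ∈ [0, 1] (presmoothed gradient magnitude,
   saturated so a 30 mm inter-leaf step registers as strongly as the
   600 mm leaf/background step), and f's gradient is diffused into a
   smooth vector field **v**(i, j) = (x(i, j), y(i, j)) by minimizing
   µ·|∇**v**|² + |∇f|²·|**v** − ∇f|².
3. **Center-of-divergence (CoD) initialization** — a pixel p(i, j) is a
   scatter-point candidate when the field's x-component crosses zero
   upward toward its right neighbour, sign-tested as
   x(i,j) ≤ x(i+1,j) with |sign(x(i,j)) + sign(x(i+1,j))| ≤ 1, and
   analogously in y toward the neighbour below. Candidates satisfying
   both tests are field sources — one small cluster per (visible part
   of a) leaf — and are thinned so no two retained centers lie within a
   distance threshold. One small circle is seeded per center.
4. **Active contours** — each circle evolves as a closed snake:
   implicit elasticity/rigidity (α, β) plus the GVF as external force
   (with a small outward balloon term), inflating from the seed to the
   leaf rim or to the inter-leaf depth boundary. Contours are
   rasterized, contested pixels go to the nearest seed, and the result
   is one mask per leaf.
5. **Evaluation** — every ground-truth leaf is classified as
   *correct* (IoU above threshold), *failure* (not detected),
   *unseparated* (its match also swallows an occluding partner) or
   *over-segmented* (covered only by partial pieces), stratified into
   single vs. occluded leaves, with percentage rates per stratum.

A seeded synthetic scene generator replaces the camera: superellipse
leaves on tilted depth planes, constructed occlusion pairs with a
configurable depth offset, Gaussian depth noise and edge dropout, green
foliage over a brown floor, and exact per-leaf ground truth.

## Worked example

```bash
leafseg3d simulate --n-scenes 1 --seed 0 --n-leaves 4 --size 320 240 --out scenes
leafseg3d segment --color scenes/color_0000.png --depth scenes/depth_0000.png --out seg
```

prints `4 leaf segments -> seg` and writes a 16-bit instance label map,
an overlay PNG (yellow = final leaf boundaries, green = initialization
circles) and a per-segment table:

```
id,seed_i,seed_j,area_px
1,210,65,2368
2,52,102,2875
3,206,105,2269
4,224,132,1346
```

Each row is one leaf: the seed is the divergence center that initialized
its contour, and `area_px` its final visible mask area. The full loop

```bash
leafseg3d end-to-end --n-scenes 2 --seed 0 --n-leaves 4 --size 320 240 --out e2e
```

prints `overall segmentation rate: 100.00% (8/8 leaves)` — all eight
ground-truth leaves across the two scenes were recovered with IoU ≥ 0.5
and no occlusion left unsplit.

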