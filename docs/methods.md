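# Methods

`veinmorph` post-processes binary leaf-vein segmentation masks into
physical measurements: it repairs occlusion gaps, extracts a burr-reduced
skeleton, and reports vein length and angle-corrected width in mm via a
scale bar. This note records the models, the numerical choices, and what
the synthetic validation does and does not show.

## Convex hull-scan repair

Segmentation of a creased leaf often fragments the main vein. Repair is
purely geometric:

1. **Gap detection.** Connected components (8-connectivity) are split
   into fragments (area ≥ `min_fragment_px`, default 25) and noise
   (smaller). For every fragment pair whose minimal boundary-to-boundary
   Euclidean distance is ≤ `max_gap_px` (default 40), the two nearest
   boundary points define a gap axis.
2. **Point collection.** Boundary pixels of both fragments are collected
   from a slab aligned with the gap axis: within the gap span (±
   `window_margin_px`, default 10, along the axis) and the full fragment
   cross-section across it. Noise components contribute only from the
   narrow corridor directly between the fragments. The slab reading —
   rather than an axis-aligned box around the two nearest points — is
   deliberate: a box narrower than the band cross-section leaves notches
   at the repair seams, and each notch forks the skeleton into spurious
   branches. Absorbing *outlying* noise specks, conversely, would bulge
   the repair; specks far from the gap are left to the opening stage.
3. **Hull and fill.** A Graham scan (anchor at minimal x, ties by minimal
   y; counterclockwise polar order, nearest first on ties; collinear
   candidates popped) produces the minimal convex polygon over the point
   set. Its edges are rasterized with Bresenham's algorithm and each row
   is filled between its extreme edge pixels (exact for convex
   polygons). The filled polygon is OR-ed into the mask.

Repair is extensive (output ⊇ input), never increases the component
count, and is idempotent once all gaps are closed.

## F-3MS refinement

F-3MS = **F**lood fill + **M**orphologyEx (opening) + **M**edian blur +
**M**orphological **S**keleton. Pinholes and contour roughness seed short
false skeleton branches (burrs) that inflate the pixel-count length; the
pipeline removes the seeds rather than pruning branches:

1. **Hole closing** by the three-step flood-fill construction: flood the
   background from all border pixels (4-connectivity), invert, OR with
   the original. Exactly the interior cavities flip to foreground.
2. **Opening** with a square element (default 3×3) removes isolated dots.
3. **Grayscale** conversion of the red-on-black render by the luma
   weights 0.299/0.587/0.114, rounded half away from zero.
4. **Median filtering** (default 5×5, edge replication at borders)
   smooths the contour. 5×5 is the default because it gives the best
   joint length/width recovery on rough-contoured bands; 3×3 and 7×7 are
   available through `F3msConfig`.
5. **Otsu binarization**: the threshold k maximizes the between-class
   variance w₀w₁(u₀−u₁)², ties to the smallest k, foreground = gray > k.
   A constant image yields a warning and an empty mask.
6. **Morphological skeleton** (Lantuéjoul): S(A) = ⋃ₖ [(A ⊖ kB) −
   (A ⊖ kB)∘B] with a 3×3 cross (default) or square element, iterated
   until the erosion empties. The residues satisfy the exact
   reconstruction identity A = ⋃ₖ (Sₖ ⊕ kB), which the tests verify on
   every mask they touch.

**Unit-width reduction.** The raw residue union is exactly 2 px thick
wherever the local shape width is even (the erosion of a 2-row band by a
3×3 element is empty, so the entire 2-row band survives as a residue) —
which would double the pixel-count length of an even-thickness band
(measured: 818 residue pixels for a 400 px band). By default the pipeline
therefore reduces the residue union to unit thickness with hit-or-miss
morphological thinning and drops isolated single-pixel residue dots (shed
by convex corners such as rounded vein caps; they carry no centerline
information). `unit_width=False` restores the raw union. This is a
reduction of the morphological-skeleton residue, not a thinning of the
shape, and no branch/spur pruning is performed anywhere.

## Length and width measurement

**Length** is the number of foreground skeleton pixels times the scale
bar (mm/pixel), every pixel counted once with no √2 weighting of diagonal
steps — e.g. a 461.625 px group mean at 0.2645 mm/px is 122.0998 mm. The
pixel-count rule is only meaningful when the vein runs along the grid
axis, so `measure_vein` rotates the cleaned mask to horizontal (principal
axis of the skeleton pixel cloud, nearest-neighbor resampling to stay
binary) and recomputes the skeleton there; counting in the tilted frame
would undercount by up to cos 30° ≈ 13 %. The rotation staircase is
median-smoothed away before the final skeleton (staircase bumps seed
burrs), while the width contour is taken from the *un*-smoothed rotation,
because median smoothing shaves the band edge and biases the separation
low (measured −1.5 % vs −0.3 % mean width error).

**Width** uses the angle-corrected geometric model. Per column x of the
oriented vein, the upper/lower contour rows u(x) ≤ v(x) (contour = binary
boundary operator: foreground pixels with a background 4-neighbor, which
is what an edge detector degenerates to on binary input) give the
half-separation (v−u+1)/2 — the +1 counts the inclusive pixel extent, as
a band of thickness T spans exactly T rows. The skeleton inclination θ at
each column converts the vertical half-separation into the perpendicular
true width:

    w(x) = (v(x) − u(x) + 1)/2 · cos θ(x),
    cos θᵢ = Δx / √(Δx² + Δo²)   (central differences of the ordinate)

Two ordinate conventions are implemented. `midline` (default) uses the
mean skeleton row per column, under which a band tilted by φ gets
cos θ ≈ cos φ and the 1/cos φ inflation of the vertical separation
cancels. `half_separation` uses the half-separation sequence itself as
ordinate — the literal sequence-model reading — under which a tilted
constant-width band has a constant ordinate, cos θ = 1, and width is
overestimated by 1/cos φ; it is kept for fidelity. The ordinate is
smoothed with a 5-column moving average before differencing because a
raster skeleton steps in whole rows and differencing the raw staircase
biases cos θ low.

The reported width is the half-separation-based quantity (≈ half the
anatomical band thickness), matching the magnitude convention of the
measurement protocol this package follows; `full_width=True` doubles it.

Multi-pixel skeleton columns are reduced to their mean row. Reported
errors can be summarized either as |actual − measured| of group means or
as mean absolute per-image error; the CLI reports the raw measurements
and leaves aggregation to the caller.

## Segmentation-network contract

The intended upstream segmenter is MobileNetV2 feeding a DeepLabV3+
head. `segnet.build_model` encodes the wiring as a shape calculus: a
stem convolution (stride 2, 32 ch) plus the 17-block inverted-residual
sequence (expansion/channels/repeats/stride = (1,16,1,1), (6,24,2,2),
(6,32,3,2), (6,64,4,2), (6,96,3,1), (6,160,3,2), (6,320,1,1)), truncated
at the 320-channel stage. When the cumulative stride would exceed the
configured output stride (8 or 16), further stride-2 blocks run stride 1
with doubled (atrous) dilation. At 512×512 input and output stride 16 the
deepest map is 32×32×320 and the stride-4 shallow skip is 128×128×24.
ASPP (rates 6/12/18 at stride 16, 12/24/36 at 8; five branches, 256 ch)
feeds a decoder that upsamples ×4, concatenates with the skip projected
to 48 ch, refines with two 3×3 stages and upsamples ×4 twice. The tensor
arithmetic itself belongs to a deep-learning framework and is out of
scope; the shape contract is what downstream wiring and the tests need.

Also in `segnet`:

* `conv_costs` — the depthwise-separable cost model: std = DK²·M·DF²·N,
  dsc = DK²·M·DF² + M·N·DF², ratio 1/N + 1/DK² (≈ 1/9 for 3×3 kernels);
* `relu6` — min(max(0,x),6);
* `ConfusionMatrix`, `miou`, `mpa` — per-class counts p(truth, pred),
  MIoU = mean TP/(TP+FP+FN), mPA = mean per-class recall TP/(TP+FN);
  classes absent from the relevant denominator are excluded from the
  mean. (A variant definition treats per-class accuracy as
  (TP+TN)/total; on symmetric binary fixtures the two coincide.)
* `adam_step` — bias-corrected Adam exactly as the standard recurrence;
  `TrainConfig` carries the reference schedule (100 epochs, 50 frozen at
  batch 8 then unfrozen at batch 4, lr 1e-3, cosine decay, β₁ 0.9,
  β₂ 0.99, weight decay 5e-4, dropout 0.5; the step-decay γ 0.94 is
  stored but unused under the cosine scheduler).
* `PixelSegmenter` — a deliberately small numpy per-pixel logistic
  segmenter (one 3×3 kernel per channel feeding a linear classifier)
  whose only job is to exercise the two-phase frozen/unfrozen schedule,
  the cosine learning-rate curve and the Adam recurrence end to end; its
  gradients are verified against finite differences.

## Synthetic phantoms

A phantom is a capsule: all pixels within T/2 of a centerline polyline
(strict `<`, with the centerline shifted down half a pixel when T is
even so a horizontal band covers exactly T rows for either parity). The
stored truth — centerline arc length and thickness — is exact by
construction. Degradation emulates segmentation failure modes: transverse
occlusion slabs perpendicular to the local centerline direction (gap
count/length configurable), 1–2 px interior pinholes kept ≥ 5 px apart so
each is a distinct cavity, and isolated background specks (removable by a
3×3 opening). All randomness flows from the single integer seed in the
spec; identical specs are bit-identical.

Validation conditions mirror the measurement protocol: straight bands of
arc length 300–500 px, thickness 12–24 px, tilts 0–30°, two 8 px gaps and
five pinholes, measured end to end against the stored truth (length
within 7 %, midline width within 5 % of T/2). The capsule's rounded caps
extend the skeleton by roughly T/2 at each extremity, so the pixel count
carries a small +T/L bias that the length tolerance absorbs; this is a
property of capsule phantoms, not of tapering real veins. What the
phantoms do **not** emulate: photometric texture, taper, branching
secondary veins, curvature beyond a shallow arc, and annotation noise —
so passing recovery tests demonstrates the geometry pipeline is
self-consistent, not that a particular segmentation network is accurate
on real leaves.

The augmentation ops (scale, translate, mirror, rotate; nearest-neighbor
for masks, exact `rot90` for quarter turns) and the PASCAL-VOC dataset
writer (JPEGImages/, SegmentationClass/, ImageSets/Segmentation with a
seeded largest-remainder 8:1:1 split) produce training fixtures in the
layout the network tooling expects.

## Degenerate inputs and ties

* Otsu on a constant image: warning, threshold at that level, empty mask.
* Graham scan on collinear points: the two extreme endpoints.
* `fill_polygon` on a 2-vertex hull: the Bresenham segment.
* Contour columns with fewer than two contour pixels are omitted from
  u/v; `cos_theta_profile` needs ≥ 3 points and copies endpoint values
  from the nearest interior.
* Division-free metric policy: classes with empty union (MIoU) or empty
  truth (mPA) are skipped from the mean.
* All kernel sides must be odd; configuration dataclasses validate on
  construction.

## Problem sizes

Tests and the acceptance script run on phantoms of a few hundred pixels'
length and property studies of 20–200 random instances (hull oracle
n ≤ 60, Otsu 100 images, 20 phantoms per recovery study, 16 images and
2+2 epochs for the training smoke) — sizes at which the brute-force
oracles remain exact and the whole validation completes in about a
minute on one core.
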