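# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `shootseg`. All lengths are millimetres; +z is vertical.

## Synthetic plant model

The generator emulates a young dicot shoot (soybean/tomato-like) at desk
scale. It is a *stated world*: its defaults define the conditions under
which the pipeline is tested, and they are not tuned to test outcomes.

**Stem.** Points sampled on a cylinder surface (radius `stem_radius`,
default 1.5; height `stem_height`, default 120), stratified in z so the stem
has no axial gaps, uniform in azimuth, plus isotropic Gaussian jitter
`noise_sigma` (default 0.05; the pipeline's acceptance world uses 0). With
zero jitter every stem point is exactly `stem_radius` from the axis.

**Leaves.** Each leaf = petiole + blade, all labeled `leaf` with one
instance ID. The petiole is a 1 mm-wide strip from the stem surface outward
(default length 8, elevation 10–30°). The blade is a rectangle
`leaf_length x leaf_width` (defaults 40 x 20) that

- *tapers* toward base and tip with half-width `W/2 * sqrt(sin(pi u/L))`, so
  the extreme points along the first principal axis lie on the midline as on
  a real leaf (a sharp-cornered rectangle would make "the two PC1 extremes"
  ambiguous along a whole edge);
- *bends* along its long axis by a sinusoid of amplitude `0.08 L`,
  reparameterized by arc length so the bend is isometric: the geodesic
  length of the generated blade equals the nominal length exactly. This
  makes the geodesic length/width estimators measure something a flat-plane
  test could not.

Blades are sampled on a jittered grid with cell size ~1 mm so that the point
spacing stays below the fixed 1.5 mm clustering radius (real MVS clouds of
these plants are denser still). A leaf instance includes its petiole;
recorded ground-truth length is `petiole_length + blade arc length`, width is
the blade's maximum width. Attachment heights are spread over the upper 60%
of the stem with golden-angle azimuths, mirroring phyllotaxis and keeping
different leaves > 1.5 mm apart.

**MVS artifacts.** `inject_artifacts` adds `floor(ghost_fraction * N)`
jittered copies of stem points displaced 0.5–2 mm horizontally (ghost
points from photogrammetric reconstruction) and cuts 3 mm disks out of
leaves until ~`gap_fraction` of leaf points are gone. The magnitudes are
chosen, not fitted: no quantitative artifact model was available.

What a green test on this world does *not* establish: robustness to real
photogrammetric noise statistics, occlusion between touching leaves,
trifoliate/compound leaves, soil clutter, or growth-stage variation.

## Annotation-efficient protocol

`downsample_random` keeps `ceil(ratio * N)` points uniformly without
replacement (the reference protocol's ratio is 0.2); `make_weak_annotation`
keeps full labels on exactly `min(k, N)` uniformly chosen points and sets
all other labels to the sentinel −1. The desk pipeline applies weak labeling
at ratio 1.0: its synthetic clouds are already sparse relative to the fixed
1.5 mm cluster radius, so the full-scale 0.2 down-sampling is exercised in
the I/O tests rather than in the end-to-end run.

## Backbone

A voxel U-Net stands in for a sparse-convolutional U-Net, honouring the
contract that matters downstream: per-point features obtained by voxel
broadcast, permutation equivariance, identical rows for points sharing a
voxel. Points hash to `floor(coord / voxel_size)` (desk default 2.0 mm);
per-voxel inputs are means of per-point channels; each pyramid level applies
a linear + ReLU block, mean-pools to `child // 2` parents going down, and
gathers + concatenates skip features coming up; final per-voxel features
broadcast back to points. Channels default to (16, 32, 64).

Per-point input channels are the centroid-centered x, y, z, the horizontal
distance to the vertical centroid axis (all / 50 mm), and three local
covariance shape descriptors over the 16 nearest neighbours — linearity,
planarity, verticality. The descriptors are needed at desk scale: this
backbone has pointwise layers only (no spatial kernels), and without them it
is capacity-limited near 82 mIoU *even under full supervision*, because
nothing in the architecture can compute local surface orientation. All input
channels are invariant to translation and to rotation about z.

Everything (layers, batch norm, segment pooling, SGD with momentum 0.9,
polynomial learning-rate decay with power 0.9 and floor 1e-4, global
gradient-norm clipping at 5) is plain numpy with handwritten backprop,
verified against central finite differences. Desk-scale learning rate is
0.03; the reference schedule's 0.1 oscillates on this small numpy network.

## Self-supervised objective

Two views per cloud (rotation about z uniform in [0, 2π), translation ±10,
per-point jitter σ = 0.1; the optional 0.9–1.1 rescaling is off by default
because absolute organ size is itself a discriminative stem/leaf cue and
forcing scale invariance into the representation measurably hurts transfer).
One FPS index set, computed on the un-augmented coordinates, subsamples both
views' representations so that rows correspond across views; columns are
standardized over the H sampled rows before the cross-correlation. λ
defaults to 0.005, keeping the diagonal and off-diagonal terms comparable.
During training a zero-variance (dead) channel gets an ε-floored standard
deviation instead of an error so a dead ReLU cannot abort the run; the
public `cross_correlation` operation raises, naming the dimension.

At fine-tuning time the final projection layer of the pretrained network is
re-initialized (the standard projector-discard of self-supervised learning);
only the trunk transfers.

**Honest negative result.** In this desk world the pretraining margin of the
reference method does not reproduce: with 50 labeled points per cloud the
semantic task already saturates near the voxel-purity ceiling (~99 mIoU
attainable; ~96–98 reached), so pretrained-vs-random-init differences are
0 ± ~1 mIoU point with seed-dependent sign. The margin reported at full
scale belongs to a regime — 512-dimensional sparse CNN, raw xyz+RGB inputs,
real MVS data — that does not scale down to a desk CPU. Alternatives that
were tried and did not yield a stable positive margin: xyz-only inputs
(absolute accuracy too low), larger backbones at finer voxels (same
plateau), worlds with MVS artifacts, shorter fine-tuning budgets, and
batch-normalized head inputs.

## Segmentation and clustering

Semantic head: pointwise MLP K→32→n, argmax labels with ties to the lowest
class index; cross-entropy averaged over labeled points only. Offset head:
two pointwise layers with a batch-normalization layer, K→32→3. Instance
training optimizes the unit-weight sum of the semantic, L1-regression and
cosine-direction losses at annotated instance points; centroid targets in
the weak setting are means over the *annotated* points of an instance (the
full instance is unknown by construction). Zero-norm vectors in the
direction loss are skipped with a warning (the cosine is undefined there).

Clustering: connected components of the radius graph (1.5 mm) over
leaf-labeled points; components below `min_size` (default 50) are dropped as
specks; proposal confidence is component size normalized by the largest
component (no learned scorer exists in this pipeline). The union of the
original-coordinate and shifted-coordinate proposal sets is deduplicated by
greedy NMS at point-set IoU 0.5, then each point is assigned to the
highest-confidence surviving proposal containing it, making the final
instances disjoint.

## Evaluation

Per-class precision, recall, F1 and IoU are percentages from one-vs-rest
counts (unlabeled ground truth excluded); means are unweighted class
averages; a class absent from both prediction and truth is excluded from the
means with a warning. Instance AP follows the indoor-benchmark protocol:
confidence-sorted greedy matching with one prediction per ground-truth
instance, all-point-interpolated area under the precision–recall curve,
averaged over IoU thresholds 0.50:0.05:0.95, plus single-threshold AP@50 and
AP@25 (leaves are the only evaluated instance class). Trait agreement uses
R² = 1 − SS_res/SS_tot and RMSE.

## Trait extraction

Stem diameter slices the stem's z-range into four equal parts, fits the
lowest slice's principal axis through its centroid (orthogonal least
squares — vertical-axis ordinary least squares is ill-posed for near-vertical
stems), and returns twice the median perpendicular distance. For points
exactly on a cylinder surface whose fitted axis is the true axis this is
exact irrespective of angular density.

Geodesics run on a k-nearest-neighbour graph (k = 10) over the raw points
with Euclidean edge weights; a disconnected pair falls back to the
straight-line distance with a warning. Leaf length takes the PC1-extreme
pair; among candidates within 1% of the extreme projection, the point
closest to the centroid in the orthogonal components is chosen — this
resolves the whole-edge ties of flat rectangular test shapes
deterministically and direction-independently. Leaf width bins the PC1
projection into five equal intervals, takes the PC2- and PC3-extreme pair
geodesics per non-empty bin (gappy leaves are expected; empty bins are
skipped, and a bin with no spread counts as width 0), and returns the
longest path. A degenerate-input conflict is resolved pragmatically: purely
1-D clouds measure length normally and width ≈ 0 rather than erroring; only
clouds with no spread at all are rejected.

## Determinism

Every stochastic step (generation, down-sampling, weak labeling,
augmentation, FPS start, batch selection, weight init) derives from explicit
integer seeds through `numpy.random.default_rng`; reruns with the same
config reproduce loss traces exactly. Checkpoints bundle weights, configs
and seed.

## Limitations

- The backbone is not a true sparse CNN: it has no spatial kernels, relying
  on hand-computed local shape descriptors instead; full-scale voxel sizes
  (0.2 mm) and dimensions (D = 512, 10,000 iterations) are configurable but
  not practical on one CPU.
- Semantic and instance networks are trained separately (as in the reference
  design); no joint multi-task model.
- Trait extraction assumes simple leaves; compound leaves would need
  per-leaflet instances.
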