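# shootseg

Weakly supervised 3D plant-shoot segmentation and organ-level phenotyping on
point clouds, at desk scale.

Point-wise annotation of plant point clouds is the bottleneck of 3D
phenotyping: labeling every point of a photogrammetric soybean or tomato
shoot takes hours per plant. `shootseg` implements an annotation-efficient
pipeline in which only *k* points per cloud (k = 50/100/200) keep their
labels:

1. **Self-supervised pretraining.** Two randomly transformed views of an
   unlabeled cloud X are passed through a shared voxel U-Net f_θ, giving
   representations Z_p, Z_q (M x D). One farthest-point-sampling index set
   reduces both to H x D, and the column-standardized cross-correlation
   matrix Z (D x D) is driven toward the identity by

       L_VIB = Σ_i (1 − Z_ii)² + λ Σ_i Σ_{j≠i} Z_ij²,

   so corresponding feature channels become view-invariant while distinct
   channels decorrelate — no labels needed.
2. **Weakly supervised fine-tuning.** A semantic head (stem vs leaf,
   cross-entropy at the k labeled points) and an offset head predicting
   per-point vectors o_i toward the leaf-instance centroid ĉ_i, trained with

       L_inst = L_sem + L_o-reg + L_o-dir,
       L_o-reg = (1/Σm_i) Σ_i ‖o_i − (ĉ_i − p_i)‖₁ m_i,
       L_o-dir = −(1/Σm_i) Σ_i (o_i·(ĉ_i−p_i)) / (‖o_i‖‖ĉ_i−p_i‖) m_i.

3. **Instance clustering.** Leaf-labeled points are grouped by 1.5 mm
   ball-query connected components twice — on the original coordinates (Cc)
   and on the offset-shifted coordinates (Cs) — and the union C of both
   proposal sets (deduplicated by IoU-0.5 non-maximum suppression) gives the
   leaf instances.
4. **Trait extraction.** Stem diameter = 2 x median perpendicular distance of
   the lowest z-quartile of stem points to their orthogonal-least-squares
   line; leaf length = geodesic between the PC1 extremes of a leaf instance;
   leaf width = longest geodesic between PC2/PC3 extreme pairs over 5 PC1
   bins. Segmentation quality is scored with per-class precision / recall /
   F1 / IoU and mIoU; instances with AP averaged over IoU thresholds
   0.50:0.05:0.95 (plus AP@50, AP@25); traits with R² and RMSE.

Everything runs against a seeded **synthetic plant generator** (cylindrical
stem, petioles, bent tapered leaf blades, optional multi-view-stereo ghost
points and leaf gaps) that records exact ground-truth labels and traits, so
the whole pipeline is testable on one CPU in minutes without any dataset
download.

## Worked example

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the desk-scale experiment (20 training + 5 validation synthetic plants,
50-point weak labels, 300 pretraining + 300 fine-tuning iterations) and
prints:

```
semantic mIoU (pretrained): 95.44
semantic mIoU (baseline):   93.92
instance AP / AP@50 / AP@25: 96.8 / 100.0 / 100.0
leaves matched at IoU>=0.5: 20/20
stem_diameter: R2 0.996  RMSE 0.056 mm
leaf_length: R2 0.991  RMSE 0.664 mm
leaf_width: R2 0.974  RMSE 0.582 mm
```

Read: held-out stem–leaf segmentation reaches ~95 mIoU from only 50 labeled
points per cloud; every true leaf is recovered as a predicted instance with
point-set IoU ≥ 0.5; and the organ traits measured from labeled clouds agree
with the generator's ground truth to within fractions of a millimetre.
The same experiment is available as `shootseg pipeline --out runs/demo
--seed 1`, which writes the full metrics report to `runs/demo/metrics.json`.

Individual stages are available as `shootseg synth | weaklabel | pretrain |
finetune | infer | eval | traits | trait-eval`; see `shootseg --help`.

```python
from shootseg import PlantSpec, generate_plant, extract_traits

cloud, truth = generate_plant(PlantSpec(n_leaves=3, seed=7))
record = extract_traits(cloud)     # stem diameter + per-leaf length/width, mm
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete desk-scale experiment from scratch under the given seed
— generation, weak labeling, pretraining, both fine-tunings, validation
metrics and trait agreement — printing the summary above and writing the
JSON report to `--out`.

## Layout

- `src/shootseg/synthetic.py` — seeded plant generator with exact ground truth
- `src/shootseg/io.py` — TXT/PLY clouds, soil removal, down-sampling, weak labels
- `src/shootseg/voxelnet.py` — voxel U-Net backbone (numpy, manual backprop)
- `src/shootseg/pretrain.py` — augmentations, FPS, cross-correlation objective
- `src/shootseg/segmentation.py` — heads, weak-supervision losses, clustering
- `src/shootseg/metrics.py` — semantic metrics, instance AP, trait agreement
- `src/shootseg/traits.py` — stem diameter, geodesic leaf length/width
- `src/shootseg/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
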