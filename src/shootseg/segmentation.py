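"""Weakly supervised stem–leaf and leaf-instance segmentation.

Two task heads sit on the backbone's per-point features F (M x K):

* a semantic head (point-wise MLP) scoring each point as stem or leaf,
  trained with cross-entropy evaluated only at the annotated points;
* an offset head (two point-wise layers with a normalization layer)
  predicting a per-point 3-vector pointing toward the point's leaf-instance
  centroid, trained with an L1 regression loss plus a cosine direction loss,
  again only at annotated instance points.

At inference the leaf-labeled points are grouped by ball-query connected
components (radius 1.5 mm) twice — once on the original coordinates (Cc) and
once on the offset-shifted coordinates (Cs) — and the union of the two
proposal sets, deduplicated by non-maximum suppression on point-set IoU,
gives the final leaf instances C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloud import LEAF, UNLABELED, LabeledPointCloud, ValidationError
from .voxelnet import (
    SGD,
    BackboneConfig,
    BatchNorm,
    Linear,
    ReLU,
    VoxelUNet,
    load_checkpoint,
    polynomial_lr,
    restore_params,
    save_checkpoint,
)

# ---------------------------------------------------------------------------
# containers


@dataclass
class SemanticPrediction:
    scores: np.ndarray  #: (M, n) raw class scores
    labels: np.ndarray  #: (M,) argmax labels (ties -> lowest class index)


@dataclass
class InstanceSupervision:
    """Per-point binary mask and instance-centroid targets (Eqs. of the
    voting-center loss): ``mask[i]`` is 1 iff point i carries an annotated
    leaf-instance ID, and ``centroids[i]`` is the centroid of the annotated
    points of that instance."""

    mask: np.ndarray  #: (M,) bool
    centroids: np.ndarray  #: (M, 3); defined wherever mask is True


@dataclass
class Proposal:
    indices: np.ndarray  #: point indices into the owning cloud
    class_label: int
    confidence: float


@dataclass
class ClusterSet:
    proposals: list[Proposal] = field(default_factory=list)
    provenance: str = ""  #: "Cc" (original coords), "Cs" (shifted), or "C" (merged)

    def __len__(self) -> int:
        return len(self.proposals)

    def instance_labels(self, n_points: int) -> np.ndarray:
        """Per-point instance IDs 1..len (by descending confidence); 0 elsewhere."""
        out = np.zeros(n_points, dtype=np.int64)
        order = sorted(
            range(len(self.proposals)),
            key=lambda i: (-self.proposals[i].confidence, i),
        )
        for rank, i in enumerate(order):
            out[self.proposals[i].indices] = rank + 1
        return out


# ---------------------------------------------------------------------------
# heads


class MLPHead:
    """Point-wise two-layer perceptron K -> hidden -> n."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, hidden: int = 32):
        self.lin1, self.act, self.lin2 = Linear(rng, n_in, hidden), ReLU(), Linear(rng, hidden, n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.lin2.forward(self.act.forward(self.lin1.forward(x)))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.lin1.backward(self.act.backward(self.lin2.backward(g)))

    def params(self):
        return self.lin1.params() + self.lin2.params()


class OffsetHead:
    """Two point-wise layers with a batch-normalization layer, K -> 3."""

    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int = 32):
        self.lin1 = Linear(rng, n_in, hidden)
        self.bn = BatchNorm(hidden)
        self.act = ReLU()
        self.lin2 = Linear(rng, hidden, 3)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.lin2.forward(self.act.forward(self.bn.forward(self.lin1.forward(x))))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.lin1.backward(self.bn.backward(self.act.backward(self.lin2.backward(g))))

    def params(self):
        return self.lin1.params() + self.bn.params() + self.lin2.params()


def semantic_predict(features: np.ndarray, head: MLPHead) -> SemanticPrediction:
    """Score every point and take the argmax label (ties -> lowest class)."""
    features = np.asarray(features, float)
    if features.ndim != 2:
        raise ValidationError(f"features must be (M, K), got {features.shape}")
    scores = head.forward(features)
    return SemanticPrediction(scores=scores, labels=np.argmax(scores, axis=1))


# ---------------------------------------------------------------------------
# losses


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def masked_cross_entropy(
    scores: np.ndarray, gt_semantic: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Mean cross-entropy over labeled points only; unlabeled points (or
    points outside ``mask``) contribute nothing."""
    loss, _ = _masked_ce_with_grad(scores, gt_semantic, mask)
    return loss


def _masked_ce_with_grad(scores, gt_semantic, mask=None):
    scores = np.asarray(scores, float)
    gt = np.asarray(gt_semantic)
    if mask is None:
        mask = gt != UNLABELED
    mask = np.asarray(mask, bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValidationError("cross-entropy needs at least one labeled point")
    p = _softmax(scores[idx])
    y = gt[idx]
    loss = float(-np.mean(np.log(np.clip(p[np.arange(idx.size), y], 1e-300, None))))
    g = np.zeros_like(scores)
    gp = p.copy()
    gp[np.arange(idx.size), y] -= 1.0
    g[idx] = gp / idx.size
    return loss, g


def build_instance_supervision(cloud: LabeledPointCloud) -> InstanceSupervision:
    """Mask and per-point centroid targets from a (weakly) labeled cloud.

    In the weak setting only the annotated points of an instance exist, so
    centroids are means over annotated coordinates of that instance.
    """
    annotated = cloud.instance >= 1
    if not np.any(annotated):
        raise ValidationError("no annotated leaf-instance points in cloud")
    centroids = np.zeros_like(cloud.coords)
    for iid in np.unique(cloud.instance[annotated]):
        members = cloud.instance == iid
        centroids[members] = cloud.coords[members].mean(axis=0)
    return InstanceSupervision(mask=annotated, centroids=centroids)


def offset_regression_loss(
    offsets: np.ndarray, coords: np.ndarray, sup: InstanceSupervision
) -> float:
    """Masked mean L1 distance between predicted offsets and the true
    point-to-centroid displacements."""
    loss, _ = _offset_reg_with_grad(offsets, coords, sup)
    return loss


def _offset_reg_with_grad(offsets, coords, sup):
    m = np.asarray(sup.mask, bool)
    total = int(m.sum())
    if total == 0:
        raise ValidationError("offset regression needs at least one masked point")
    target = sup.centroids - coords
    diff = offsets[m] - target[m]
    loss = float(np.abs(diff).sum() / total)
    g = np.zeros_like(offsets)
    g[m] = np.sign(diff) / total
    return loss, g


def offset_direction_loss(
    offsets: np.ndarray, coords: np.ndarray, sup: InstanceSupervision
) -> float:
    """Masked mean negative cosine between predicted offsets and true
    displacement directions; -1 at perfect alignment, +1 anti-parallel.
    Points where either vector has zero norm are skipped with a warning."""
    loss, _ = _offset_dir_with_grad(offsets, coords, sup)
    return loss


def _offset_dir_with_grad(offsets, coords, sup):
    m = np.asarray(sup.mask, bool)
    total = int(m.sum())
    if total == 0:
        raise ValidationError("direction loss needs at least one masked point")
    target = sup.centroids - coords
    o, t = offsets[m], target[m]
    no = np.linalg.norm(o, axis=1)
    nt = np.linalg.norm(t, axis=1)
    ok = (no > 0) & (nt > 0)
    if not np.all(ok):
        warnings.warn(
            f"direction loss: skipping {int((~ok).sum())} zero-norm vector(s)",
            RuntimeWarning,
            stacklevel=3,
        )
    if not np.any(ok):
        return 0.0, np.zeros_like(offsets)
    o_hat = o[ok] / no[ok, None]
    t_hat = t[ok] / nt[ok, None]
    cos = np.sum(o_hat * t_hat, axis=1)
    loss = float(-(cos.sum()) / total)
    # d cos/d o = (t_hat - o_hat * cos) / |o|
    g_local = -(t_hat - o_hat * cos[:, None]) / no[ok, None] / total
    g = np.zeros_like(offsets)
    midx = np.flatnonzero(m)
    g[midx[ok]] = g_local
    return loss, g


def instance_loss(sem_loss: float, reg_loss: float, dir_loss: float) -> float:
    """Voting-center loss: unit-weight sum of the three parts."""
    for v in (sem_loss, reg_loss, dir_loss):
        if not np.isfinite(v):
            raise ValidationError("instance loss parts must be finite")
    return float(sem_loss + reg_loss + dir_loss)


# ---------------------------------------------------------------------------
# clustering


def ball_cluster(
    coords: np.ndarray,
    semantic_labels: np.ndarray,
    radius: float = 1.5,
    min_size: int = 50,
    provenance: str = "Cc",
) -> ClusterSet:
    """Group leaf-labeled points into connected components of the radius
    graph (two points connect iff within ``radius`` mm).  Components smaller
    than ``min_size`` are discarded; confidence = size / largest size."""
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    coords = np.asarray(coords, float)
    leaf_idx = np.flatnonzero(np.asarray(semantic_labels) == LEAF)
    if leaf_idx.size == 0:
        return ClusterSet(provenance=provenance)
    pts = coords[leaf_idx]
    pairs = cKDTree(pts).query_pairs(r=radius, output_type="ndarray")
    n = leaf_idx.size
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(adj, directed=False)
    proposals = []
    sizes = np.bincount(comp, minlength=n_comp)
    for c in range(n_comp):
        if sizes[c] >= min_size:
            proposals.append(
                Proposal(indices=leaf_idx[comp == c], class_label=LEAF, confidence=0.0)
            )
    if proposals:
        largest = max(len(p.indices) for p in proposals)
        for p in proposals:
            p.confidence = len(p.indices) / largest
    return ClusterSet(proposals=proposals, provenance=provenance)


def _point_set_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.intersect1d(a, b, assume_unique=True).size
    if inter == 0:
        return 0.0
    return inter / (a.size + b.size - inter)


def merge_proposals(cc: ClusterSet, cs: ClusterSet, iou_threshold: float = 0.5) -> ClusterSet:
    """Union of the two proposal sets with greedy non-maximum suppression.

    Proposals are visited by descending confidence (original-coordinate
    proposals first on ties); a proposal is suppressed when its point-set IoU
    with an already kept one reaches ``iou_threshold``.  Finally every point
    is assigned to the surviving proposal of highest confidence that contains
    it, so merged proposals are disjoint.
    """
    pool = list(cc.proposals) + list(cs.proposals)
    order = sorted(range(len(pool)), key=lambda i: (-pool[i].confidence, i))
    kept: list[Proposal] = []
    for i in order:
        p = pool[i]
        if all(_point_set_iou(p.indices, q.indices) < iou_threshold for q in kept):
            kept.append(p)
    # resolve residual overlaps: each point goes to its best surviving proposal
    owner: dict[int, int] = {}
    for rank, p in enumerate(kept):  # kept is confidence-sorted
        for idx in p.indices:
            owner.setdefault(int(idx), rank)
    merged = []
    for rank, p in enumerate(kept):
        idx = np.array(sorted(i for i, r in owner.items() if r == rank), dtype=np.int64)
        if idx.size:
            merged.append(Proposal(indices=idx, class_label=p.class_label,
                                   confidence=p.confidence))
    return ClusterSet(proposals=merged, provenance="C")


# ---------------------------------------------------------------------------
# fine-tuning


@dataclass(frozen=True)
class FinetuneConfig:
    """Fine-tuning hyper-parameters (desk-scale defaults; full scale is
    4,000 iterations at batch size 2)."""

    iterations: int = 300
    batch_size: int = 2
    lr: float = 0.1
    lr_power: float = 0.9
    lr_floor: float = 1e-4
    momentum: float = 0.9
    n_classes: int = 2
    hidden: int = 32
    cluster_radius: float = 1.5  #: mm, ball-query threshold
    min_cluster_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.batch_size < 1:
            raise ValidationError("iterations and batch_size must be >= 1")
        if self.n_classes < 2:
            raise ValidationError("need at least two semantic classes")


class SegmentationModel:
    """Backbone plus task heads; produced by :func:`finetune`."""

    def __init__(self, backbone: VoxelUNet, task: str, config: FinetuneConfig):
        if task not in ("semantic", "instance"):
            raise ValidationError(f"unknown task {task!r}")
        rng = np.random.default_rng(config.seed + 1)
        self.backbone = backbone
        self.task = task
        self.config = config
        k = backbone.config.out_dim
        self.sem_head = MLPHead(rng, k, config.n_classes, config.hidden)
        self.offset_head = OffsetHead(rng, k, config.hidden) if task == "instance" else None

    def modules(self) -> dict:
        mods = {"backbone": self.backbone, "sem_head": self.sem_head}
        if self.offset_head is not None:
            mods["offset_head"] = self.offset_head
        return mods

    def params(self):
        return [p for m in self.modules().values() for p in m.params()]

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def save(self, path) -> None:
        save_checkpoint(
            path,
            self.modules(),
            {"backbone": self.backbone.config, "finetune": self.config},
            extra={"task": self.task, "stage": "finetune"},
        )

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        arrays, meta = load_checkpoint(path)
        bb = BackboneConfig(**{**meta["configs"]["backbone"],
                               "channels": tuple(meta["configs"]["backbone"]["channels"])})
        cfg = FinetuneConfig(**meta["configs"]["finetune"])
        model = cls(VoxelUNet(bb), meta["extra"]["task"], cfg)
        restore_params(model.modules(), arrays)
        return model


def finetune(
    dataset_weak: list[LabeledPointCloud],
    pretrained: str | VoxelUNet | None,
    task: str,
    config: FinetuneConfig | None = None,
    backbone_config: BackboneConfig | None = None,
    out_path: str | None = None,
    log_every: int = 0,
) -> tuple[SegmentationModel, list[float]]:
    """Fine-tune (or train from scratch when ``pretrained`` is None — the
    'baseline' setting) a segmentation model on weakly annotated clouds.

    Semantic task: masked cross-entropy at annotated points.  Instance task:
    cross-entropy plus offset L1 regression and direction losses at annotated
    instance points.  Returns the model and the per-iteration loss history.
    """
    cfg = config or FinetuneConfig()
    for i, cloud in enumerate(dataset_weak):
        if not np.any(cloud.semantic != UNLABELED):
            raise ValidationError(f"training cloud {i} has no labeled points")
        if task == "instance" and not np.any(cloud.instance >= 1):
            raise ValidationError(f"training cloud {i} has no annotated instances")

    def _trunk_transfer(src: VoxelUNet) -> VoxelUNet:
        # keep the pretrained trunk but re-initialize the final projection:
        # that layer is the self-supervised projector and is specialized to
        # the pretraining objective, not to the task heads
        dst = VoxelUNet(src.config)
        for dst_layer, src_layer in zip(dst.layers()[:-1], src.layers()[:-1]):
            for pd, ps in zip(dst_layer.params(), src_layer.params()):
                pd.value[...] = ps.value
        return dst

    if isinstance(pretrained, VoxelUNet):
        bb_cfg = pretrained.config
        backbone = _trunk_transfer(pretrained)
    elif pretrained is not None:
        arrays, meta = load_checkpoint(pretrained)
        bb_cfg = BackboneConfig(**{**meta["configs"]["backbone"],
                                   "channels": tuple(meta["configs"]["backbone"]["channels"])})
        if backbone_config is not None and backbone_config != bb_cfg:
            raise ValidationError("backbone_config conflicts with the checkpoint's config")
        loaded = VoxelUNet(bb_cfg)
        restore_params({"backbone": loaded}, arrays)
        backbone = _trunk_transfer(loaded)
    else:
        bb_cfg = backbone_config or BackboneConfig(seed=cfg.seed)
        backbone = VoxelUNet(bb_cfg)

    model = SegmentationModel(backbone, task, cfg)
    opt = SGD(model.params(), momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed)
    sup_cache = [
        build_instance_supervision(c) if task == "instance" else None for c in dataset_weak
    ]
    history: list[float] = []
    for it in range(cfg.iterations):
        model.zero_grad()
        batch = rng.integers(len(dataset_weak), size=cfg.batch_size)
        total = 0.0
        for ci in batch:
            cloud = dataset_weak[ci]
            feats = model.backbone.forward(cloud)
            scores = model.sem_head.forward(feats)
            ce, g_scores = _masked_ce_with_grad(scores, cloud.semantic)
            g_feats = model.sem_head.backward(g_scores / cfg.batch_size)
            loss = ce
            if task == "instance":
                sup = sup_cache[ci]
                offsets = model.offset_head.forward(feats)
                reg, g_reg = _offset_reg_with_grad(offsets, cloud.coords, sup)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    dirv, g_dir = _offset_dir_with_grad(offsets, cloud.coords, sup)
                loss = instance_loss(ce, reg, dirv)
                g_feats = g_feats + model.offset_head.backward((g_reg + g_dir) / cfg.batch_size)
            model.backbone.backward(g_feats)
            total += loss
        mean_loss = total / cfg.batch_size
        if not np.isfinite(mean_loss):
            raise FloatingPointError(f"fine-tuning diverged at iteration {it}")
        history.append(mean_loss)
        opt.step(polynomial_lr(it, cfg.iterations, cfg.lr, cfg.lr_power, cfg.lr_floor))
        if log_every and (it % log_every == 0 or it == cfg.iterations - 1):
            print(f"[finetune/{task}] iter {it:5d}  loss {mean_loss:.4f}")
    if out_path is not None:
        model.save(out_path)
    return model, history


# ---------------------------------------------------------------------------
# inference


def infer(cloud: LabeledPointCloud, model: SegmentationModel, task: str | None = None):
    """Run a trained model on a cloud.

    Semantic task: returns a :class:`SemanticPrediction`.  Instance task:
    returns ``(SemanticPrediction, ClusterSet, instance_ids)`` where the
    cluster set is the NMS-merged union of the original-coordinate (Cc) and
    offset-shifted (Cs) ball clusterings and ``instance_ids`` assigns 0 to
    points outside every proposal.
    """
    task = task or model.task
    if task != model.task:
        raise ValidationError(f"model was trained for {model.task!r}, not {task!r}")
    feats = model.backbone.forward(cloud)
    pred = semantic_predict(feats, model.sem_head)
    if task == "semantic":
        return pred
    offsets = model.offset_head.forward(feats)
    cfg = model.config
    cc = ball_cluster(cloud.coords, pred.labels, cfg.cluster_radius,
                      cfg.min_cluster_size, provenance="Cc")
    cs = ball_cluster(cloud.coords + offsets, pred.labels, cfg.cluster_radius,
                      cfg.min_cluster_size, provenance="Cs")
    merged = merge_proposals(cc, cs)
    return pred, merged, merged.instance_labels(len(cloud))


__all__ = [
    "SemanticPrediction",
    "InstanceSupervision",
    "Proposal",
    "ClusterSet",
    "MLPHead",
    "OffsetHead",
    "semantic_predict",
    "masked_cross_entropy",
    "build_instance_supervision",
    "offset_regression_loss",
    "offset_direction_loss",
    "instance_loss",
    "ball_cluster",
    "merge_proposals",
    "FinetuneConfig",
    "SegmentationModel",
    "finetune",
    "infer",
]
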