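"""Self-supervised backbone pretraining with a viewpoint-bottleneck objective.

Two randomly transformed views of the same unlabeled cloud are pushed through
the shared backbone; the per-point representations are subsampled with one
farthest-point-sampling index set (computed on the un-augmented coordinates so
rows correspond across views), their column-standardized cross-correlation
matrix ``Z`` (D x D) is formed, and the loss

    L = sum_i (1 - Z_ii)^2 + lambda * sum_{i != j} Z_ij^2

drives ``Z`` toward the identity: corresponding feature channels of the two
views become perfectly correlated while distinct channels decorrelate.  The
minimizer therefore learns augmentation-invariant, non-redundant features
without any labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import LabeledPointCloud, ValidationError
from .voxelnet import (
    SGD,
    BackboneConfig,
    VoxelUNet,
    polynomial_lr,
    save_checkpoint,
)


@dataclass(frozen=True)
class VIBConfig:
    """Pretraining hyper-parameters.

    Full-scale values are H=1024, D=512, 10,000 iterations; the defaults
    here are desk-scale so pretraining finishes in minutes on one CPU.
    """

    H: int = 1024  #: representations kept per cloud after FPS (clamped to M)
    D: int = 32  #: representation dimension (full scale: 512)
    lam: float = 0.005  #: trade-off between invariance and redundancy terms
    iterations: int = 300  #: full scale: 10,000
    batch_size: int = 2
    lr: float = 0.1  #: initial learning rate, polynomially decayed
    lr_power: float = 0.9
    lr_floor: float = 1e-4
    momentum: float = 0.9
    #: include the 0.9-1.1 uniform rescaling in the augmentation menu.  Off by
    #: default: absolute organ size is a discriminative cue for stem-vs-leaf,
    #: and forcing scale invariance into the representation hurts transfer.
    augment_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.H < 2 or self.D < 2:
            raise ValidationError("H and D must be >= 2")
        if self.lam <= 0:
            raise ValidationError("lambda must be > 0")
        if self.iterations < 1 or self.batch_size < 1:
            raise ValidationError("iterations and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# augmentation


def random_view(
    cloud: LabeledPointCloud,
    seed: int,
    rotate: bool = True,
    scale: bool = True,
    translate: bool = True,
    jitter: bool = True,
) -> LabeledPointCloud:
    """Random geometric transformation of a cloud (one training 'viewpoint').

    Applies, in order: rotation about z uniform in [0, 2pi), uniform scale in
    [0.9, 1.1], per-axis translation in [-10, 10] mm and per-point Gaussian
    jitter (sigma 0.1 mm).  Labels, colors and point order are untouched.
    """
    rng = np.random.default_rng(seed)
    coords = cloud.coords.copy()
    if rotate:
        a = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(a), np.sin(a)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        coords = coords @ rot.T
    if scale:
        coords = coords * rng.uniform(0.9, 1.1)
    if translate:
        coords = coords + rng.uniform(-10.0, 10.0, size=3)
    if jitter:
        coords = coords + rng.normal(0.0, 0.1, size=coords.shape)
    return cloud.with_coords(coords)


# ---------------------------------------------------------------------------
# farthest point sampling


def farthest_point_sample(coords: np.ndarray, H: int, seed: int = 0) -> np.ndarray:
    """Greedy max–min subsampling: start at a seeded random point, then
    repeatedly add the point whose minimum distance to the chosen set is
    largest (ties to the lowest index).  Returns H indices in selection
    order."""
    coords = np.asarray(coords, dtype=np.float64)
    m = coords.shape[0]
    if not (1 <= H <= m):
        raise ValidationError(f"H must be in [1, {m}], got {H}")
    rng = np.random.default_rng(seed)
    chosen = np.empty(H, dtype=np.int64)
    chosen[0] = rng.integers(m)
    min_d = np.linalg.norm(coords - coords[chosen[0]], axis=1)
    for i in range(1, H):
        nxt = int(np.argmax(min_d))
        chosen[i] = nxt
        np.minimum(min_d, np.linalg.norm(coords - coords[nxt], axis=1), out=min_d)
    return chosen


# ---------------------------------------------------------------------------
# cross-correlation and loss


def _standardize_columns(z: np.ndarray, eps: float | None):
    mu = z.mean(axis=0)
    sd = z.std(axis=0)
    if eps is None:
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            raise ValidationError(f"zero-variance feature dimension(s): {bad.tolist()}")
        sd_eff = sd
    else:
        sd_eff = np.maximum(sd, eps)
    return (z - mu) / sd_eff, sd_eff


def cross_correlation(zp: np.ndarray, zq: np.ndarray, eps: float | None = None) -> np.ndarray:
    """Column-standardized cross-correlation matrix Z (D x D): standardize
    each feature over the H rows, then ``Z_ij = (1/H) sum_h zp[h,i] zq[h,j]``.

    Rows must correspond point-for-point across the two views.  A
    zero-variance column raises unless ``eps`` is given (training uses a
    small floor so dead channels do not abort the run).
    """
    zp, zq = np.asarray(zp, float), np.asarray(zq, float)
    if zp.shape != zq.shape or zp.ndim != 2:
        raise ValidationError(f"shapes must match and be 2-D, got {zp.shape} vs {zq.shape}")
    h = zp.shape[0]
    zp_hat, _ = _standardize_columns(zp, eps)
    zq_hat, _ = _standardize_columns(zq, eps)
    return zp_hat.T @ zq_hat / h


def vib_loss(z: np.ndarray, lam: float) -> float:
    """Redundancy-reduction loss: ``sum_i (1 - Z_ii)^2 + lam * sum_{i!=j} Z_ij^2``.

    Zero exactly when Z is the identity.
    """
    z = np.asarray(z, float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValidationError(f"Z must be square, got {z.shape}")
    if lam <= 0:
        raise ValidationError("lambda must be > 0")
    diag = np.diag(z)
    off = z - np.diag(diag)
    return float(np.sum((1.0 - diag) ** 2) + lam * np.sum(off**2))


def _vib_loss_grad(z: np.ndarray, lam: float) -> np.ndarray:
    g = 2.0 * lam * z
    np.fill_diagonal(g, -2.0 * (1.0 - np.diag(z)))
    return g


def _cross_corr_with_grad(zp: np.ndarray, zq: np.ndarray, lam: float, eps: float = 1e-8):
    """Loss value plus gradients w.r.t. the raw (unstandardized) inputs."""
    h = zp.shape[0]
    zp_hat, sp = _standardize_columns(zp, eps)
    zq_hat, sq = _standardize_columns(zq, eps)
    corr = zp_hat.T @ zq_hat / h
    loss = vib_loss(corr, lam)
    g_corr = _vib_loss_grad(corr, lam)
    g_zp_hat = zq_hat @ g_corr.T / h
    g_zq_hat = zp_hat @ g_corr / h

    def destandardize(g_hat, z_hat, sd):
        return (g_hat - g_hat.mean(axis=0) - z_hat * (g_hat * z_hat).mean(axis=0)) / sd

    return loss, destandardize(g_zp_hat, zp_hat, sp), destandardize(g_zq_hat, zq_hat, sq)


# ---------------------------------------------------------------------------
# training loop


def pretrain(
    dataset: list[LabeledPointCloud],
    backbone_config: BackboneConfig | None = None,
    vib_config: VIBConfig | None = None,
    out_path: str | None = None,
    log_every: int = 0,
) -> tuple[VoxelUNet, list[float]]:
    """Pretrain a backbone on unlabeled clouds; returns (net, loss history).

    Each iteration samples ``batch_size`` clouds, builds two random views per
    cloud, extracts features with the shared backbone, subsamples both views
    with one FPS index set computed on the original coordinates, and takes
    one SGD step on the viewpoint-bottleneck loss.  Fully deterministic under
    the config seeds; aborts if the loss goes non-finite.
    """
    if not dataset:
        raise ValidationError("pretraining needs at least one cloud")
    vib = vib_config or VIBConfig()
    bb = backbone_config or BackboneConfig(out_dim=vib.D, seed=vib.seed)
    if bb.out_dim != vib.D:
        raise ValidationError(
            f"backbone out_dim ({bb.out_dim}) must equal representation dim D ({vib.D})"
        )
    net = VoxelUNet(bb)
    opt = SGD(net.params(), momentum=vib.momentum)
    rng = np.random.default_rng(vib.seed)
    history: list[float] = []
    for it in range(vib.iterations):
        net.zero_grad()
        batch = rng.integers(len(dataset), size=vib.batch_size)
        total = 0.0
        for ci in batch:
            cloud = dataset[ci]
            sp, sq, sf = rng.integers(2**31, size=3)
            view_p = random_view(cloud, seed=int(sp), scale=vib.augment_scale)
            view_q = random_view(cloud, seed=int(sq), scale=vib.augment_scale)
            idx = farthest_point_sample(cloud.coords, min(vib.H, len(cloud)), seed=int(sf))
            zp = net.forward(view_p)
            zq = net.forward(view_q)  # layer caches now belong to view q
            loss, g_zp_s, g_zq_s = _cross_corr_with_grad(zp[idx], zq[idx], vib.lam)
            scale = 1.0 / vib.batch_size
            g_zq = np.zeros_like(zq)
            g_zq[idx] = g_zq_s * scale
            net.backward(g_zq)
            net.forward(view_p)  # restore caches for view p
            g_zp = np.zeros_like(zp)
            g_zp[idx] = g_zp_s * scale
            net.backward(g_zp)
            total += loss
        mean_loss = total / vib.batch_size
        if not np.isfinite(mean_loss):
            raise FloatingPointError(
                f"pretraining diverged at iteration {it}: loss={mean_loss}"
            )
        history.append(mean_loss)
        opt.step(polynomial_lr(it, vib.iterations, vib.lr, vib.lr_power, vib.lr_floor))
        if log_every and (it % log_every == 0 or it == vib.iterations - 1):
            print(f"[pretrain] iter {it:5d}  loss {mean_loss:.4f}")
    if out_path is not None:
        save_checkpoint(
            out_path,
            {"backbone": net},
            {"backbone": bb, "vib": vib},
            extra={"loss_history": history, "stage": "pretrain"},
        )
    return net, history


__all__ = [
    "VIBConfig",
    "random_view",
    "farthest_point_sample",
    "cross_correlation",
    "vib_loss",
    "pretrain",
]
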