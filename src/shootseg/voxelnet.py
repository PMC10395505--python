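"""Voxel-based U-shaped feature extractor with handwritten backprop.

Desk-scale stand-in for a sparse-convolutional U-Net: points are hashed into
an integer voxel grid (``floor(coord / voxel_size)``), per-voxel input
features are the mean of the member points' features, and a small
encoder–decoder runs over the occupied voxels — per-level linear + ReLU
blocks, mean-pooling to a coarser grid (parent voxel = ``child // 2``) on the
way down, gather-upsampling plus skip concatenation on the way up.  The final
per-voxel features are broadcast back to the member points, so the network is
permutation-equivariant and two points sharing a voxel receive identical
rows.

Everything is plain numpy with explicit forward caches and a ``backward``
pass, which keeps the stack deterministic, dependency-free and fast enough
for desk-scale training on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .cloud import LabeledPointCloud, ValidationError

# ---------------------------------------------------------------------------
# voxelization


@dataclass
class VoxelMapping:
    """Bidirectional point/voxel assignment on a floor grid."""

    voxel_size: float
    keys: np.ndarray  #: (V, 3) integer voxel coordinates, lexicographically sorted
    point_to_voxel: np.ndarray  #: (N,) index into ``keys`` per point
    counts: np.ndarray  #: (V,) member count per voxel

    @property
    def n_voxels(self) -> int:
        return int(self.keys.shape[0])

    def voxel_to_points(self) -> list[np.ndarray]:
        order = np.argsort(self.point_to_voxel, kind="stable")
        splits = np.cumsum(self.counts[:-1])
        return np.split(order, splits)


def voxelize(coords: np.ndarray, voxel_size: float) -> VoxelMapping:
    """Assign every point to the voxel ``floor(coord / voxel_size)``."""
    if voxel_size <= 0:
        raise ValidationError(f"voxel_size must be > 0, got {voxel_size!r}")
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("coords contain non-finite values")
    keys_per_point = np.floor(coords / voxel_size).astype(np.int64)
    keys, inverse, counts = np.unique(
        keys_per_point, axis=0, return_inverse=True, return_counts=True
    )
    return VoxelMapping(float(voxel_size), keys, inverse.ravel(), counts)


# ---------------------------------------------------------------------------
# layers


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class BatchNorm:
    """Feature standardization over the rows of the current batch with a
    learned affine map.  Batch statistics are always used, which keeps the
    layer a pure deterministic function of its input."""

    def __init__(self, n: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mu = x.mean(axis=0)
        xc = x - self._mu
        self._var = xc.var(axis=0) + self.eps  # var of xc == var of x
        self._std = np.sqrt(x.var(axis=0) + self.eps)
        self._xhat = xc / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        n = g.shape[0]
        self.gamma.grad += (g * self._xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        gh = g * self.gamma.value
        return (gh - gh.mean(axis=0) - self._xhat * (gh * self._xhat).mean(axis=0)) / self._std

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


def _segment_mean(x: np.ndarray, seg: np.ndarray, n_seg: int, counts: np.ndarray) -> np.ndarray:
    out = np.zeros((n_seg, x.shape[1]))
    np.add.at(out, seg, x)
    return out / counts[:, None]


def _segment_sum(x: np.ndarray, seg: np.ndarray, n_seg: int) -> np.ndarray:
    out = np.zeros((n_seg, x.shape[1]))
    np.add.at(out, seg, x)
    return out


# ---------------------------------------------------------------------------
# network


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of the voxel U-Net.

    ``channels`` gives the width per pyramid level (depth = len(channels));
    ``out_dim`` is D during pretraining and K for the fine-tuning heads.
    """

    channels: tuple[int, ...] = (16, 32, 64)
    voxel_size: float = 2.0  #: mm; full-scale values are 0.2 (soybean) / 0.5 (tomato)
    in_dim: int = 7
    out_dim: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValidationError("at least one pyramid level is required")
        if any(c < 2 for c in self.channels) or self.out_dim < 2:
            raise ValidationError("channel widths and out_dim must be >= 2")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be > 0")


def local_shape_features(coords: np.ndarray, k: int = 16) -> np.ndarray:
    """Per-point covariance shape descriptors over the k nearest neighbours:
    linearity, planarity and verticality of the local neighbourhood.  Thin
    vertical structures (stems, petioles) score high linearity, blades high
    planarity; verticality is the |z| component of the principal direction.
    All three are invariant to rotation about z and to translation."""
    from scipy.spatial import cKDTree

    n = coords.shape[0]
    k_eff = min(k, n)
    _, idx = cKDTree(coords).query(coords, k=k_eff)
    nbr = coords[idx]  # (N, k, 3)
    centered = nbr - nbr.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k_eff
    w, v = np.linalg.eigh(cov)  # ascending eigenvalues
    lam = w[:, ::-1]  # descending
    lam1 = np.maximum(lam[:, 0], 1e-12)
    linearity = (lam[:, 0] - lam[:, 1]) / lam1
    planarity = (lam[:, 1] - lam[:, 2]) / lam1
    verticality = np.abs(v[:, 2, -1])  # |z| of the principal eigenvector
    return np.column_stack([linearity, planarity, verticality])


def point_input_features(cloud: LabeledPointCloud, scale: float = 50.0) -> np.ndarray:
    """Per-point input channels: centroid-centered x, y, z and the horizontal
    distance from the vertical centroid axis (all divided by ``scale`` mm),
    plus the three local covariance shape descriptors.  Centering makes the
    features — and hence the network — exactly invariant to rigid
    translations of the cloud."""
    c = cloud.coords - cloud.coords.mean(axis=0)
    r = np.hypot(c[:, 0], c[:, 1])
    return np.column_stack(
        [c / scale, r[:, None] / scale, local_shape_features(cloud.coords)]
    )


class VoxelUNet:
    """U-shaped encoder–decoder over occupied voxels; see module docstring."""

    def __init__(self, config: BackboneConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        self.enc_lin = [Linear(rng, config.in_dim, ch[0])]
        self.enc_act = [ReLU()]
        for l in range(1, len(ch)):
            self.enc_lin.append(Linear(rng, ch[l - 1], ch[l]))
            self.enc_act.append(ReLU())
        self.dec_lin, self.dec_act = [], []
        for l in range(len(ch) - 2, -1, -1):
            self.dec_lin.append(Linear(rng, ch[l + 1] + ch[l], ch[l]))
            self.dec_act.append(ReLU())
        self.out_lin = Linear(rng, ch[0], config.out_dim)

    # -- parameter plumbing -------------------------------------------------

    def layers(self):
        return [*self.enc_lin, *self.dec_lin, self.out_lin]

    def params(self) -> list[Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward / backward -------------------------------------------------

    def _build_hierarchy(self, coords: np.ndarray):
        vm = voxelize(coords, self.config.voxel_size)
        keys = vm.keys
        parents, counts = [], []
        for _ in range(len(self.config.channels) - 1):
            pk, inv, cnt = np.unique(
                np.floor_divide(keys, 2), axis=0, return_inverse=True, return_counts=True
            )
            parents.append(inv.ravel())
            counts.append(cnt)
            keys = pk
        return vm, parents, counts

    def forward(self, cloud: LabeledPointCloud) -> np.ndarray:
        """Per-point features, shape (N, out_dim)."""
        feats = point_input_features(cloud)
        return self.forward_features(cloud.coords, feats)

    def forward_features(self, coords: np.ndarray, point_feats: np.ndarray) -> np.ndarray:
        vm, parents, counts = self._build_hierarchy(coords)
        self._vm, self._parents, self._counts = vm, parents, counts

        x = _segment_mean(point_feats, vm.point_to_voxel, vm.n_voxels, vm.counts)
        skips = []
        for l, (lin, act) in enumerate(zip(self.enc_lin, self.enc_act)):
            x = act.forward(lin.forward(x))
            skips.append(x)
            if l < len(parents):
                x = _segment_mean(x, parents[l], counts[l].shape[0], counts[l])
        self._skip_dims = [s.shape[1] for s in skips]
        for i, (lin, act) in enumerate(zip(self.dec_lin, self.dec_act)):
            l = len(self.enc_lin) - 2 - i  # level we are upsampling to
            up = x[parents[l]]
            x = act.forward(lin.forward(np.concatenate([up, skips[l]], axis=1)))
        voxel_out = self.out_lin.forward(x)
        return voxel_out[vm.point_to_voxel]

    def backward(self, g_points: np.ndarray) -> None:
        """Accumulate parameter gradients from per-point output gradients."""
        vm, parents, counts = self._vm, self._parents, self._counts
        g = _segment_sum(g_points, vm.point_to_voxel, vm.n_voxels)
        g = self.out_lin.backward(g)
        g_skips = [None] * len(self.enc_lin)
        for i in range(len(self.dec_lin) - 1, -1, -1):
            l = len(self.enc_lin) - 2 - i
            g_cat = self.dec_lin[i].backward(self.dec_act[i].backward(g))
            c_up = g_cat.shape[1] - self._skip_dims[l]
            g_up, g_skip = g_cat[:, :c_up], g_cat[:, c_up:]
            if g_skips[l] is None:
                g_skips[l] = g_skip
            else:
                g_skips[l] = g_skips[l] + g_skip
            g = _segment_sum(g_up, parents[l], counts[l].shape[0])
        for l in range(len(self.enc_lin) - 1, -1, -1):
            if l < len(parents):
                g = g[parents[l]] / counts[l][parents[l], None]
            if g_skips[l] is not None:
                g = g + g_skips[l]
            g = self.enc_lin[l].backward(self.enc_act[l].backward(g))
        # gradient w.r.t. the raw input features is not needed


# ---------------------------------------------------------------------------
# optimization and checkpoints


def polynomial_lr(
    iteration: int, total: int, initial: float = 0.1, power: float = 0.9, floor: float = 1e-4
) -> float:
    """Polynomially decayed learning rate with a floor."""
    frac = min(max(iteration / max(total, 1), 0.0), 1.0)
    return floor + (initial - floor) * (1.0 - frac) ** power


class SGD:
    """SGD with momentum and global gradient-norm clipping."""

    def __init__(self, params: list[Param], momentum: float = 0.9, clip_norm: float = 5.0):
        self.params = params
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        scale = 1.0
        if self.clip_norm:
            gnorm = np.sqrt(sum(float(np.sum(p.grad**2)) for p in self.params))
            if gnorm > self.clip_norm:
                scale = self.clip_norm / gnorm
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v -= lr * scale * p.grad
            p.value += v


def save_checkpoint(path, modules: dict, configs: dict, extra: dict | None = None) -> None:
    """Persist named modules' parameters plus JSON-serializable configs."""
    arrays = {}
    for name, mod in modules.items():
        for i, p in enumerate(mod.params() if hasattr(mod, "params") else mod):
            arrays[f"{name}.{i}"] = p.value
    meta = {"configs": {k: asdict(v) if hasattr(v, "__dataclass_fields__") else v
                        for k, v in configs.items()},
            "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[dict, dict]:
    """Return (arrays-by-name, meta dict) from :func:`save_checkpoint`."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    return arrays, meta


def restore_params(modules: dict, arrays: dict) -> None:
    for name, mod in modules.items():
        plist = mod.params() if hasattr(mod, "params") else mod
        for i, p in enumerate(plist):
            key = f"{name}.{i}"
            if key not in arrays:
                raise ValidationError(f"checkpoint missing parameter {key}")
            if arrays[key].shape != p.value.shape:
                raise ValidationError(
                    f"checkpoint parameter {key} has shape {arrays[key].shape}, "
                    f"expected {p.value.shape}"
                )
            p.value[...] = arrays[key]


__all__ = [
    "VoxelMapping",
    "voxelize",
    "BackboneConfig",
    "VoxelUNet",
    "point_input_features",
    "Param",
    "Linear",
    "ReLU",
    "BatchNorm",
    "SGD",
    "polynomial_lr",
    "save_checkpoint",
    "load_checkpoint",
    "restore_params",
]
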