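"""Seeded generator of plant-shoot point clouds with exact ground truth.

The generator emulates a young soybean/tomato-like shoot at desk scale: a
vertical cylindrical stem plus a handful of leaves, each leaf a tapered blade
bent along its long axis and attached to the stem by a short petiole.  Every
point carries a semantic label (stem/leaf) and a leaf-instance ID, and the
true organ traits (stem diameter, per-leaf length and width) are recorded
from the generating geometry, so segmentation networks and trait estimators
can be validated without any external data.

Geometry notes
--------------
* ``+z`` is vertical; all lengths are millimetres.
* The blade is bent isometrically: the midline is reparameterised by arc
  length, so the geodesic length of the generated blade equals the nominal
  blade length exactly (up to sampling noise).
* The blade tapers toward base and tip (width profile ``W * sin(pi u/L)**0.5``)
  so the extreme points along the first principal axis lie on the midline,
  as on a real leaf.
* A leaf instance includes its petiole; the recorded ground-truth leaf length
  is therefore ``petiole_length + blade arc length``.

Optional multi-view-stereo artifacts — ghost points beside the stem and
circular holes in the leaves — can be injected to emulate photogrammetric
reconstruction defects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import LEAF, STEM, LabeledPointCloud, ValidationError

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))  # ~2.39996 rad

ScalarOrRange = float | tuple[float, float]


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one synthetic plant (all lengths in mm)."""

    stem_height: float = 120.0
    stem_radius: float = 1.5
    n_leaves: int = 4
    leaf_length: ScalarOrRange = 40.0  #: blade arc length; scalar or (lo, hi)
    leaf_width: ScalarOrRange = 20.0  #: max blade width; scalar or (lo, hi)
    petiole_length: float = 8.0
    points_per_organ: int = 700
    noise_sigma: float = 0.05
    ghost_fraction: float = 0.0
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stem_height", "stem_radius", "petiole_length"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("leaf_length", "leaf_width"):
            for v in _as_range(getattr(self, name)):
                if not np.isfinite(v) or v <= 0:
                    raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        if self.n_leaves < 0:
            raise ValidationError("n_leaves must be >= 0")
        if self.points_per_organ < 1:
            raise ValidationError("points_per_organ must be >= 1")
        if self.noise_sigma < 0 or not np.isfinite(self.noise_sigma):
            raise ValidationError("noise_sigma must be finite and >= 0")
        for name in ("ghost_fraction", "gap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v!r}")


@dataclass
class GroundTruthTraits:
    """Exact organ traits of a generated plant (mm)."""

    stem_diameter: float
    #: one (instance_id, leaf_length, leaf_width) triple per generated leaf
    leaves: list[tuple[int, float, float]]

    def as_rows(self, plant_id: str = "") -> list[dict]:
        rows = [
            {"plant_id": plant_id, "instance_id": 0, "trait": "stem_diameter",
             "value_mm": self.stem_diameter}
        ]
        for iid, length, width in self.leaves:
            rows.append({"plant_id": plant_id, "instance_id": iid,
                         "trait": "leaf_length", "value_mm": length})
            rows.append({"plant_id": plant_id, "instance_id": iid,
                         "trait": "leaf_width", "value_mm": width})
        return rows


def _as_range(v: ScalarOrRange) -> tuple[float, float]:
    if isinstance(v, (tuple, list)):
        if len(v) != 2:
            raise ValidationError(f"range must have two entries, got {v!r}")
        return float(v[0]), float(v[1])
    return float(v), float(v)


def _stratified_1d(n: int, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """n jittered points covering [lo, hi] without gaps larger than ~1.4 cells."""
    u = (np.arange(n) + rng.uniform(0.2, 0.8, size=n)) / n
    return lo + u * (hi - lo)


def _arclength_param(length: float, amplitude: float, n_table: int = 2048):
    """Return ``t(u)`` mapping arc length u along the bent midline to the
    abscissa t of the curve ``(t, A sin(2 pi t / length))``."""
    t_grid = np.linspace(0.0, length, n_table)
    b = amplitude * np.sin(2.0 * np.pi * t_grid / length)
    seg = np.hypot(np.diff(t_grid), np.diff(b))
    s = np.concatenate([[0.0], np.cumsum(seg)])

    def t_of_u(u: np.ndarray) -> np.ndarray:
        return np.interp(u, s, t_grid)

    return t_of_u, float(s[-1])


def _sample_stem(spec: PlantSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.points_per_organ
    z = _stratified_1d(n, 0.0, spec.stem_height, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    pts = np.column_stack(
        [spec.stem_radius * np.cos(theta), spec.stem_radius * np.sin(theta), z]
    )
    if spec.noise_sigma > 0:
        pts += rng.normal(0.0, spec.noise_sigma, size=pts.shape)
    return pts


def _leaf_frame(azimuth: float, pitch: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u_hat = np.array(
        [np.cos(pitch) * np.cos(azimuth), np.cos(pitch) * np.sin(azimuth), np.sin(pitch)]
    )
    v_hat = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
    w_hat = np.cross(u_hat, v_hat)
    return u_hat, v_hat, w_hat


def _sample_leaf(
    spec: PlantSpec,
    blade_length: float,
    blade_width: float,
    attach_z: float,
    azimuth: float,
    pitch: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Points of one leaf = petiole strip + bent tapered blade."""
    u_hat, v_hat, w_hat = _leaf_frame(azimuth, pitch)
    base = np.array(
        [spec.stem_radius * np.cos(azimuth), spec.stem_radius * np.sin(azimuth), attach_z]
    )

    # petiole: narrow strip from the stem surface to the blade base
    n_pet = max(
        8,
        int(round(spec.points_per_organ * spec.petiole_length / max(blade_length, 1.0) * 0.5)),
    )
    s = _stratified_1d(n_pet, 0.0, spec.petiole_length, rng)
    lat = rng.uniform(-0.5, 0.5, size=n_pet)
    pet = base + s[:, None] * u_hat + lat[:, None] * v_hat

    # blade: stratified grid in (arc length u, relative width xi)
    n_blade = spec.points_per_organ
    nu = max(2, int(round(np.sqrt(n_blade * blade_length / blade_width))))
    nv = max(2, int(np.ceil(n_blade / nu)))
    du, dv = blade_length / nu, 1.0 / nv
    iu, iv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    u = (iu.ravel() + rng.uniform(0.3, 0.7, size=nu * nv)) * du
    xi = -1.0 + 2.0 * (iv.ravel() + rng.uniform(0.3, 0.7, size=nu * nv)) * dv

    t_of_u, _ = _arclength_param(blade_length, 0.08 * blade_length)
    t = t_of_u(u)
    bend = 0.08 * blade_length * np.sin(2.0 * np.pi * t / blade_length)
    half_width = 0.5 * blade_width * np.sqrt(np.sin(np.pi * np.clip(u / blade_length, 0, 1)))
    v = xi * half_width

    blade_origin = base + spec.petiole_length * u_hat
    blade = blade_origin + t[:, None] * u_hat + v[:, None] * v_hat + bend[:, None] * w_hat

    pts = np.vstack([pet, blade])
    if spec.noise_sigma > 0:
        pts += rng.normal(0.0, spec.noise_sigma, size=pts.shape)
    return pts


def generate_plant(spec: PlantSpec) -> tuple[LabeledPointCloud, GroundTruthTraits]:
    """Generate one plant cloud with labels, instance IDs and true traits.

    Stem points get semantic ``STEM`` and instance 0; each leaf (petiole +
    blade) gets semantic ``LEAF`` and instance ID ``1..n_leaves``.  The same
    spec (including its ``seed``) always yields the identical cloud.
    """
    rng = np.random.default_rng(spec.seed)
    parts, semantics, instances = [], [], []

    stem = _sample_stem(spec, rng)
    parts.append(stem)
    semantics.append(np.full(len(stem), STEM))
    instances.append(np.zeros(len(stem), dtype=np.int64))

    lo_l, hi_l = _as_range(spec.leaf_length)
    lo_w, hi_w = _as_range(spec.leaf_width)
    leaves: list[tuple[int, float, float]] = []
    phase = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(spec.n_leaves):
        blade_length = rng.uniform(lo_l, hi_l)
        blade_width = rng.uniform(lo_w, hi_w)
        attach_z = spec.stem_height * (0.35 + 0.6 * (i + 0.5) / spec.n_leaves)
        azimuth = (phase + i * _GOLDEN_ANGLE) % (2.0 * np.pi)
        pitch = rng.uniform(np.deg2rad(10.0), np.deg2rad(30.0))
        pts = _sample_leaf(spec, blade_length, blade_width, attach_z, azimuth, pitch, rng)
        parts.append(pts)
        semantics.append(np.full(len(pts), LEAF))
        instances.append(np.full(len(pts), i + 1, dtype=np.int64))
        leaves.append((i + 1, spec.petiole_length + blade_length, blade_width))

    cloud = LabeledPointCloud(
        coords=np.vstack(parts),
        semantic=np.concatenate(semantics),
        instance=np.concatenate(instances),
        id=f"plant-{spec.seed}",
    )
    if spec.ghost_fraction > 0 or spec.gap_fraction > 0:
        cloud = inject_artifacts(
            cloud, spec.ghost_fraction, spec.gap_fraction,
            seed=int(rng.integers(2**31)),
        )
    traits = GroundTruthTraits(stem_diameter=2.0 * spec.stem_radius, leaves=leaves)
    return cloud, traits


def inject_artifacts(
    cloud: LabeledPointCloud,
    ghost_fraction: float,
    gap_fraction: float,
    seed: int = 0,
    gap_disk_radius: float = 3.0,
) -> LabeledPointCloud:
    """Emulate multi-view-stereo defects: ghost points beside the stem and
    circular holes in the leaves.

    Adds ``floor(ghost_fraction * N)`` jittered copies of random stem points,
    displaced 0.5–2 mm horizontally and labelled stem; deletes leaf points
    inside randomly placed disks (radius ``gap_disk_radius``) until about
    ``gap_fraction`` of the leaf points are gone.  Surviving points keep
    their labels and order; ghosts are appended at the end.
    """
    for name, v in (("ghost_fraction", ghost_fraction), ("gap_fraction", gap_fraction)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {v!r}")
    if ghost_fraction == 0.0 and gap_fraction == 0.0:
        return cloud

    rng = np.random.default_rng(seed)
    n = len(cloud)
    keep = np.ones(n, dtype=bool)

    leaf_idx = np.flatnonzero(cloud.semantic == LEAF)
    if gap_fraction > 0 and leaf_idx.size:
        target = int(np.floor(gap_fraction * leaf_idx.size))
        removed = 0
        guard = 0
        while removed < target and guard < 10 * len(leaf_idx):
            guard += 1
            alive = leaf_idx[keep[leaf_idx]]
            if alive.size == 0:
                break
            center_i = alive[rng.integers(alive.size)]
            center = cloud.coords[center_i]
            same = alive[cloud.instance[alive] == cloud.instance[center_i]]
            d = np.linalg.norm(cloud.coords[same] - center, axis=1)
            hit = same[d <= gap_disk_radius]
            keep[hit] = False
            removed += hit.size

    ghosts = None
    n_ghost = int(np.floor(ghost_fraction * n))
    if n_ghost > 0:
        stem_idx = np.flatnonzero(cloud.semantic == STEM)
        if stem_idx.size == 0:
            raise ValidationError("ghost injection needs at least one stem point")
        src = stem_idx[rng.integers(stem_idx.size, size=n_ghost)]
        angle = rng.uniform(0.0, 2.0 * np.pi, size=n_ghost)
        mag = rng.uniform(0.5, 2.0, size=n_ghost)
        offset = np.column_stack(
            [mag * np.cos(angle), mag * np.sin(angle), np.zeros(n_ghost)]
        )
        ghosts = cloud.coords[src] + offset

    survivors = cloud.select(keep)
    if ghosts is None:
        return survivors
    coords = np.vstack([survivors.coords, ghosts])
    semantic = np.concatenate([survivors.semantic, np.full(n_ghost, STEM)])
    instance = np.concatenate([survivors.instance, np.zeros(n_ghost, dtype=np.int64)])
    colors = None
    if survivors.colors is not None:
        colors = np.vstack([survivors.colors, survivors.colors[:1].repeat(n_ghost, axis=0)])
    return LabeledPointCloud(
        coords=coords, colors=colors, semantic=semantic, instance=instance, id=cloud.id
    )


#: default parameter ranges for :func:`generate_dataset`
DEFAULT_SPEC_RANGES: dict[str, ScalarOrRange | tuple[int, int]] = {
    "stem_height": (90.0, 150.0),
    "stem_radius": (1.0, 2.5),
    "n_leaves": (2, 5),
    "leaf_length": (25.0, 50.0),
    "leaf_width": (12.0, 25.0),
    "petiole_length": (5.0, 10.0),
    "points_per_organ": 700,
    "noise_sigma": 0.05,
    "ghost_fraction": 0.0,
    "gap_fraction": 0.0,
}


def generate_dataset(
    n_plants: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
) -> list[tuple[LabeledPointCloud, GroundTruthTraits]]:
    """Generate ``n_plants`` plants with spec parameters drawn uniformly from
    ``spec_ranges`` (scalar = fixed, 2-tuple = uniform range) under one master
    seed; per-plant seeds are derived deterministically."""
    if n_plants < 1:
        raise ValidationError("n_plants must be >= 1")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        unknown = set(spec_ranges) - set(ranges)
        if unknown:
            raise ValidationError(f"unknown spec parameters: {sorted(unknown)}")
        ranges.update(spec_ranges)
    for k, v in ranges.items():
        lo, hi = _as_range(v) if not isinstance(v, (int, float)) else (v, v)
        if hi < lo:
            raise ValidationError(f"empty range for {k}: {v!r}")

    master = np.random.default_rng(seed)
    child_seeds = master.integers(2**31, size=n_plants)
    out = []
    for i in range(n_plants):
        rng = np.random.default_rng(child_seeds[i])

        def draw(key: str, integer: bool = False):
            v = ranges[key]
            lo, hi = _as_range(v)
            if lo == hi:
                return int(lo) if integer else lo
            if integer:
                return int(rng.integers(int(lo), int(hi) + 1))
            return float(rng.uniform(lo, hi))

        spec = PlantSpec(
            stem_height=draw("stem_height"),
            stem_radius=draw("stem_radius"),
            n_leaves=draw("n_leaves", integer=True),
            leaf_length=_as_range(ranges["leaf_length"]),
            leaf_width=_as_range(ranges["leaf_width"]),
            petiole_length=draw("petiole_length"),
            points_per_organ=int(draw("points_per_organ")),
            noise_sigma=float(draw("noise_sigma")),
            ghost_fraction=float(draw("ghost_fraction")),
            gap_fraction=float(draw("gap_fraction")),
            seed=int(child_seeds[i]),
        )
        cloud, traits = generate_plant(spec)
        cloud.id = f"plant-{i:03d}"
        out.append((cloud, traits))
    return out


__all__ = [
    "PlantSpec",
    "GroundTruthTraits",
    "generate_plant",
    "inject_artifacts",
    "generate_dataset",
    "DEFAULT_SPEC_RANGES",
]
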