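"""Core point-cloud container shared by every stage of the pipeline.

A :class:`LabeledPointCloud` holds per-point 3D coordinates in millimetres,
optional RGB colors in [0, 1], a semantic label per point (stem / leaf / soil,
or the unlabeled sentinel) and a leaf-instance ID per point.  It is the
universal exchange object between the synthetic generator, the I/O layer, the
networks and the trait extractors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Project-wide label coding (stable cross-module contract).
STEM = 0
LEAF = 1
SOIL = 2
UNLABELED = -1

#: instance sentinel: 0 = stem / no instance, -1 = unlabeled
NO_INSTANCE = 0

LABEL_NAMES = {STEM: "stem", LEAF: "leaf", SOIL: "soil", UNLABELED: "unlabeled"}


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class LabeledPointCloud:
    """Point cloud with optional per-point semantics and leaf-instance IDs.

    Parameters
    ----------
    coords:
        ``(N, 3)`` float array, millimetres.
    colors:
        Optional ``(N, 3)`` float array in ``[0, 1]``.
    semantic:
        ``(N,)`` int array with values in ``{STEM, LEAF, SOIL, UNLABELED}``.
    instance:
        ``(N,)`` int array; ``>= 1`` on leaf instances, ``0`` for stem/none,
        ``-1`` for unlabeled.
    """

    coords: np.ndarray
    colors: np.ndarray | None = None
    semantic: np.ndarray = field(default=None)  # type: ignore[assignment]
    instance: np.ndarray = field(default=None)  # type: ignore[assignment]
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValidationError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords contain non-finite values")
        n = self.coords.shape[0]
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64)
            if self.colors.shape != (n, 3):
                raise ValidationError(f"colors must be (N, 3), got {self.colors.shape}")
        if self.semantic is None:
            self.semantic = np.full(n, UNLABELED, dtype=np.int64)
        else:
            self.semantic = np.asarray(self.semantic, dtype=np.int64)
            if self.semantic.shape != (n,):
                raise ValidationError("semantic must be (N,)")
        if self.instance is None:
            self.instance = np.full(n, UNLABELED, dtype=np.int64)
        else:
            self.instance = np.asarray(self.instance, dtype=np.int64)
            if self.instance.shape != (n,):
                raise ValidationError("instance must be (N,)")
        # instance annotated implies semantic annotated
        if np.any((self.instance != UNLABELED) & (self.semantic == UNLABELED)):
            raise ValidationError(
                "points with an annotated instance must carry a semantic label"
            )

    def __len__(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_points(self) -> int:
        return len(self)

    def select(self, index: np.ndarray, id_suffix: str = "") -> "LabeledPointCloud":
        """Return the sub-cloud at ``index`` (bool mask or integer indices)."""
        index = np.asarray(index)
        return LabeledPointCloud(
            coords=self.coords[index],
            colors=None if self.colors is None else self.colors[index],
            semantic=self.semantic[index],
            instance=self.instance[index],
            id=self.id + id_suffix,
        )

    def copy(self) -> "LabeledPointCloud":
        return LabeledPointCloud(
            coords=self.coords.copy(),
            colors=None if self.colors is None else self.colors.copy(),
            semantic=self.semantic.copy(),
            instance=self.instance.copy(),
            id=self.id,
        )

    def with_coords(self, coords: np.ndarray) -> "LabeledPointCloud":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=np.float64)
        if out.coords.shape != self.coords.shape:
            raise ValidationError("replacement coords must keep the same shape")
        return out

    def is_fully_labeled(self) -> bool:
        return bool(np.all(self.semantic != UNLABELED))

    def equal_to(self, other: "LabeledPointCloud", atol: float = 0.0) -> bool:
        """Field-wise equality; ``atol`` allows coordinate round-off."""
        if len(self) != len(other):
            return False
        if not np.allclose(self.coords, other.coords, atol=atol, rtol=0.0):
            return False
        if (self.colors is None) != (other.colors is None):
            return False
        if self.colors is not None and not np.allclose(
            self.colors, other.colors, atol=max(atol, 1e-9), rtol=0.0
        ):
            return False
        return bool(
            np.array_equal(self.semantic, other.semantic)
            and np.array_equal(self.instance, other.instance)
        )


__all__ = [
    "LabeledPointCloud",
    "ValidationError",
    "STEM",
    "LEAF",
    "SOIL",
    "UNLABELED",
    "NO_INSTANCE",
    "LABEL_NAMES",
]
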