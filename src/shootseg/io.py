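"""Reading/writing labeled point clouds and weak-annotation generation.

Two on-disk dialects are supported, both plain text:

* **TXT** — whitespace-delimited ``x y z [red green blue] [semantic instance]``
  with a one-line ``#``-prefixed header naming the columns (the plain
  per-point label files shipped with public plant datasets, but
  self-describing).  A headerless file with exactly three columns is
  accepted as bare coordinates.
* **PLY** — ASCII PLY with float properties ``x y z [red green blue]
  [semantic instance]``.

Weak annotation follows the annotation-efficient protocol: optionally
down-sample the cloud by a ratio factor, then keep the original labels on k
randomly chosen points and set every other point's labels to the unlabeled
sentinel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import LEAF, SOIL, STEM, UNLABELED, LabeledPointCloud, ValidationError

_FLOAT_FMT = "%.6f"
_KNOWN_CLASSES = {STEM, LEAF, SOIL}


class ParseError(ValueError):
    """Malformed point-cloud file; the message names the offending line."""


def _columns_of(cloud: LabeledPointCloud) -> list[str]:
    cols = ["x", "y", "z"]
    if cloud.colors is not None:
        cols += ["red", "green", "blue"]
    if np.any(cloud.semantic != UNLABELED) or np.any(cloud.instance != UNLABELED):
        cols += ["semantic", "instance"]
    return cols


def _rows_of(cloud: LabeledPointCloud, cols: list[str]) -> np.ndarray:
    parts = [cloud.coords]
    if "red" in cols:
        parts.append(cloud.colors)
    if "semantic" in cols:
        parts.append(cloud.semantic[:, None].astype(float))
        parts.append(cloud.instance[:, None].astype(float))
    return np.hstack(parts)


def write_point_cloud(cloud: LabeledPointCloud, path: str | Path, format: str | None = None) -> None:
    """Write ``cloud`` to ``path`` in the TXT or PLY dialect.

    The format is taken from the file suffix when not given explicitly.
    Output is deterministic: fixed column order and fixed float formatting,
    so two writes of the same cloud are byte-identical.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    cols = _columns_of(cloud)
    rows = _rows_of(cloud, cols)

    def fmt_row(row: np.ndarray) -> str:
        fields = [_FLOAT_FMT % v for v in row[: len(cols) - (2 if "semantic" in cols else 0)]]
        if "semantic" in cols:
            fields += [str(int(row[-2])), str(int(row[-1]))]
        return " ".join(fields)

    lines: list[str]
    if fmt == "txt":
        lines = ["# " + " ".join(cols)]
        lines += [fmt_row(r) for r in rows]
    elif fmt == "ply":
        lines = ["ply", "format ascii 1.0", f"element vertex {len(cloud)}"]
        for c in cols:
            kind = "int" if c in ("semantic", "instance") else "float"
            lines.append(f"property {kind} {c}")
        lines.append("end_header")
        lines += [fmt_row(r) for r in rows]
    else:
        raise ValidationError(f"unknown point-cloud format {fmt!r}")
    path.write_text("\n".join(lines) + "\n")


def _assemble(data: np.ndarray, cols: list[str], cloud_id: str) -> LabeledPointCloud:
    idx = {c: i for i, c in enumerate(cols)}
    coords = data[:, [idx["x"], idx["y"], idx["z"]]]
    colors = data[:, [idx["red"], idx["green"], idx["blue"]]] if "red" in idx else None
    n = data.shape[0]
    semantic = (
        data[:, idx["semantic"]].astype(np.int64) if "semantic" in idx
        else np.full(n, UNLABELED, dtype=np.int64)
    )
    instance = (
        data[:, idx["instance"]].astype(np.int64) if "instance" in idx
        else np.full(n, UNLABELED, dtype=np.int64)
    )
    return LabeledPointCloud(coords, colors, semantic, instance, id=cloud_id)


def _parse_rows(lines: list[str], n_cols: int, first_lineno: int) -> np.ndarray:
    out = np.empty((len(lines), n_cols))
    for i, line in enumerate(lines):
        fields = line.split()
        if len(fields) != n_cols:
            raise ParseError(
                f"line {first_lineno + i}: expected {n_cols} columns, got {len(fields)}"
            )
        try:
            out[i] = [float(f) for f in fields]
        except ValueError as exc:
            raise ParseError(f"line {first_lineno + i}: {exc}") from None
    return out


def read_point_cloud(path: str | Path, format: str | None = None) -> LabeledPointCloud:
    """Read a TXT or PLY cloud; missing label columns become UNLABELED."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if fmt == "txt":
        if lines and lines[0].lstrip().startswith("#"):
            cols = lines[0].lstrip("# ").split()
            body, first = lines[1:], 2
        else:
            cols = ["x", "y", "z"]
            body, first = lines, 1
            if body and len(body[0].split()) != 3:
                raise ParseError(
                    "line 1: headerless TXT must have exactly 3 columns (x y z)"
                )
        data = _parse_rows(body, len(cols), first)
        return _assemble(data, cols, path.stem)
    if fmt == "ply":
        if not lines or lines[0].strip() != "ply":
            raise ParseError("line 1: not an ASCII PLY file")
        cols: list[str] = []
        n_vertex = None
        header_end = None
        for i, ln in enumerate(lines):
            t = ln.split()
            if t[:2] == ["element", "vertex"]:
                n_vertex = int(t[2])
            elif t and t[0] == "property":
                cols.append(t[-1])
            elif t == ["end_header"]:
                header_end = i
                break
        if header_end is None or n_vertex is None:
            raise ParseError("PLY header missing end_header or element vertex")
        body = lines[header_end + 1 : header_end + 1 + n_vertex]
        if len(body) < n_vertex:
            raise ParseError(f"expected {n_vertex} vertex rows, found {len(body)}")
        data = _parse_rows(body, len(cols), header_end + 2)
        return _assemble(data, cols, path.stem)
    raise ValidationError(f"unknown point-cloud format {fmt!r}")


def remove_class(cloud: LabeledPointCloud, class_label: int) -> LabeledPointCloud:
    """Drop all points of one semantic class (e.g. soil), preserving order."""
    if class_label not in _KNOWN_CLASSES:
        raise ValidationError(f"unknown class label {class_label!r}")
    keep = cloud.semantic != class_label
    if not np.any(keep):
        raise ValidationError("removing this class would leave an empty cloud")
    return cloud.select(keep)


def downsample_random(cloud: LabeledPointCloud, ratio: float, seed: int = 0) -> LabeledPointCloud:
    """Uniform random down-sampling without replacement, keeping
    ``ceil(ratio * N)`` points; survivor order is preserved."""
    if not (0.0 < ratio <= 1.0):
        raise ValidationError(f"ratio must be in (0, 1], got {ratio!r}")
    n = len(cloud)
    k = int(np.ceil(ratio * n))
    if k >= n:
        return cloud.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return cloud.select(idx)


def make_weak_annotation(cloud: LabeledPointCloud, k: int, seed: int = 0) -> LabeledPointCloud:
    """Keep labels on ``min(k, N)`` random points; unlabel everything else.

    Requires a fully labeled input (weak annotation derives from full
    labels).  Coordinates and colors are untouched.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k!r}")
    if not cloud.is_fully_labeled():
        raise ValidationError("weak annotation requires a fully labeled cloud")
    n = len(cloud)
    out = cloud.copy()
    if k >= n:
        return out
    rng = np.random.default_rng(seed)
    keep = rng.choice(n, size=k, replace=False)
    mask = np.ones(n, dtype=bool)
    mask[keep] = False
    out.semantic[mask] = UNLABELED
    out.instance[mask] = UNLABELED
    return out


def write_traits_csv(rows: list[dict], path: str | Path) -> None:
    """Write a long-format trait table (plant_id, instance_id, trait, value_mm)."""
    pd.DataFrame(rows, columns=["plant_id", "instance_id", "trait", "value_mm"]).to_csv(
        path, index=False
    )


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"plant_id", "instance_id", "trait", "value_mm"}
    if not expected.issubset(df.columns):
        raise ParseError(f"trait table must have columns {sorted(expected)}")
    return df


__all__ = [
    "ParseError",
    "read_point_cloud",
    "write_point_cloud",
    "remove_class",
    "downsample_random",
    "make_weak_annotation",
    "write_traits_csv",
    "read_traits_csv",
]
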