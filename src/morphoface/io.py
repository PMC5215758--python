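"""Reading and writing of the dataset formats.

Landmark configurations travel in TPS files (the de-facto dialect written by
the TPSdig family of digitizing programs: an ``LM=<k>`` count line followed by
``k`` whitespace-separated coordinate pairs, with optional ``ID=``, ``IMAGE=``
and ``SCALE=`` key lines per record).  Covariates travel in a CSV with columns
``id``, ``bmi``, ``whr``.  Photographs are ordinary 8- or 16-bit PNG/JPEG.

Coordinate convention: TPS files store y increasing *upward*, whereas image
arrays index rows downward.  Coordinates are kept exactly as written; the one
documented flip (``row = height - 1 - y``) is applied at image-sampling time
only (see :mod:`morphoface.warping`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml


class TpsParseError(ValueError):
    """Raised when a TPS landmark file is malformed."""


@dataclass
class LandmarkConfiguration:
    """Raw digitized 2D points for one specimen, in image pixel coordinates."""

    specimen_id: str
    points: np.ndarray  # (k, 2) float
    image_ref: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinate in specimen {self.specimen_id!r}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class SemilandmarkScheme:
    """Which landmarks are anatomical, which slide, and which enter each analysis.

    ``curves`` are ordered landmark-index sequences along digitized curves;
    curve *interior* points are semilandmarks free to slide along the local
    tangent, while ``fixed_indices`` (anatomical landmarks and curve endpoints)
    never move.  ``shape_subset`` selects the points entering the shape
    analysis; ``warp_set`` the (super)set used for image warping.
    """

    n_points: int
    curves: list[list[int]] = field(default_factory=list)
    fixed_indices: list[int] = field(default_factory=list)
    shape_subset: list[int] = field(default_factory=list)
    warp_set: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.warp_set:
            self.warp_set = list(range(self.n_points))
        if not self.shape_subset:
            self.shape_subset = list(range(self.n_points))
        all_idx = (
            [i for c in self.curves for i in c]
            + self.fixed_indices
            + self.shape_subset
            + self.warp_set
        )
        if any(i < 0 or i >= self.n_points for i in all_idx):
            raise ValueError("landmark index out of range")
        if not set(self.shape_subset) <= set(self.warp_set):
            raise ValueError("shape_subset must be a subset of warp_set")
        seen: set[int] = set()
        interiors: set[int] = set()
        for c in self.curves:
            if len(set(c)) != len(c):
                raise ValueError("repeated index within a curve")
            if seen & set(c):
                raise ValueError("an index appears in two curves")
            seen |= set(c)
            interiors |= set(c[1:-1])
        if interiors & set(self.fixed_indices):
            raise ValueError("fixed index inside a curve interior")

    @property
    def sliding_indices(self) -> list[int]:
        """Interior curve points, i.e. the semilandmarks that slide."""
        out: list[int] = []
        for c in self.curves:
            out.extend(c[1:-1])
        return sorted(set(out) - set(self.fixed_indices))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_points": int(self.n_points),
            "curves": [[int(i) for i in c] for c in self.curves],
            "fixed_indices": [int(i) for i in self.fixed_indices],
            "shape_subset": [int(i) for i in self.shape_subset],
            "warp_set": [int(i) for i in self.warp_set],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SemilandmarkScheme":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


_KEY_RE = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file into a list of configurations, in file order.

    Raises :class:`TpsParseError` (naming the offending record) on a malformed
    count line, a non-numeric coordinate, or point counts that differ across
    records.  ``SCALE=`` is stored but never applied to the coordinates.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEY_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TpsParseError(f"{path}: record {record}: expected LM= line, got {line!r}")
        try:
            k = int(m.group(2))
        except ValueError:
            raise TpsParseError(f"{path}: record {record}: bad LM count {m.group(2)!r}") from None
        i += 1
        pts = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= len(lines):
                raise TpsParseError(f"{path}: record {record}: truncated coordinate block")
            parts = lines[i].split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"{path}: record {record}: expected 2 coordinates on line {i + 1}"
                )
            try:
                pts[j] = [float(parts[0]), float(parts[1])]
            except ValueError:
                raise TpsParseError(
                    f"{path}: record {record}: non-numeric coordinate on line {i + 1}"
                ) from None
            i += 1
        spec_id: str | None = None
        image_ref: str | None = None
        scale: float | None = None
        while i < len(lines):
            m = _KEY_RE.match(lines[i].strip())
            if not m or m.group(1).upper() == "LM":
                break
            key, val = m.group(1).upper(), m.group(2)
            if key == "ID":
                spec_id = val
            elif key == "IMAGE":
                image_ref = val
            elif key == "SCALE":
                try:
                    scale = float(val)
                except ValueError:
                    raise TpsParseError(
                        f"{path}: record {record}: bad SCALE value {val!r}"
                    ) from None
            i += 1
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id if spec_id is not None else str(record),
                points=pts,
                image_ref=image_ref,
                scale=scale,
            )
        )
        record += 1
    counts = {c.n_points for c in configs}
    if len(counts) > 1:
        raise TpsParseError(f"{path}: inconsistent point counts across records: {sorted(counts)}")
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file re-readable by :func:`read_tps`."""
    if not configs:
        raise ValueError("empty configuration list")
    counts = {c.n_points for c in configs}
    if len(counts) > 1:
        raise ValueError(f"unequal point counts: {sorted(counts)}")
    out: list[str] = []
    for c in configs:
        out.append(f"LM={c.n_points}")
        for x, y in c.points:
            out.append(f"{x:.10g} {y:.10g}")
        if c.image_ref is not None:
            out.append(f"IMAGE={c.image_ref}")
        if c.scale is not None:
            out.append(f"SCALE={c.scale:.10g}")
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the covariate CSV into a DataFrame indexed by specimen id.

    Expects columns ``id``, ``bmi`` (kg/m^2) and ``whr`` (dimensionless),
    case-insensitively.  Duplicate ids, non-numeric cells, and non-positive
    values are hard errors naming the row.
    """
    df = pd.read_csv(path, dtype={0: str})
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "bmi", "whr"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate specimen id {dup.iloc[0]!r}")
    for col in ("bmi", "whr"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} in row {bad[0] + 2}")
        nonpos = df.index[vals <= 0]
        if len(nonpos):
            raise ValueError(f"{path}: non-positive {col} in row {nonpos[0] + 2}")
        df[col] = vals.astype(float)
    return df[["id", "bmi", "whr"]].set_index("id")


def load_image(path: str | Path) -> np.ndarray:
    """Load an RGB image as an (H, W, 3) float array with values in [0, 1].

    8- and 16-bit inputs are rescaled by their dtype maximum; an alpha channel
    is dropped.  Grayscale images are rejected: the texture analysis is defined
    on three color channels.
    """
    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path}: expected an RGB(A) image, got shape {arr.shape}")
    arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        out = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        out = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(float)
    else:
        raise ValueError(f"{path}: unsupported image dtype {arr.dtype}")
    if out.min() < 0 or out.max() > 1:
        raise ValueError(f"{path}: image values outside [0, 1]")
    return out


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Save an (H, W, 3) float array in [0, 1] as an 8-bit image file."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) array")
    iio.imwrite(Path(path), (np.clip(arr, 0.0, 1.0) * 255.0).round().astype(np.uint8))
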