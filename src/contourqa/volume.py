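"""Volumes, binary organ masks, structure sets, and NIfTI / report I/O.

All spatial data lives on a regular 3D grid with physical voxel spacing in
millimetres. The in-memory axis convention is ``(x, y, z)`` with ``x`` the
in-plane column, ``y`` the in-plane row, and ``z`` the slice index; volumes
read from disk are reoriented to the closest-to-canonical (RAS) orientation
so slice-wise operations always iterate the last axis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

#: The twelve upper-abdominal organs-at-risk this toolkit was designed around.
CANONICAL_ORGANS = (
    "aorta",
    "large_bowel",
    "small_bowel",
    "duodenum",
    "esophagus",
    "left_kidney",
    "right_kidney",
    "liver",
    "pancreas",
    "spinal_cord",
    "spleen",
    "stomach",
)

#: Fixed column schema for per-organ metric reports.
REPORT_COLUMNS = (
    "case_id",
    "organ",
    "dsc",
    "mda_mm",
    "hd95_mm",
    "pvd_pct",
    "sdsc",
    "apl_mm",
    "rapl_mm_per_cc",
    "ref_volume_cc",
    "auto_volume_cc",
    "flags",
)


class GeometryError(ValueError):
    """Raised when paired grids disagree in shape or spacing."""


def _validate_geometry(data: np.ndarray, spacing, name: str) -> tuple[float, float, float]:
    if data.ndim != 3:
        raise ValueError(f"{name} must be 3-dimensional, got shape {data.shape}")
    if any(s < 1 for s in data.shape):
        raise ValueError(f"{name} axes must each have length >= 1, got {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError("spacing must have three components")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing components must be positive and finite, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data:
        3D floating-point array indexed ``(x, y, z)``.
    spacing:
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all strictly positive.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = _validate_geometry(self.data, self.spacing, "ImageVolume.data")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """New volume on the same grid (shape must match)."""
        if tuple(np.shape(data)) != self.shape:
            raise GeometryError("replacement data must keep the grid shape")
        return ImageVolume(np.asarray(data, dtype=np.float64), self.spacing, self.origin)


@dataclass
class BinaryMask:
    """A binary organ mask on the same kind of grid as :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        self.spacing = _validate_geometry(self.data, self.spacing, "BinaryMask.data")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        """Mask volume in cubic centimetres (voxel count x voxel volume)."""
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def is_empty(self) -> bool:
        return not self.data.any()

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        if tuple(np.shape(data)) != self.shape:
            raise GeometryError("replacement data must keep the grid shape")
        return BinaryMask(np.asarray(data) != 0, self.spacing, self.origin)


def same_geometry(a, b, atol: float = 1e-6) -> bool:
    return a.shape == b.shape and np.allclose(a.spacing, b.spacing, atol=atol)


def require_same_geometry(a, b) -> None:
    """Fail loudly before any pairwise computation on mismatched grids."""
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=1e-6):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


@dataclass
class StructureSet:
    """Named binary organ masks sharing one grid geometry."""

    organs: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.organs)
        for name in names[1:]:
            require_same_geometry(self.organs[names[0]], self.organs[name])

    @property
    def names(self) -> list[str]:
        return list(self.organs)

    @property
    def geometry(self) -> tuple:
        first = next(iter(self.organs.values()))
        return (first.shape, first.spacing, first.origin)

    def __getitem__(self, name: str) -> BinaryMask:
        return self.organs[name]

    def __len__(self) -> int:
        return len(self.organs)

    def __contains__(self, name: str) -> bool:
        return name in self.organs

    def items(self):
        return self.organs.items()

    def add(self, name: str, mask: BinaryMask) -> None:
        if self.organs:
            require_same_geometry(next(iter(self.organs.values())), mask)
        self.organs[name] = mask


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_from_geometry(spacing, origin) -> np.ndarray:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    return affine


def read_volume(path) -> ImageVolume:
    """Read a 3D NIfTI volume, reorienting to the canonical axis order.

    Spacing is taken from the header (mm); intensities are widened to
    float64.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(vol: ImageVolume, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(vol.data, dtype=np.float32),
        _affine_from_geometry(vol.spacing, vol.origin),
    )
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.spacing, vol.origin)


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8),
        _affine_from_geometry(mask.spacing, mask.origin),
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def write_label_map(structures: StructureSet, label_table: Mapping[int, str], path) -> None:
    """Write a structure set as one integer label map (later labels win overlaps)."""
    shape, spacing, origin = structures.geometry
    out = np.zeros(shape, dtype=np.int16)
    name_to_label = {v: k for k, v in label_table.items()}
    for name, mask in structures.items():
        out[mask.data] = name_to_label[name]
    img = nib.Nifti1Image(out, _affine_from_geometry(spacing, origin))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def load_label_table(path) -> dict[int, str]:
    """Load a JSON label table mapping integer labels to organ names."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def read_structures(label_map_path, label_table: Mapping[int, str]) -> StructureSet:
    """Split an integer label map into one BinaryMask per named label.

    Labels listed in ``label_table`` but absent from the volume produce empty
    masks and a warning; 0 is always background.
    """
    names = list(label_table.values())
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate organ names in label table: {names}")
    if 0 in label_table:
        raise ValueError("label 0 is reserved for background")
    vol = read_volume(label_map_path)
    labels = np.rint(vol.data).astype(np.int64)
    present = set(np.unique(labels).tolist())
    organs: dict[str, BinaryMask] = {}
    for label, name in label_table.items():
        if label not in present:
            warnings.warn(f"label {label} ({name}) not present in {label_map_path}; "
                          "creating empty mask", stacklevel=2)
        organs[name] = BinaryMask(labels == label, vol.spacing, vol.origin)
    return StructureSet(organs)


def structures_from_masks(masks: Mapping[str, BinaryMask]) -> StructureSet:
    """Build a structure set from per-organ masks (overlap permitted)."""
    return StructureSet(dict(masks))


# ---------------------------------------------------------------------------
# Metric / grade reports
# ---------------------------------------------------------------------------

def report_frame(records: Iterable[Mapping]) -> pd.DataFrame:
    records = list(records)
    if not records:
        raise ValueError("cannot build a report from an empty result collection")
    df = pd.DataFrame(records)
    missing = [c for c in ("case_id", "organ") if c not in df.columns]
    if missing:
        raise ValueError(f"report records missing required fields: {missing}")
    ordered = [c for c in REPORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def write_report(records: Iterable[Mapping], path, format: str = "csv") -> None:
    """Write one row per (case, organ) with metrics, categories, and scores.

    Numeric formatting is locale independent; CSV uses full ``repr``
    precision so a re-parsed report equals the in-memory values.
    """
    df = report_frame(records)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        df.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'csv' or 'json')")


def read_report(path, format: str = "csv") -> pd.DataFrame:
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        return pd.read_json(path, orient="records")
    raise ValueError(f"unknown report format {format!r}")
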