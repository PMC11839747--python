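"""Typed containers and I/O for fat-water images, muscle label maps and cohort tables.

All computation downstream happens in voxel space; the NIfTI affine is used
only to derive the voxel volume. Label maps must be supplied on the image
grid — nothing in this package resamples silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical encoding of the ten muscle groups (five per leg). Integer 0 is
#: background. Order: left leg 1-5, right leg 6-10, each leg in the order
#: anterior compartment (AC), deep posterior compartment (DPC), lateral
#: compartment (LC), soleus, gastrocnemius.
MUSCLE_LABELS: Mapping[int, tuple[str, str]] = {
    1: ("anterior_compartment", "left"),
    2: ("deep_posterior_compartment", "left"),
    3: ("lateral_compartment", "left"),
    4: ("soleus", "left"),
    5: ("gastrocnemius", "left"),
    6: ("anterior_compartment", "right"),
    7: ("deep_posterior_compartment", "right"),
    8: ("lateral_compartment", "right"),
    9: ("soleus", "right"),
    10: ("gastrocnemius", "right"),
}

MUSCLE_NAMES = ("anterior_compartment", "deep_posterior_compartment",
                "lateral_compartment", "soleus", "gastrocnemius")

#: Columns of a muscle-measures table as written by :func:`write_measures`.
MEASURE_COLUMNS = ("participant_id", "source", "muscle", "side",
                   "volume_ml", "imf_pct", "n_voxels", "n_voxels_eroded",
                   "eroded_flag")

AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes do not share a voxel grid (shape or affine differ)."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel grid geometry: array dims plus the voxel-to-world affine (mm)."""

    affine: np.ndarray  # 4x4
    dims: tuple[int, int, int]

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        object.__setattr__(self, "affine", aff)
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        object.__setattr__(self, "dims", dims)
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("affine has a singular spatial part (zero voxel volume)")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.affine)[:3, :3])))

    def matches(self, other: "VoxelGeometry", atol: float = AFFINE_ATOL) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0)

    def require_match(self, other: "VoxelGeometry", what: str = "volumes") -> None:
        if self.dims != other.dims:
            raise GridMismatchError(
                f"{what} have different shapes: {self.dims} vs {other.dims}")
        if not np.allclose(self.affine, other.affine, atol=AFFINE_ATOL, rtol=0.0):
            raise GridMismatchError(
                f"{what} have different affines (element-wise difference > {AFFINE_ATOL})")


@dataclass(frozen=True)
class FatWaterVolume:
    """Paired fat- and water-signal 3D images on a shared grid.

    Signal units are arbitrary but must be consistent between the two
    channels; the fat fraction is invariant to a common rescaling.
    """

    fat: np.ndarray
    water: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self):
        fat = np.asarray(self.fat, dtype=float)
        water = np.asarray(self.water, dtype=float)
        if fat.shape != water.shape:
            raise GridMismatchError(
                f"fat and water shapes differ: {fat.shape} vs {water.shape}")
        if fat.shape != self.geometry.dims:
            raise GridMismatchError(
                f"array shape {fat.shape} does not match geometry dims {self.geometry.dims}")
        for name, arr in (("fat", fat), ("water", water)):
            if (arr < 0).any():
                logger.warning("negative %s intensities clamped to 0 "
                               "(%d voxels)", name, int((arr < 0).sum()))
                arr = np.clip(arr, 0.0, None)
            object.__setattr__(self, name, arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.geometry.dims


@dataclass(frozen=True)
class LabelMap:
    """Integer multi-label muscle mask on the same grid as the images."""

    labels: np.ndarray
    geometry: VoxelGeometry
    label_table: Mapping[int, tuple[str, str]] = field(
        default_factory=lambda: dict(MUSCLE_LABELS))

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("label map contains non-integral voxel values")
            arr = np.round(arr).astype(np.int16)
        if arr.shape != self.geometry.dims:
            raise GridMismatchError(
                f"label shape {arr.shape} does not match geometry dims {self.geometry.dims}")
        present = set(np.unique(arr).tolist()) - {0}
        unknown_canon = present - set(MUSCLE_LABELS)
        if unknown_canon:
            raise ValueError(
                f"label values {sorted(unknown_canon)} are outside the canonical "
                f"10-muscle table (valid: 1..10)")
        unknown = present - set(self.label_table)
        if unknown:
            raise ValueError(
                f"label values {sorted(unknown)} missing from the supplied label table")
        object.__setattr__(self, "labels", arr)
        object.__setattr__(self, "label_table", dict(self.label_table))
        if not present:
            logger.warning("label map is empty (all background)")

    @property
    def present_labels(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def mask(self, label: int) -> np.ndarray:
        return np.asarray(self.labels == label)


def _load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def read_fat_water(path_fat, path_water) -> FatWaterVolume:
    """Read a fat/water NIfTI pair; the two files must share the voxel grid."""
    fat, aff_f = _load_nifti(path_fat)
    water, aff_w = _load_nifti(path_water)
    if fat.shape != water.shape:
        raise GridMismatchError(
            f"fat {fat.shape} and water {water.shape} images differ in shape")
    if not np.allclose(aff_f, aff_w, atol=AFFINE_ATOL, rtol=0.0):
        raise GridMismatchError(
            f"fat and water affines differ by more than {AFFINE_ATOL}")
    geom = VoxelGeometry(affine=aff_f, dims=fat.shape)
    return FatWaterVolume(fat=fat, water=water, geometry=geom)


def read_label_map(path, reference: VoxelGeometry) -> LabelMap:
    """Read an integer label map and check it against the reference grid."""
    arr, aff = _load_nifti(path)
    geom = VoxelGeometry(affine=aff, dims=arr.shape)
    geom.require_match(reference, what="label map and reference image")
    return LabelMap(labels=arr, geometry=geom)


def write_fat_water(vol: FatWaterVolume, path_fat, path_water) -> None:
    aff = vol.geometry.affine
    nib.save(nib.Nifti1Image(vol.fat.astype(np.float64), aff), str(path_fat))
    nib.save(nib.Nifti1Image(vol.water.astype(np.float64), aff), str(path_water))


def write_label_map(lm: LabelMap, path) -> None:
    nib.save(nib.Nifti1Image(lm.labels.astype(np.int16), lm.geometry.affine),
             str(path))


def write_measures(measures: pd.DataFrame, path) -> None:
    """Write a muscle-measures table to CSV.

    Missing IMF (empty eroded mask) is written as an empty cell, never as 0.
    """
    df = measures.copy()
    for col in MEASURE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"measures table is missing column {col!r}")
    df = df.loc[:, list(MEASURE_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.12g")


def read_measures(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measures CSV is missing columns {sorted(missing)}")
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort covariate CSV: participant_id, age, bmi, sex[, pf_left, pf_right]."""
    df = pd.read_csv(path)
    required = {"participant_id", "age", "bmi", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"duplicate participant ids: {dup}")
    bad_sex = set(df["sex"].unique()) - {"female", "male"}
    if bad_sex:
        raise ValueError(f"sex must be 'female' or 'male', got {sorted(bad_sex)}")
    for col in ("age", "bmi"):
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals <= 0).any():
            raise ValueError(f"{col} must be finite and positive")
    return df
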