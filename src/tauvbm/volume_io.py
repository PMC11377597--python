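"""Volumetric and tabular I/O with strict grid compatibility.

All images in the pipeline are assumed to already live on one common grid
(spatial normalisation happens upstream, in a VBM preprocessing pipeline);
this module refuses mismatched grids rather than resampling, because silent
resampling corrupts voxel counts that every downstream percentage depends on.

Missing voxels are encoded as NaN and are excluded from every mask and
statistic downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "LabelAtlas",
    "SubjectRecord",
    "GridMismatchError",
    "load_volume",
    "save_volume",
    "assert_same_grid",
    "load_subject_table",
    "subjects_to_frame",
]

#: voxel-size agreement tolerance, mm
VOXEL_TOL_MM = 1e-3

SCANNERS = ("PETCT", "HRRT")
SCAN_WINDOWS = ("W80_100", "W80_90")
GROUPS = ("control", "athlete")


class GridMismatchError(ValueError):
    """Two volumes do not share dimensions / voxel sizes."""


@dataclass
class ImageVolume:
    """A 3-D scalar grid (grey-matter volume, SUVR, or w-score values).

    ``data`` is float; NaN marks missing voxels. ``voxel_size_mm`` is the
    (x, y, z) voxel edge length in millimetres.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    space_tag: str = "common"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3-D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive reals, got {self.voxel_size_mm}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data, self.voxel_size_mm, self.space_tag)


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation on the analysis grid; 0 = background."""

    labels: np.ndarray
    name_table: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.name_table)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    def regions(self) -> list[int]:
        return sorted((set(np.unique(self.labels).tolist()) - {0}))


@dataclass
class SubjectRecord:
    """Demographics, acquisition covariates and group membership."""

    subject_id: str
    age: float
    tiv: float
    group: str
    education: float | None = None
    scanner: str | None = None
    scan_window: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"subject {self.subject_id}: group must be one of {GROUPS}")
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValueError(f"subject {self.subject_id}: age must be > 0, got {self.age}")
        if not np.isfinite(self.tiv) or self.tiv <= 0:
            raise ValueError(f"subject {self.subject_id}: tiv must be > 0, got {self.tiv}")
        if self.group == "athlete":
            if self.scanner not in SCANNERS:
                raise ValueError(
                    f"athlete {self.subject_id}: scanner must be one of {SCANNERS}, got {self.scanner}"
                )
            if self.scan_window not in SCAN_WINDOWS:
                raise ValueError(
                    f"athlete {self.subject_id}: scan_window must be one of "
                    f"{SCAN_WINDOWS}, got {self.scan_window}"
                )


def load_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI-1 image as an :class:`ImageVolume`.

    4-D images are rejected here: dynamic PET series must go through
    :func:`tauvbm.pet.average_frames` first.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    # trailing singleton dims (e.g. 16x16x16x1) are harmless
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim == 4:
        raise ValueError(
            f"{path}: 4-D image; average time frames first "
            "(tauvbm.pet.average_frames / `tauvbm pet --frames`)"
        )
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel size in header: {zooms}")
    return ImageVolume(np.asarray(data, dtype=float), zooms)


def save_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write as NIfTI-1 with a diagonal affine built from the voxel sizes."""
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, os.fspath(path))


def assert_same_grid(a: ImageVolume, b: ImageVolume, tol_mm: float = VOXEL_TOL_MM) -> None:
    """Fail unless the two volumes share dimensions and voxel sizes (within tol)."""
    if a.shape != b.shape:
        raise GridMismatchError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    dv = np.abs(np.asarray(a.voxel_size_mm) - np.asarray(b.voxel_size_mm))
    if np.any(dv > tol_mm):
        raise GridMismatchError(
            f"voxel size mismatch beyond {tol_mm} mm: {a.voxel_size_mm} vs {b.voxel_size_mm}"
        )


_REQUIRED_COLS = ("subject_id", "age", "tiv", "group")
_KNOWN_COLS = set(_REQUIRED_COLS) | {"education", "scanner", "scan_window"}


def load_subject_table(path: str | os.PathLike) -> list[SubjectRecord]:
    """Read a subject CSV (header row required) into typed records.

    Unknown columns are preserved in ``record.extras``. Errors name the
    offending row and column.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    df = pd.read_csv(path)
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    records = []
    for i, row in df.iterrows():
        for col in ("age", "tiv"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ValueError(f"{path}: row {i}, column '{col}': non-numeric value {row[col]!r}")
        extras = {c: row[c] for c in df.columns if c not in _KNOWN_COLS}
        edu = row.get("education")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                tiv=float(row["tiv"]),
                group=str(row["group"]),
                education=float(edu) if edu is not None and np.isfinite(float(edu)) else None,
                scanner=_opt_str(row.get("scanner")),
                scan_window=_opt_str(row.get("scan_window")),
                extras=extras,
            )
        )
    return records


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return str(v)


def subjects_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabular view of subject records (extras flattened into columns)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "age": r.age,
            "tiv": r.tiv,
            "group": r.group,
            "education": r.education,
            "scanner": r.scanner,
            "scan_window": r.scan_window,
        }
        row.update(r.extras)
        rows.append(row)
    return pd.DataFrame(rows)
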