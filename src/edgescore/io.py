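"""NIfTI I/O for SUV volumes and lesion masks, plus CSV feature tables.

Volumes are SUV-calibrated 3-D scalar grids.  Geometry follows the NIfTI
convention: 0-based voxel indices, physical positions are voxel centers in
mm obtained through the affine.  Masks are stored as uint8 {0,1}; any
nonzero voxel on read is treated as foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when a file violates the expected imaging format."""


class SchemaError(ValueError):
    """Raised when feature records do not share a common column manifest."""


@dataclass
class PETVolume:
    """A 3-D SUV grid with physical geometry.

    Parameters
    ----------
    values : (ni, nj, nk) float array
        SUV values; must be finite and non-negative.
    spacing : length-3 sequence
        Voxel spacing along each array axis in mm; all components > 0.
    affine : (4, 4) array, optional
        Voxel-index -> physical-mm mapping.  Defaults to a diagonal affine
        built from ``spacing`` with origin at zero.
    """

    values: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got {self.values.ndim}-D")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if not np.all(self.spacing > 0):
            raise FormatError(f"non-positive voxel spacing {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume contains non-finite values")
        if np.any(self.values < 0):
            raise FormatError("SUV values must be non-negative")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def index_to_mm(self, index: Sequence[float]) -> np.ndarray:
        """Physical mm coordinates of a (possibly fractional) voxel index."""
        idx = np.asarray(index, dtype=np.float64)
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LesionMask:
    """Binary lesion mask sharing the geometry of its PETVolume."""

    values: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3-D mask, got {self.values.ndim}-D")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if not np.all(self.spacing > 0):
            raise FormatError(f"non-positive voxel spacing {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def index_to_mm(self, index: Sequence[float]) -> np.ndarray:
        idx = np.asarray(index, dtype=np.float64)
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got shape {data.shape}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    if not np.all(spacing > 0):
        raise FormatError(f"{path}: non-positive spacing {spacing}")
    return np.asarray(data), spacing, np.asarray(img.affine)


def read_volume(path: str | Path) -> PETVolume:
    """Read a 3-D SUV NIfTI volume; spacing comes from the header."""
    data, spacing, affine = _load_nifti(path)
    return PETVolume(values=data.astype(np.float64), spacing=spacing, affine=affine)


def read_mask(path: str | Path) -> LesionMask:
    """Read a binary lesion mask; any nonzero voxel is foreground."""
    data, spacing, affine = _load_nifti(path)
    return LesionMask(values=data != 0, spacing=spacing, affine=affine)


def write_volume(volume: PETVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def write_mask(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.affine)
    img.header.set_zooms(tuple(mask.spacing))
    nib.save(img, str(path))


def write_feature_table(rows: Iterable[Mapping[str, object]], path: str | Path,
                        manifest: Sequence[str] | None = None) -> None:
    """Write per-lesion feature records to CSV.

    All rows must share one column manifest; the column order of the output
    is the manifest order (taken from the first row if not given).
    """
    rows = list(rows)
    if manifest is None:
        manifest = list(rows[0].keys()) if rows else []
    manifest = list(manifest)
    for i, row in enumerate(rows):
        if list(row.keys()) != manifest and set(row.keys()) != set(manifest):
            missing = set(manifest) - set(row.keys())
            extra = set(row.keys()) - set(manifest)
            raise SchemaError(
                f"row {i} does not match the column manifest "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
    df = pd.DataFrame(rows, columns=manifest)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # round_trip parser: the default fast parser is not correctly rounded,
    # which would break byte-identical reproduction of feature tables
    return pd.read_csv(path, float_precision="round_trip")
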