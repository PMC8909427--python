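"""Volume and table I/O plus isotropic resampling.

Arrays are indexed ``(x, y, z)`` in the header's physical frame: voxel
``(i, j, k)`` sits at ``origin + (i, j, k) * spacing`` mm.  SimpleITK stores
arrays ``(z, y, x)``, so readers/writers transpose once at the boundary.
Masks are boolean in memory and unsigned 8-bit on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from segstress.errors import DegenerateMaskError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The eight texture/first-order features the eta analysis centres on.
DEFAULT_FEATURE_LIST = (
    "firstorder_Maximum",
    "gldm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformity",
    "ngtdm_Coarseness",
    "glszm_GrayLevelVariance",
    "glrlm_RunEntropy",
    "glcm_MCC",
    "glszm_GrayLevelNonUniformityNormalized",
)


@dataclass
class ImageVolume:
    """3D scalar grid (HU for CT) with physical spacing and origin in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryMask:
    """3D boolean grid sharing the grid of its paired :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if not self.voxels.any():
            raise DegenerateMaskError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def volume_mm3(self) -> float:
        """Foreground volume as voxel count times voxel volume."""
        return float(self.voxels.sum()) * float(np.prod(self.spacing))

    def same_grid(self, other: "BinaryMask | ImageVolume") -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class RunConfig:
    """Parameters of one uncertainty-propagation run.

    Defaults mirror a clinically motivated setting: a 1.18 mm surface
    tolerance (interobserver variability scale for lung GTVs), 300 perturbed
    masks per patient, 25 HU intensity bins on a 1 mm isotropic grid.
    """

    tolerance_mm: float = 1.18
    n_realizations: int = 300
    bin_width_hu: float = 25.0
    voxel_size_mm: float = 1.0
    n_simulations: int = 1000
    seed: int = 0
    feature_list: tuple[str, ...] = field(default_factory=lambda: DEFAULT_FEATURE_LIST)

    def __post_init__(self) -> None:
        if self.tolerance_mm <= 0:
            raise ValidationError("tolerance_mm must be > 0")
        if self.n_realizations < 1:
            raise ValidationError("n_realizations must be >= 1")
        if self.bin_width_hu <= 0:
            raise ValidationError("bin_width_hu must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "feature_list" in raw:
            raw["feature_list"] = tuple(raw["feature_list"])
        return cls(**raw)


_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(f"unsupported volume format: {path.name} (use NIfTI or NRRD)")


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI or NRRD scalar volume; spacing/origin from the header."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all ITK IO failures
        raise FormatError(f"could not read {path}: {exc}") from exc
    voxels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(voxels=voxels, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask; any strictly positive voxel counts as foreground."""
    vol = read_volume(path)
    return BinaryMask(voxels=vol.voxels > 0, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.voxels.transpose(2, 1, 0)).astype(np.uint8)
    )
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, str(path))


def _to_sitk(vol: ImageVolume | BinaryMask) -> sitk.Image:
    arr = vol.voxels
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def resample_isotropic(
    vol: ImageVolume | BinaryMask, target_mm: float = 1.0, is_mask: bool | None = None
) -> ImageVolume | BinaryMask:
    """Resample to an isotropic ``target_mm`` grid preserving physical extent.

    Images are linearly interpolated; masks use nearest-neighbour so the
    output stays strictly binary.
    """
    if target_mm <= 0:
        raise ValidationError("target_mm must be > 0")
    if is_mask is None:
        is_mask = isinstance(vol, BinaryMask)
    if np.allclose(vol.spacing, (target_mm,) * 3):
        return vol
    img = _to_sitk(vol)
    new_size = [
        max(1, int(round(sz * sp / target_mm)))
        for sz, sp in zip(img.GetSize(), img.GetSpacing())
    ]
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing((target_mm,) * 3)
    resampler.SetSize(new_size)
    resampler.SetOutputOrigin(img.GetOrigin())
    resampler.SetOutputDirection(img.GetDirection())
    resampler.SetInterpolator(sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear)
    out = resampler.Execute(img)
    voxels = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    if is_mask:
        if not (voxels > 0).any():
            raise DegenerateMaskError("mask is empty after resampling")
        return BinaryMask(voxels=voxels > 0, spacing=out.GetSpacing(), origin=out.GetOrigin())
    return ImageVolume(voxels=voxels, spacing=out.GetSpacing(), origin=out.GetOrigin())


# ---------------------------------------------------------------------------
# survival and feature tables


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-patient overall-survival follow-up."""

    patient_id: str
    time_days: float
    event: bool


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival CSV with columns patient_id, time_days, event.

    Rows with missing time or event are dropped with a logged warning,
    mirroring the usual cohort-exclusion step.  Duplicate patient ids are an
    error.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "time_days", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(f"survival CSV must have columns {sorted(required)}")
    time = pd.to_numeric(df["time_days"], errors="coerce")
    bad_numeric = time.isna() & df["time_days"].notna()
    if bad_numeric.any():
        raise ValidationError(
            f"non-numeric time_days for patients {df.loc[bad_numeric, 'patient_id'].tolist()}"
        )
    event = pd.to_numeric(df["event"], errors="coerce")
    keep = time.notna() & event.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "dropping %d survival rows with missing time/event: %s",
            n_dropped,
            df.loc[~keep, "patient_id"].tolist(),
        )
    df = df[keep]
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id values: {dupes}")
    return [
        SurvivalRecord(patient_id=pid, time_days=float(t), event=bool(int(e)))
        for pid, t, e in zip(df["patient_id"], time[keep], event[keep])
    ]


def write_survival_table(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_days": [r.time_days for r in records],
            "event": [int(r.event) for r in records],
        }
    ).to_csv(path, index=False)
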