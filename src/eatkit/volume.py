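"""Volumetric data model, NIfTI/NRRD I/O, and tube-voltage calibration.

A CT volume is a 3D grid of Hounsfield units (HU) with anisotropic voxel
spacing. Voxel indices are 0-based and the physical position of a voxel
center is ``origin + index * spacing`` (voxel-center convention). All
attenuation analysis downstream assumes volumes have been normalized to the
120 kVp reference tube voltage via :func:`adjust_to_reference_kvp`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .exceptions import CalibrationError, FormatError, GeometryError

HU_MIN = -1024.0
HU_MAX = 3071.0

#: Reference tube voltage (kVp) that all attenuation values are normalized to.
REFERENCE_KVP = 120.0


class Phase(str, enum.Enum):
    """Contrast phase of a CT acquisition."""

    NONCONTRAST = "noncontrast"
    CONTRAST = "contrast"


@dataclass(frozen=True)
class CTVolume:
    """A calibrated HU voxel grid.

    Parameters
    ----------
    voxels
        3D array of Hounsfield units, axis order (x, y, z) with z axial.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Physical position (mm) of voxel (0, 0, 0).
    tube_voltage
        Acquisition tube voltage in kVp.
    phase
        Contrast phase of the scan.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tube_voltage: float = REFERENCE_KVP
    phase: Phase = Phase.CONTRAST

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise FormatError(f"volume must be 3D, got {vox.ndim}D")
        if any(n < 2 for n in vox.shape):
            raise FormatError(f"every axis must have length >= 2, got {vox.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if vox.size and (vox.min() < HU_MIN or vox.max() > HU_MAX):
            raise FormatError(
                f"HU outside [{HU_MIN:g}, {HU_MAX:g}]: range [{vox.min():g}, {vox.max():g}]"
            )
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "phase", Phase(self.phase))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class VoxelMask:
    """Binary region of interest co-registered to a :class:`CTVolume` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise FormatError(f"mask must be 3D, got {vox.ndim}D")
        if vox.dtype != bool:
            uniq = np.unique(vox)
            if not np.all(np.isin(uniq, [0, 1])):
                raise FormatError(f"mask values must be 0/1, got {uniq[:8]}")
            vox = vox.astype(bool)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def from_volume(cls, volume: CTVolume, voxels: np.ndarray) -> "VoxelMask":
        mask = cls(voxels, volume.spacing, volume.origin)
        if mask.voxels.shape != volume.shape:
            raise GeometryError(
                f"mask shape {mask.voxels.shape} != volume shape {volume.shape}"
            )
        return mask

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def same_grid(self, other: "CTVolume | VoxelMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == (other.shape if isinstance(other, VoxelMask) else other.shape)
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "CTVolume | VoxelMask") -> None:
        if not self.same_grid(other):
            raise GeometryError(
                f"grids differ: shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}"
            )

    def volume_ml(self) -> float:
        """Mask volume in mL (voxel count x voxel volume)."""
        return float(self.voxels.sum()) * float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class Centerline:
    """Ordered vessel centerline in physical (mm) coordinates."""

    points: np.ndarray
    arc_length: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise GeometryError(f"centerline needs >= 2 3D points, got shape {pts.shape}")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise GeometryError("consecutive centerline points must be distinct")
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "arc_length", arc)

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    @classmethod
    def from_csv(cls, path: str | Path) -> "Centerline":
        """Read a 3-column x,y,z CSV of points in mm."""
        pts = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(pts)

    def to_csv(self, path: str | Path) -> Path:
        np.savetxt(path, self.points, delimiter=",", fmt="%.6g")
        return Path(path)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("nifti", "nrrd"):
            raise FormatError(f"unknown format {fmt!r}")
        return fmt
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise FormatError(f"cannot infer format from {path.name!r}; pass format=")


def read_volume(
    path: str | Path,
    format: str | None = None,
    tube_voltage: float = REFERENCE_KVP,
    phase: Phase | str = Phase.CONTRAST,
) -> CTVolume:
    """Read a 3D volume from NIfTI or NRRD.

    Spacing and origin come from the file header. HU values outside the
    representable CT range [-1024, 3071] are clamped with a warning
    (reconstruction padding values occur in practice). Tube voltage and
    contrast phase are not part of either header and are supplied by the
    caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise FormatError(f"expected 3D payload, got {data.ndim}D in {path.name}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(o) for o in np.asarray(img.affine)[:3, 3])
    else:
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise FormatError(f"expected 3D payload, got {img.GetDimension()}D in {path.name}")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
    data = np.asarray(data)
    if data.size and (data.min() < HU_MIN or data.max() > HU_MAX):
        warnings.warn(
            f"{path.name}: clamping HU outside [{HU_MIN:g}, {HU_MAX:g}]", stacklevel=2
        )
        data = np.clip(data, HU_MIN, HU_MAX)
    return CTVolume(data, spacing, origin, tube_voltage=tube_voltage, phase=Phase(phase))


def write_volume(volume: CTVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a volume to NIfTI or NRRD.

    Integer-valued HU are stored as signed 16-bit (lossless for the CT
    range); non-integer HU fall back to a float64 container.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    data = volume.voxels
    if np.issubdtype(data.dtype, np.integer) or (
        data.size and np.all(np.mod(data, 1) == 0)
    ):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float64)
    if fmt == "nifti":
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(data, affine)
        img.header.set_data_dtype(data.dtype)
        nib.save(img, str(path))
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
    return path


def write_mask(mask: VoxelMask, path: str | Path, format: str | None = None) -> Path:
    """Write a binary mask as an unsigned 8-bit 0/1 volume."""
    path = Path(path)
    fmt = _infer_format(path, format)
    data = mask.voxels.astype(np.uint8)
    if fmt == "nifti":
        affine = np.diag(list(mask.spacing) + [1.0])
        affine[:3, 3] = mask.origin
        img = nib.Nifti1Image(data, affine)
        img.header.set_data_dtype(np.uint8)
        nib.save(img, str(path))
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(mask.spacing)
        img.SetOrigin(mask.origin)
        sitk.WriteImage(img, str(path))
    return path


def read_mask(path: str | Path, format: str | None = None) -> VoxelMask:
    """Read a 0/1 volume as a :class:`VoxelMask`."""
    vol = read_volume(path, format=format)
    return VoxelMask(vol.voxels, vol.spacing, vol.origin)


#: Identity calibration: volumes already at the 120 kVp reference.
IDENTITY_CALIBRATION: Mapping[float, tuple[float, float]] = {REFERENCE_KVP: (1.0, 0.0)}


def adjust_to_reference_kvp(
    volume: CTVolume,
    calibration: Mapping[float, tuple[float, float]] = IDENTITY_CALIBRATION,
) -> CTVolume:
    """Normalize attenuation to the 120 kVp reference tube voltage.

    The per-voltage correction is an affine map ``h -> slope * h + intercept``
    whose coefficients are scanner-specific and supplied by the caller; the
    entry for 120 kVp must be the identity (1, 0). Returns a new volume at
    120 kVp; the input is unmodified.
    """
    kvp = float(volume.tube_voltage)
    entry = calibration.get(kvp)
    if entry is None:
        entry = calibration.get(int(kvp)) if kvp == int(kvp) else None
    if entry is None:
        raise CalibrationError(f"no calibration entry for {kvp:g} kVp")
    slope, intercept = (float(v) for v in entry)
    ref = calibration.get(REFERENCE_KVP, calibration.get(int(REFERENCE_KVP)))
    if ref is not None and tuple(float(v) for v in ref) != (1.0, 0.0):
        raise CalibrationError("calibration entry for 120 kVp must be (1, 0)")
    if kvp == REFERENCE_KVP:
        adjusted = volume.voxels.copy()
    else:
        adjusted = slope * volume.voxels.astype(float) + intercept
        adjusted = np.clip(adjusted, HU_MIN, HU_MAX)
    return replace(volume, voxels=adjusted, tube_voltage=REFERENCE_KVP)
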