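"""Per-patient imaging biomarkers.

The central quantity is *EAT dispersion*: the difference between the mean
attenuation of the high ((-45, -15] HU) and low ([-195, -45] HU) adipose
compartments within a region of interest. A larger dispersion indicates a
more heterogeneous fat depot (co-existing adipocyte hypertrophy, inflammation
and fibrosis pull voxels toward opposite ends of the fat HU range).

Also here: the enhancing-EAT fraction (fat volume that leaves the fat HU
range on the contrast-enhanced scan), body-surface-area indexing of volumes,
and the Agatston coronary calcium score on noncontrast scans.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .exceptions import InputError, PhaseError
from .segmentation import CompartmentDefinition, compartment_masks
from .volume import CTVolume, Phase, VoxelMask

__all__ = [
    "EATStats",
    "PatientMetrics",
    "METRICS_COLUMNS",
    "compute_eat_stats",
    "compute_eeat",
    "bsa_mosteller",
    "index_by_bsa",
    "agatston_score",
]


@dataclass(frozen=True)
class EATStats:
    """Compartment attenuation statistics for one region.

    ``dispersion = mean_high - mean_low`` (positive: the low compartment sits
    well below the high one). All fields are NaN when a compartment is empty.
    """

    mean_low: float
    mean_high: float
    mean_total: float
    dispersion: float
    vol_low: float
    vol_high: float
    vol_total: float
    n_low: int
    n_high: int

    @property
    def evaluable(self) -> bool:
        return not (math.isnan(self.mean_low) or math.isnan(self.mean_high))

    @classmethod
    def missing(cls) -> "EATStats":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, nan, 0, 0)


#: Fixed column order of the per-patient metrics CSV.
METRICS_COLUMNS = (
    "patient_id",
    "la_mean_low_hu",
    "la_mean_high_hu",
    "la_dispersion_hu",
    "rca_dispersion_hu",
    "lcx_dispersion_hu",
    "lad_dispersion_hu",
    "e_eat_pct",
    "la_volume_index",
    "la_eat_volume_index",
    "agatston",
    "bsa",
)


@dataclass
class PatientMetrics:
    """One patient's imaging biomarkers, serializable as one CSV row."""

    patient_id: str
    la: EATStats = field(default_factory=EATStats.missing)
    rca: EATStats = field(default_factory=EATStats.missing)
    lcx: EATStats = field(default_factory=EATStats.missing)
    lad: EATStats = field(default_factory=EATStats.missing)
    e_eat_pct: float = float("nan")
    la_volume_index: float = float("nan")
    la_eat_volume_index: float = float("nan")
    agatston: float = float("nan")
    bsa: float = float("nan")

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "la_mean_low_hu": self.la.mean_low,
            "la_mean_high_hu": self.la.mean_high,
            "la_dispersion_hu": self.la.dispersion,
            "rca_dispersion_hu": self.rca.dispersion,
            "lcx_dispersion_hu": self.lcx.dispersion,
            "lad_dispersion_hu": self.lad.dispersion,
            "e_eat_pct": self.e_eat_pct,
            "la_volume_index": self.la_volume_index,
            "la_eat_volume_index": self.la_eat_volume_index,
            "agatston": self.agatston,
            "bsa": self.bsa,
        }


def compute_eat_stats(
    volume: CTVolume,
    roi: VoxelMask,
    comp: CompartmentDefinition = CompartmentDefinition(),
) -> EATStats:
    """Compartment means, volumes and dispersion of fat voxels in an ROI.

    Means are plain arithmetic means of voxel HU per compartment; volumes
    are voxel counts times the voxel volume, in mL. If either compartment is
    empty the region is not evaluable: a missing-value result is returned
    with a warning so the patient can be excluded listwise downstream.
    """
    low, high, total = compartment_masks(volume, roi, comp)
    n_low = int(low.voxels.sum())
    n_high = int(high.voxels.sum())
    if n_low == 0 or n_high == 0:
        warnings.warn(
            f"empty {'low' if n_low == 0 else 'high'} compartment: region not evaluable",
            stacklevel=2,
        )
        return EATStats.missing()
    hu = volume.voxels
    mean_low = float(hu[low.voxels].mean())
    mean_high = float(hu[high.voxels].mean())
    mean_total = float(hu[total.voxels].mean())
    return EATStats(
        mean_low=mean_low,
        mean_high=mean_high,
        mean_total=mean_total,
        dispersion=mean_high - mean_low,
        vol_low=low.volume_ml(),
        vol_high=high.volume_ml(),
        vol_total=total.volume_ml(),
        n_low=n_low,
        n_high=n_high,
    )


def compute_eeat(vol_total_noncontrast: float, vol_total_contrast: float) -> float:
    """Enhancing-EAT fraction in percent.

    ``100 * (V_nc - V_ce) / V_nc``: the share of the noncontrast fat volume
    that no longer falls in the fat HU range on the contrast-enhanced scan.
    Negative values (more fat-range volume with contrast) are permitted with
    a warning; a zero noncontrast volume yields NaN.
    """
    if vol_total_noncontrast <= 0:
        warnings.warn("noncontrast EAT volume is 0: e-EAT undefined", stacklevel=2)
        return float("nan")
    frac = 100.0 * (vol_total_noncontrast - vol_total_contrast) / vol_total_noncontrast
    if frac < 0:
        warnings.warn(f"negative e-EAT ({frac:.1f}%)", stacklevel=2)
    return frac


def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Body surface area in m^2, Mosteller formula sqrt(h*w/3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise InputError(f"height/weight must be positive, got {height_cm}, {weight_kg}")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def index_by_bsa(value_ml: float, height_cm: float, weight_kg: float) -> float:
    """Index a volume by body surface area (mL/m^2)."""
    return value_ml / bsa_mosteller(height_cm, weight_kg)


_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def _agatston_weight(peak_hu: float) -> int:
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


def agatston_score(
    volume: CTVolume,
    region: Optional[VoxelMask] = None,
    threshold: float = 130.0,
    min_lesion_area_mm2: float = 1.0,
    axial_axis: int = 2,
) -> float:
    """Agatston coronary calcium score on a noncontrast scan.

    Per axial slice, 8-connected lesions of voxels at or above 130 HU with
    in-plane area >= 1 mm^2 contribute ``area * weight``, where the weight
    steps with the lesion's peak HU (130-199 -> 1, 200-299 -> 2,
    300-399 -> 3, >= 400 -> 4). Slice contributions are scaled by
    ``slice_spacing / 3 mm`` so the score is comparable to the classic
    3 mm-slice protocol. Refuses contrast-enhanced input: iodinated blood
    exceeds the 130 HU threshold and would mimic calcium.
    """
    if volume.phase is not Phase.NONCONTRAST:
        raise PhaseError("Agatston scoring requires the noncontrast scan")
    hu = np.moveaxis(volume.voxels, axial_axis, 0)
    mask = None
    if region is not None:
        region.require_same_grid(volume)
        mask = np.moveaxis(region.voxels, axial_axis, 0)
    in_plane = [s for i, s in enumerate(volume.spacing) if i != axial_axis]
    pixel_area = float(in_plane[0] * in_plane[1])
    slice_factor = float(volume.spacing[axial_axis]) / 3.0
    total = 0.0
    for k in range(hu.shape[0]):
        plane = hu[k] >= threshold
        if mask is not None:
            plane &= mask[k]
        if not plane.any():
            continue
        labels, n = ndimage.label(plane, structure=_EIGHT_CONNECTED)
        for lesion in range(1, n + 1):
            sel = labels == lesion
            area = float(sel.sum()) * pixel_area
            if area < min_lesion_area_mm2:
                continue
            peak = float(hu[k][sel].max())
            total += area * _agatston_weight(peak) * slice_factor
    return total
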