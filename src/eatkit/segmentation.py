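"""Analysis-mask construction.

Three mask producers feed the attenuation metrics:

* :func:`compartment_masks` — split an ROI into the low ([-195, -45] HU) and
  high ((-45, -15] HU) adipose attenuation compartments. The two bands form a
  contiguous real-valued partition of the fat range [-195, -15]: -45 belongs
  to the low compartment, so every in-range value lands in exactly one band.
* :func:`interpolate_sparse_mask` — reconstruct a full 3D region from a few
  manually annotated slices by linear blending of per-slice signed distance
  transforms (shape-based interpolation).
* :func:`pericoronary_cylinder_mask` — a tube of fixed radius around a vessel
  centerline restricted to an arc-length window, used to sample perivascular
  fat (e.g. a 4 mm radius over 40 mm of vessel, starting 10 mm from the
  right coronary ostium).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.ndimage import distance_transform_edt

from .exceptions import GeometryError, InputError
from .volume import Centerline, CTVolume, VoxelMask

__all__ = [
    "CompartmentDefinition",
    "SparseAnnotation",
    "compartment_masks",
    "interpolate_sparse_mask",
    "pericoronary_cylinder_mask",
    "VESSEL_WINDOWS",
]

#: Default (start_offset_mm, length_mm) sampling windows per coronary vessel:
#: the RCA window starts 10 mm distal to the ostium, LAD/LCX at the ostium.
VESSEL_WINDOWS: Mapping[str, tuple[float, float]] = {
    "rca": (10.0, 40.0),
    "lad": (0.0, 40.0),
    "lcx": (0.0, 40.0),
}


@dataclass(frozen=True)
class CompartmentDefinition:
    """HU bands for the adipose attenuation compartments.

    ``low_band`` is a closed interval, ``high_band`` half-open on the left
    (its lower edge equals the low band's upper edge), so the union
    ``total_band`` is a gap-free partition of the fat range.
    """

    low_band: tuple[float, float] = (-195.0, -45.0)
    high_band: tuple[float, float] = (-45.0, -15.0)

    def __post_init__(self) -> None:
        lo, hi = self.low_band, self.high_band
        if not (lo[0] < lo[1] and hi[0] < hi[1]):
            raise InputError(f"degenerate bands {lo}, {hi}")
        if lo[1] != hi[0]:
            raise InputError(f"bands must be contiguous: low {lo} vs high {hi}")

    @property
    def total_band(self) -> tuple[float, float]:
        return (self.low_band[0], self.high_band[1])

    def in_low(self, hu: np.ndarray) -> np.ndarray:
        return (hu >= self.low_band[0]) & (hu <= self.low_band[1])

    def in_high(self, hu: np.ndarray) -> np.ndarray:
        return (hu > self.high_band[0]) & (hu <= self.high_band[1])

    def in_total(self, hu: np.ndarray) -> np.ndarray:
        return (hu >= self.low_band[0]) & (hu <= self.high_band[1])


@dataclass(frozen=True)
class SparseAnnotation:
    """Manual contours on a few slices, to be interpolated to a 3D mask."""

    slice_axis: int
    contours: Mapping[int, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.contours) < 2:
            raise InputError("need >= 2 annotated slices")
        shapes = set()
        masks = {}
        for k, m in self.contours.items():
            m = np.asarray(m).astype(bool)
            if m.ndim != 2:
                raise InputError(f"slice {k}: annotation must be 2D")
            if not m.any():
                raise InputError(f"slice {k}: annotated mask is empty")
            shapes.add(m.shape)
            masks[int(k)] = m
        if len(shapes) != 1:
            raise InputError(f"annotated slices differ in shape: {shapes}")
        object.__setattr__(self, "contours", masks)

    @property
    def plane_shape(self) -> tuple[int, int]:
        return next(iter(self.contours.values())).shape


def compartment_masks(
    volume: CTVolume,
    roi: VoxelMask,
    comp: CompartmentDefinition = CompartmentDefinition(),
) -> tuple[VoxelMask, VoxelMask, VoxelMask]:
    """Split an ROI into (low, high, total) attenuation-band masks.

    The low and high masks are disjoint and their union is the total mask;
    ROI voxels outside the fat range belong to none of them.
    """
    roi.require_same_grid(volume)
    hu = volume.voxels
    inside = roi.voxels
    low = inside & comp.in_low(hu)
    high = inside & comp.in_high(hu)
    total = low | high
    mk = lambda v: VoxelMask(v, volume.spacing, volume.origin)  # noqa: E731
    return mk(low), mk(high), mk(total)


def _signed_distance(mask: np.ndarray, sampling: tuple[float, float]) -> np.ndarray:
    # positive inside, negative outside; never exactly 0 on the pixel grid
    inside = distance_transform_edt(mask, sampling=sampling)
    outside = distance_transform_edt(~mask, sampling=sampling)
    return inside - outside


def interpolate_sparse_mask(
    annotation: SparseAnnotation,
    grid: CTVolume | VoxelMask,
) -> VoxelMask:
    """Fill a full 3D mask from sparsely annotated slices.

    Annotated slices are reproduced exactly. Each intermediate slice is the
    zero superlevel set of the linear interpolation (in slice index) of the
    two bracketing slices' signed Euclidean distance transforms. Slices
    outside the annotated span stay empty.
    """
    axis = annotation.slice_axis
    shape = grid.shape
    if not 0 <= axis < 3:
        raise InputError(f"slice_axis {axis} out of range")
    moved_shape = tuple(np.moveaxis(np.empty(shape, dtype=bool), axis, 0).shape)
    if moved_shape[1:] != annotation.plane_shape:
        raise GeometryError(
            f"annotation plane {annotation.plane_shape} does not fit grid "
            f"{shape} along axis {axis}"
        )
    n_slices = shape[axis]
    keys = sorted(annotation.contours)
    if keys[0] < 0 or keys[-1] >= n_slices:
        raise GeometryError(f"annotated slice indices {keys} outside grid [0, {n_slices})")

    in_plane = tuple(s for i, s in enumerate(grid.spacing) if i != axis)
    sdt = {k: _signed_distance(annotation.contours[k], in_plane) for k in keys}

    out = np.zeros(moved_shape, dtype=bool)
    for k in keys:
        out[k] = annotation.contours[k]
    for k0, k1 in zip(keys[:-1], keys[1:]):
        for k in range(k0 + 1, k1):
            w = (k - k0) / (k1 - k0)
            out[k] = (1.0 - w) * sdt[k0] + w * sdt[k1] > 0.0
    voxels = np.moveaxis(out, 0, axis)
    return VoxelMask(voxels, grid.spacing, grid.origin)


def _nearest_on_polyline(
    points: np.ndarray, centerline: Centerline
) -> tuple[np.ndarray, np.ndarray]:
    """Distance to and arc-length parameter of the nearest polyline point.

    Ties between segments resolve to the smaller segment index (strict
    improvement required to switch).
    """
    P = centerline.points
    arc = centerline.arc_length
    best_d2 = np.full(points.shape[0], np.inf)
    best_s = np.zeros(points.shape[0])
    for i in range(len(P) - 1):
        a, b = P[i], P[i + 1]
        ab = b - a
        L2 = float(ab @ ab)
        t = np.clip((points - a) @ ab / L2, 0.0, 1.0)
        diff = points - (a + t[:, None] * ab)
        d2 = np.einsum("ij,ij->i", diff, diff)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_s[better] = arc[i] + t[better] * np.sqrt(L2)
    return np.sqrt(best_d2), best_s


def pericoronary_cylinder_mask(
    grid: CTVolume | VoxelMask,
    centerline: Centerline,
    radius: float = 4.0,
    start_offset: float = 10.0,
    length: float = 40.0,
) -> VoxelMask:
    """Voxels within ``radius`` mm of a centerline, inside an arc window.

    A voxel belongs to the mask iff its center lies within ``radius`` of the
    centerline polyline and the arc-length parameter of its nearest polyline
    point falls in ``[start_offset, start_offset + length]``.
    """
    if radius <= 0 or length <= 0 or start_offset < 0:
        raise InputError("radius/length must be > 0 and start_offset >= 0")
    if centerline.total_length < start_offset + length:
        raise GeometryError(
            f"centerline length {centerline.total_length:.1f} mm < required "
            f"{start_offset + length:.1f} mm"
        )
    shape = grid.shape
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)

    # restrict to the bounding box of the polyline inflated by the radius
    lo_mm = centerline.points.min(axis=0) - radius
    hi_mm = centerline.points.max(axis=0) + radius
    lo_idx = np.maximum(np.ceil((lo_mm - origin) / spacing).astype(int), 0)
    hi_idx = np.minimum(np.floor((hi_mm - origin) / spacing).astype(int), np.array(shape) - 1)
    voxels = np.zeros(shape, dtype=bool)
    if np.any(hi_idx < lo_idx):
        return VoxelMask(voxels, grid.spacing, grid.origin)

    axes = [np.arange(lo_idx[i], hi_idx[i] + 1) for i in range(3)]
    II, JJ, KK = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([II.ravel(), JJ.ravel(), KK.ravel()], axis=1)
    centers = origin + idx * spacing
    dist, s = _nearest_on_polyline(centers, centerline)
    keep = (dist <= radius) & (s >= start_offset) & (s <= start_offset + length)
    voxels[idx[keep, 0], idx[keep, 1], idx[keep, 2]] = True
    return VoxelMask(voxels, grid.spacing, grid.origin)
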