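"""Needle-length-constrained ROI extraction around the puncture target.

Only points within one needle length R of the target can host the needle
tail, so planning is restricted to a cube bounding the R-sphere, centred
on the target voxel.  Where the sphere's bounding box leaves the parent
image the cube is zero-padded; voxels outside the sphere or outside the
parent image are background and flagged invalid.  Directions whose ray
never reaches skin within R (needle too short, or skin not in the scan)
can additionally be blocked up front.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _march
from .geometry import SphereFrame, direction_grid
from .volume_io import LabelVolume

__all__ = ["NeedleQuery", "DirectionBlock", "ROIVolume", "crop_roi", "remove_no_skin_directions"]


@dataclass(frozen=True)
class NeedleQuery:
    """A puncture target (world mm) and the needle length R (mm)."""

    target: np.ndarray
    needle_mm: float

    def __post_init__(self) -> None:
        t = np.asarray(self.target, dtype=float)
        if t.shape != (3,):
            raise ValueError("target must be a 3-vector (world mm)")
        if self.needle_mm <= 0:
            raise ValueError("needle length must be positive")
        object.__setattr__(self, "target", t)


@dataclass(frozen=True)
class DirectionBlock:
    """Lat-lon grid of directions excluded for lack of reachable skin."""

    resolution_deg: float
    blocked: np.ndarray  # (nlat, nlon) bool


@dataclass(frozen=True)
class ROIVolume:
    """Cubic, sphere-masked crop of a parent volume centred on the target."""

    volume: LabelVolume
    radius_mm: float
    target_world: np.ndarray        # the exact query target
    center_index: int               # cube centre along each axis
    parent_offset: np.ndarray       # parent index of cube voxel (0,0,0)
    valid: np.ndarray               # inside R-sphere and inside parent image
    blocked: DirectionBlock | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.volume.labels

    @property
    def spacing_mm(self) -> float:
        return float(self.volume.spacing[0])

    @property
    def center_world(self) -> np.ndarray:
        """World position of the cube's centre voxel (the snapped target)."""
        return self.volume.index_to_world([self.center_index] * 3)


def crop_roi(vol: LabelVolume, q: NeedleQuery) -> ROIVolume:
    """Extract the centred cube bounding the needle-length sphere.

    The cube side is ``2*ceil(R/spacing) + 1`` voxels with the target at
    the exact centre voxel; world coordinates are preserved through the
    stored parent offset.  Requires an isotropic volume.
    """
    spacing = vol.spacing
    if not np.allclose(spacing, spacing[0]):
        raise ValueError("crop_roi requires an isotropic volume; resample first")
    sp = float(spacing[0])
    if not vol.contains_world(q.target):
        raise ValueError("target lies outside the volume")
    centre_idx = np.rint(vol.world_to_index(q.target)).astype(int)
    half = int(math.ceil(q.needle_mm / sp))
    side = 2 * half + 1
    cube = np.zeros((side, side, side), dtype=vol.labels.dtype)
    inside_parent = np.zeros((side, side, side), dtype=bool)

    offset = centre_idx - half
    src_lo = np.maximum(offset, 0)
    src_hi = np.minimum(offset + side, vol.shape)
    dst_lo = src_lo - offset
    dst_hi = src_hi - offset
    if np.all(src_hi > src_lo):
        sl_src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
        sl_dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
        cube[sl_dst] = vol.labels[sl_src]
        inside_parent[sl_dst] = True

    ax = (np.arange(side) - half) * sp
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    inside_sphere = (gx**2 + gy**2 + gz**2) <= q.needle_mm**2
    valid = inside_sphere & inside_parent
    cube[~inside_sphere] = 0

    roi_vol = LabelVolume(
        labels=cube,
        spacing=np.array([sp, sp, sp]),
        origin=vol.index_to_world(offset),
    )
    return ROIVolume(
        volume=roi_vol,
        radius_mm=float(q.needle_mm),
        target_world=np.asarray(q.target, float),
        center_index=half,
        parent_offset=offset,
        valid=valid,
    )


def remove_no_skin_directions(
    roi: ROIVolume,
    skin_label: int,
    resolution_deg: float = 1.0,
    frame: SphereFrame | None = None,
) -> ROIVolume:
    """Block every direction whose ray from the target cannot reach skin.

    For each direction of a lat-lon grid the ray from the target is
    traversed out to R; if it never crosses the skin (or re-enters the
    body after leaving it) the direction is recorded as blocked, which
    forces the obstruction indicator to zero downstream.  The blocked set
    is stored per direction rather than by opacifying shared near-target
    voxels, which would wrongly occlude neighbouring feasible directions.
    """
    if skin_label not in roi.volume.label_set():
        raise ValueError(
            f"skin label {skin_label} not present in ROI: degenerate mask "
            "(skin absent or entirely out of needle reach)"
        )
    _, _, dirs = direction_grid(resolution_deg, frame)
    nlat, nlon = dirs.shape[:2]
    flat = dirs.reshape(-1, 3)
    t0, seg_len, idx, inb = _march.ray_segments(
        roi.labels.shape, roi.spacing_mm, [roi.center_index] * 3, flat, roi.radius_mm
    )
    lab = _march.gather_labels(roi.labels, idx, inb, seg_len)
    seg, _, multi = _march.skin_crossings(lab, t0, skin_label)
    blocked = ((seg < 0) | multi).reshape(nlat, nlon)
    return replace(
        roi, blocked=DirectionBlock(resolution_deg=resolution_deg, blocked=blocked)
    )
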