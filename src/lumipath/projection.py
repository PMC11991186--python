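"""Equal-area sinusoidal projection of the shell map to an RGB raster.

The sinusoidal projection maps ``x = (lam - lam0) * cos(phi), y = phi``,
so pixel counts are proportional to solid angle: every valid pixel at
resolution ``r`` degrees subtends ``r**2`` square degrees regardless of
latitude.  The anterior direction (``lam = 0``) sits at the image centre.
Channel order follows the planner's convention: R = vessel attenuation,
G = soft-tissue attenuation, B = obstruction indicator x Lambertian term,
so B > 0 marks geometrically feasible directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .optics import ShellMap

__all__ = ["ProjectionImage", "project_sinusoidal", "unproject_pixel", "pixel_to_entry_point"]


@dataclass(frozen=True)
class ProjectionImage:
    """H x W x 3 float raster in [0, 1] with an invertible pixel mapping."""

    data: np.ndarray          # (H, W, 3)
    valid: np.ndarray         # (H, W) inside the sinusoidal outline
    node_index: np.ndarray    # (H, W, 2) shell (lat, lon) node per pixel
    resolution_deg: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def pixel_latlon(self, pixel) -> tuple[float, float]:
        """(phi, lam) in degrees of a pixel centre; pixel must be valid."""
        row, col = pixel
        if not self.valid[row, col]:
            raise ValueError(f"pixel {pixel} is outside the sinusoidal outline")
        res = self.resolution_deg
        phi = 90.0 - row * res
        x = col * res - 180.0
        cp = np.cos(np.deg2rad(phi))
        lam = 0.0 if cp < 1e-12 else x / cp
        return phi, lam

    def save_png(self, path: str | Path) -> None:
        """8-bit export for visual inspection (planning math stays float)."""
        arr = (np.clip(self.data, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(np.asarray(arr)).save(str(path))


def project_sinusoidal(shell: ShellMap) -> ProjectionImage:
    """Project a shell map; one pixel per shell-grid degree step.

    Each pixel is assigned the nearest shell node of its back-projected
    direction, which keeps the pixel->direction->pixel round trip within
    half a pixel everywhere.
    """
    res = shell.resolution_deg
    nlat = shell.phi_deg.size
    nlon = shell.lam_deg.size
    H = nlat
    W = int(round(360.0 / res)) + 1

    rows = np.arange(H)
    cols = np.arange(W)
    phi = 90.0 - rows * res
    x = cols * res - 180.0
    cp = np.cos(np.deg2rad(phi))
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = x[None, :] / cp[:, None]
    at_pole = cp < 1e-12
    lam[at_pole, :] = np.inf
    lam[at_pole, (W - 1) // 2] = 0.0
    valid = np.abs(lam) <= 180.0 + 1e-9

    i = np.clip(np.round((90.0 - phi) / res).astype(int), 0, nlat - 1)
    j = np.round((np.where(valid, lam, 0.0) + 180.0) / res).astype(int) % nlon
    node_index = np.stack([np.broadcast_to(i[:, None], (H, W)), j], axis=-1)

    b = shell.iobs.astype(float) * shell.aref
    chans = np.stack([shell.avas, shell.atra, b], axis=-1)  # (nlat, nlon, 3)
    data = np.where(valid[..., None], chans[node_index[..., 0], node_index[..., 1]], 0.0)
    return ProjectionImage(
        data=data, valid=valid, node_index=node_index, resolution_deg=res
    )


def unproject_pixel(img: ProjectionImage, pixel) -> np.ndarray:
    """Direction unit vector of a valid pixel (inverse sinusoidal map).

    The shell's frame is the default anterior/north frame; projections of
    shells with a custom frame should unproject through ``shell.frame``
    using :meth:`ProjectionImage.pixel_latlon`.
    """
    from .geometry import SphereFrame

    phi, lam = img.pixel_latlon(pixel)
    return SphereFrame().direction(phi, lam)


def pixel_to_entry_point(img: ProjectionImage, shell: ShellMap, pixel) -> np.ndarray:
    """World-mm skin entry point for a feasible pixel's direction."""
    row, col = pixel
    if not img.valid[row, col]:
        raise ValueError(f"pixel {pixel} is outside the sinusoidal outline")
    i, j = img.node_index[row, col]
    if not shell.iobs[i, j] or not np.isfinite(shell.depth_mm[i, j]):
        raise ValueError(f"pixel {pixel} maps to an infeasible direction")
    return shell.skin_points[i, j].copy()
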