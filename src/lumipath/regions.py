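"""Candidate safe-region extraction from the projected RGB image.

Pixels passing the channel thresholds (with a strictly positive blue
channel, which encodes feasibility) are grouped into 8-connected
components; components below the area threshold are dropped.  Each
surviving component yields a fixed, versioned 50-entry feature vector —
geometry, moments and per-channel intensity statistics — used to rank
regions the way a surgeon would, and the chosen region is eroded down to
a single entry pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage import measure

from .projection import ProjectionImage

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_VERSION",
    "CandidateRegion",
    "segment_safe_regions",
    "extract_features",
    "erode_to_point",
]

FEATURE_VERSION = 1

#: Canonical, ordered feature list.  The order and length are frozen; any
#: change must bump :data:`FEATURE_VERSION` (trained models refuse to
#: predict on a mismatched version).
FEATURE_NAMES: tuple[str, ...] = (
    # geometry (17)
    "area",
    "perimeter",
    "convex_area",
    "filled_area",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "solidity",
    "extent",
    "orientation",
    "bbox_height",
    "bbox_width",
    "centroid_row",
    "centroid_col",
    "euler_number",
    "compactness",
    # moments (14)
    "hu_1", "hu_2", "hu_3", "hu_4", "hu_5", "hu_6", "hu_7",
    "mu_11", "mu_20", "mu_02", "mu_21", "mu_12", "mu_30", "mu_03",
    # per-channel intensity statistics (15)
    "r_mean", "r_min", "r_max", "r_std", "r_sum",
    "g_mean", "g_min", "g_max", "g_std", "g_sum",
    "b_mean", "b_min", "b_max", "b_std", "b_sum",
    # position relative to the image centre (4)
    "aspect_ratio",
    "centroid_offset_row",
    "centroid_offset_col",
    "centroid_offset_norm",
)

assert len(FEATURE_NAMES) == 50


@dataclass
class CandidateRegion:
    """One 8-connected candidate entry region on the projection image."""

    pixels: np.ndarray                 # (n, 2) row/col
    area: int
    centroid: tuple[float, float]
    intensities: np.ndarray            # (n, 3) RGB at the pixels
    image_shape: tuple[int, int]
    features: np.ndarray = dc_field(default=None)
    probability: float | None = None

    def contains(self, pixel) -> bool:
        return bool(np.any(np.all(self.pixels == np.asarray(pixel), axis=1)))

    def mask(self) -> np.ndarray:
        m = np.zeros(self.image_shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


def segment_safe_regions(
    img: ProjectionImage,
    thresholds: tuple[float, float, float] = (0.0, 0.05, 0.0),
    min_area: int = 25,
) -> list[CandidateRegion]:
    """Threshold the RGB raster and split it into candidate regions.

    A pixel passes iff it is valid, its blue channel is strictly positive
    (feasible direction) and each channel meets its threshold.  The
    returned list is ordered by component label and independent of any
    enumeration order.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    r, g, b = (img.data[..., c] for c in range(3))
    tr, tg, tb = thresholds
    mask = img.valid & (b > 0) & (r >= tr) & (g >= tg) & (b >= tb)
    labelled = measure.label(mask, connectivity=2)
    regions: list[CandidateRegion] = []
    for prop in measure.regionprops(labelled):
        if prop.area < min_area:
            continue
        pix = prop.coords
        region = CandidateRegion(
            pixels=pix,
            area=int(prop.area),
            centroid=tuple(prop.centroid),
            intensities=img.data[pix[:, 0], pix[:, 1]],
            image_shape=img.shape,
        )
        region.features = extract_features(region, img)
        regions.append(region)
    return regions


def extract_features(region: CandidateRegion, img: ProjectionImage) -> np.ndarray:
    """The 50-entry feature vector of a region (see :data:`FEATURE_NAMES`)."""
    mask = region.mask()
    prop = measure.regionprops(mask.astype(np.uint8))[0]
    per = prop.perimeter
    area = float(prop.area)
    compact = 4.0 * np.pi * area / per**2 if per > 0 else 0.0
    minr, minc, maxr, maxc = prop.bbox
    mu = prop.moments_central
    hu = prop.moments_hu
    minor = prop.axis_minor_length
    aspect = prop.axis_major_length / minor if minor > 0 else 0.0
    centre = (np.array(region.image_shape, float) - 1) / 2
    off = np.asarray(prop.centroid) - centre

    vals = [
        area,
        per,
        float(prop.area_convex),
        float(prop.area_filled),
        prop.equivalent_diameter_area,
        prop.axis_major_length,
        minor,
        prop.eccentricity,
        prop.solidity,
        prop.extent,
        prop.orientation,
        float(maxr - minr),
        float(maxc - minc),
        prop.centroid[0],
        prop.centroid[1],
        float(prop.euler_number),
        compact,
        *hu,
        mu[1, 1], mu[2, 0], mu[0, 2], mu[2, 1], mu[1, 2], mu[3, 0], mu[0, 3],
    ]
    for c in range(3):
        ch = region.intensities[:, c]
        vals.extend([float(ch.mean()), float(ch.min()), float(ch.max()), float(ch.std()), float(ch.sum())])
    vals.extend([aspect, off[0], off[1], float(np.linalg.norm(off))])
    out = np.asarray(vals, dtype=float)
    assert out.shape == (len(FEATURE_NAMES),)
    return out


def erode_to_point(region: CandidateRegion) -> tuple[int, int]:
    """Iteratively erode a region to its single recommended entry pixel.

    3x3 binary erosion is repeated while the set stays non-empty; when the
    next step would empty it, the surviving pixel closest to the centroid
    of the last non-empty set is returned (ties: smallest row, then
    column).  The result is always a member of the original region and is
    deterministic.
    """
    mask = region.mask()
    if not mask.any():
        raise ValueError("cannot erode an empty region")
    struct = np.ones((3, 3), dtype=bool)
    while True:
        nxt = ndimage.binary_erosion(mask, structure=struct)
        if not nxt.any():
            break
        mask = nxt
    pts = np.argwhere(mask)
    centroid = pts.mean(axis=0)
    d2 = np.sum((pts - centroid) ** 2, axis=1)
    order = np.lexsort((pts[:, 1], pts[:, 0], d2))
    row, col = pts[order[0]]
    return int(row), int(col)
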