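"""Synthetic training corpora for the surgeon-preference classifier.

Each corpus entry is one phantom: the full illumination + projection +
region-extraction pipeline is run and the rule-based annotator marks the
"surgeon-preferred" region, yielding a grouped, imbalanced region dataset
on which classifier recovery of the (known) rule is measurable.
"""

from __future__ import annotations

import numpy as np

from . import optics, projection
from . import phantom as phantom_mod
from . import regions as regions_mod
from .recommend import RegionDataset
from .roi import NeedleQuery, crop_roi
from .volume_io import resample_isotropic

__all__ = ["phantom_regions", "build_region_corpus"]


def phantom_regions(
    seed: int,
    needle_mm: float = 60.0,
    resolution_deg: float = 3.0,
    min_area: int = 3,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing_mm: float = 2.5,
):
    """Run one phantom through illumination -> projection -> regions.

    Returns ``(regions, image, shell, spec)``; the target is the nodule
    centroid, per clinical practice.
    """
    spec = phantom_mod.PhantomSpec(shape=shape, spacing_mm=spacing_mm, seed=seed)
    vol = phantom_mod.generate_phantom(spec)
    cfg = phantom_mod.default_tissue_config(spec)
    nod = np.argwhere(vol.labels == spec.labels["nodule"])
    target = vol.index_to_world(nod.mean(axis=0))
    roi = crop_roi(resample_isotropic(vol), NeedleQuery(target=target, needle_mm=needle_mm))
    field = optics.build_absorption_field(roi, cfg)
    field = optics.dilate_obstacles(field, cfg.obstacle_margin_mm)
    shell = optics.compute_shell_map(
        roi, field, resolution_deg=resolution_deg, weights=cfg.weights
    )
    img = projection.project_sinusoidal(shell)
    regs = regions_mod.segment_safe_regions(
        img, thresholds=cfg.thresholds, min_area=min_area
    )
    return regs, img, shell, spec


def build_region_corpus(
    n_images: int,
    seed: int = 0,
    needle_mm: float = 60.0,
    resolution_deg: float = 3.0,
    min_area: int = 3,
    flip_rate: float = 0.0,
) -> RegionDataset:
    """Assemble a grouped region dataset from ``n_images`` seeded phantoms.

    Phantom seeds are ``seed*10000 + i`` so corpora for different master
    seeds do not overlap.  Images that yield no region (fully occluded
    target) are skipped.
    """
    feats, labels, groups = [], [], []
    for i in range(n_images):
        phantom_seed = seed * 10000 + i
        try:
            regs, img, _, _ = phantom_regions(
                phantom_seed, needle_mm=needle_mm,
                resolution_deg=resolution_deg, min_area=min_area,
            )
        except (ValueError, RuntimeError):  # rare: no feasible geometry draw
            continue
        if not regs:
            continue
        y = phantom_mod.annotate_regions_rulebased(
            regs, img.shape, flip_rate=flip_rate, seed=phantom_seed
        )
        for r, lab in zip(regs, y):
            feats.append(r.features)
            labels.append(bool(lab))
            groups.append(i)
    return RegionDataset(
        X=np.asarray(feats, float),
        y=np.asarray(labels, bool),
        groups=np.asarray(groups),
    )
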