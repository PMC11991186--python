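"""Exact voxel traversal for batches of rays leaving a common origin.

Rays start at the centre of a given voxel and are cut into segments at
every voxel-face crossing out to a fixed radius.  Because the per-axis
face crossings of a straight ray form arithmetic sequences, a whole batch
can be traversed with array operations: generate the three sequences, sort
them jointly, and classify each inter-crossing segment by the voxel its
midpoint falls in.  Line integrals over piecewise-constant voxel fields
are then exact (up to float rounding), unlike fixed-step sampling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ray_segments", "gather_labels", "skin_crossings"]

_EPS_LEN = 1e-9


def ray_segments(shape, spacing_mm: float, center_index, dirs, radius_mm: float):
    """Cut rays into voxel-aligned segments.

    Parameters
    ----------
    shape : grid shape (3,)
    spacing_mm : isotropic voxel size
    center_index : integer index of the origin voxel (ray start = its centre)
    dirs : (n, 3) unit directions
    radius_mm : march length R

    Returns
    -------
    t0 : (n, m) segment start distances (mm)
    seg_len : (n, m) segment lengths (mm); zero-length segments are
        corner touches and must be ignored for classification
    idx : (n, m, 3) voxel index of each segment midpoint, clipped to grid
    inb : (n, m) True where the midpoint is inside the grid
    """
    dirs = np.atleast_2d(np.asarray(dirs, float))
    n = dirs.shape[0]
    sp = float(spacing_mm)
    c = np.asarray(center_index, float)

    # per-axis face crossings: first at 0.5*sp/|d|, then every sp/|d|
    max_k = int(np.floor(radius_mm / sp + 0.5)) + 1
    k = np.arange(max_k)
    parts = []
    for a in range(3):
        da = np.abs(dirs[:, a:a + 1])
        with np.errstate(divide="ignore"):
            t = (0.5 + k[None, :]) * sp / da  # inf where da == 0
        parts.append(t)
    t_all = np.concatenate(parts, axis=1)
    t_all[t_all > radius_mm] = np.inf
    t_all = np.concatenate([t_all, np.full((n, 1), radius_mm)], axis=1)
    t_all.sort(axis=1)
    # drop columns that are inf for every ray
    m_keep = int(np.max(np.sum(np.isfinite(t_all), axis=1)))
    t_all = t_all[:, :m_keep]
    t_edges = np.concatenate([np.zeros((n, 1)), np.minimum(t_all, radius_mm)], axis=1)
    t0 = t_edges[:, :-1]
    seg_len = np.clip(np.diff(t_edges, axis=1), 0.0, None)
    t_mid = t0 + 0.5 * seg_len
    pos = c[None, None, :] + t_mid[:, :, None] * dirs[:, None, :] / sp
    idx = np.rint(pos).astype(np.int64)
    shape = np.asarray(shape)
    inb = np.all((idx >= 0) & (idx < shape[None, None, :]), axis=2)
    np.clip(idx, 0, shape[None, None, :] - 1, out=idx)
    return t0, seg_len, idx, inb


def gather_labels(labels: np.ndarray, idx, inb, seg_len, background: int = 0):
    """Per-segment labels; out-of-grid segments read as background.

    Zero-length (corner-touch) segments inherit the label of the previous
    real segment so they cannot create spurious transitions.
    """
    lab = labels[idx[..., 0], idx[..., 1], idx[..., 2]]
    lab = np.where(inb, lab, background)
    real = seg_len > _EPS_LEN
    m = lab.shape[1]
    last_real = np.where(real, np.arange(m)[None, :], 0)
    np.maximum.accumulate(last_real, axis=1, out=last_real)
    return np.take_along_axis(lab, last_real, axis=1)


def skin_crossings(lab, t0, skin_label: int, background: int = 0):
    """Locate the first skin contact along each ray.

    A crossing is the first segment whose label is the skin label: a ray
    that leaves the body without ever touching a skin voxel does *not*
    count (the skin may simply be missing from the scan there, so the
    direction is conservatively infeasible).  Returns ``(seg (n,), t (n,),
    multi (n,))`` where ``seg`` is -1 for rays that never cross, ``t`` the
    crossing distance (nan if none) and ``multi`` flags rays that re-enter
    interior tissue after first leaving the body (e.g. through a skin
    fold) — such rays are rejected as puncture paths.  Merely brushing
    further skin voxels of the stair-stepped surface after exit is not a
    re-entry: the needle tail outside the body may graze the skin.
    """
    n, m = lab.shape
    inside = lab != background
    hit = lab == skin_label
    has = hit.any(axis=1)
    seg = np.where(has, hit.argmax(axis=1), -1)
    t = np.where(has, np.take_along_axis(t0, np.maximum(seg, 0)[:, None], axis=1)[:, 0], np.nan)

    cols = np.arange(m)[None, :]
    after = cols >= seg[:, None]
    out_after = (~inside) & after & has[:, None]
    has_out = out_after.any(axis=1)
    first_out = np.where(has_out, out_after.argmax(axis=1), m)
    interior = inside & (lab != skin_label)
    multi = (interior & (cols > first_out[:, None])).any(axis=1) & has
    return seg, t, multi
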