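"""Seeded synthetic thorax phantoms and a rule-based region annotator.

Real planning inputs are CT segmentation masks; this module builds
thorax-*like* label volumes from parametric solids so the whole pipeline
can be exercised and validated without any imaging data: a body ellipsoid
wrapped in a one-voxel skin shell, two lungs split into lobe compartments,
branching vessel trees with graded radii, rib arcs, an opaque heart blob,
an airway tube, and a spherical nodule inside the target lobe.

Every phantom is verified to contain at least one obstacle-free corridor
from the nodule to the skin (by a brute-force ray sweep); if the sampled
geometry has none, the geometry is re-drawn deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, TissueConfig

__all__ = [
    "PHANTOM_LABELS",
    "PhantomSpec",
    "generate_phantom",
    "default_tissue_config",
    "annotate_regions_rulebased",
]

#: Canonical label vocabulary of the phantom.
PHANTOM_LABELS: dict[str, int] = {
    "background": 0,
    "body": 1,
    "skin": 2,
    "lobe_target": 3,
    "lobe_other": 4,
    "vessel": 5,
    "bone": 6,
    "heart": 7,
    "airway": 8,
    "nodule": 9,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic thorax; all physical sizes in mm."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 2.5
    seed: int = 0
    n_ribs: int = 4
    n_lobes: int = 3  # compartments of the nodule-hosting lung (2..5)
    nodule_radius_mm: float = 6.0
    rib_radius_mm: float = 4.0
    vessel_radii_mm: tuple[float, ...] = (3.0, 2.0, 1.3)
    labels: dict[str, int] = field(default_factory=lambda: dict(PHANTOM_LABELS))

    def __post_init__(self) -> None:
        if min(self.shape) < 48:
            raise ValueError("phantom grid must be at least 48 voxels per axis")
        if not 2 <= self.n_lobes <= 5:
            raise ValueError("n_lobes must be between 2 and 5")
        if self.nodule_radius_mm <= 0:
            raise ValueError("nodule radius must be positive")


def default_tissue_config(spec: PhantomSpec | None = None) -> TissueConfig:
    """Tissue roles for the phantom vocabulary.

    Bones, heart, airways and non-target lobes are opaque (hard obstacles);
    body, skin and the target lobe absorb at 0.02/mm; vessels at 0.1/mm in
    the vessel channel; the nodule is the transparent target.
    """
    lab = (spec.labels if spec is not None else PHANTOM_LABELS)
    roles = {
        lab["background"]: "transparent",
        lab["body"]: "absorbing",
        lab["skin"]: "absorbing",
        lab["lobe_target"]: "absorbing",
        lab["lobe_other"]: "opaque",
        lab["vessel"]: "absorbing",
        lab["bone"]: "opaque",
        lab["heart"]: "opaque",
        lab["airway"]: "opaque",
        lab["nodule"]: "target",
    }
    k = {label: 0.0 for label in roles}
    for name in ("body", "skin", "lobe_target"):
        k[lab[name]] = 0.02
    k[lab["vessel"]] = 0.1
    return TissueConfig(
        roles=roles,
        k=k,
        vascular=frozenset({lab["vessel"]}),
        skin_label=lab["skin"],
    )


def _ellipsoid(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _stamp_capsules(mask: np.ndarray, coords, spacing_mm: float, segments) -> None:
    """OR capsule solids (segment p->q dilated by radius r, all mm) into mask."""
    x, y, z = coords
    for p, q, r in segments:
        p = np.asarray(p, float)
        q = np.asarray(q, float)
        d = q - p
        seg_len2 = float(d @ d)
        # restrict work to the capsule's bounding box
        lo = np.minimum(p, q) - r
        hi = np.maximum(p, q) + r
        sub = (
            (x >= lo[0]) & (x <= hi[0])
            & (y >= lo[1]) & (y <= hi[1])
            & (z >= lo[2]) & (z <= hi[2])
        )
        idx = np.nonzero(sub)
        if idx[0].size == 0:
            continue
        pts = np.stack(idx, axis=1) * spacing_mm - p
        if seg_len2 > 0:
            t = np.clip(pts @ d / seg_len2, 0.0, 1.0)
            closest = t[:, None] * d
        else:
            closest = np.zeros_like(pts)
        dist2 = np.sum((pts - closest) ** 2, axis=1)
        inside = dist2 <= r * r
        mask[idx[0][inside], idx[1][inside], idx[2][inside]] = True


def _vessel_tree(rng, root, first_dir, radii, length0) -> list:
    """Recursive 2-way branching; returns (p, q, radius) capsule segments."""
    segments = []

    def grow(p, direction, level, length):
        if level >= len(radii):
            return
        direction = direction / np.linalg.norm(direction)
        q = p + direction * length
        segments.append((p, q, radii[level]))
        for _ in range(2):
            jitter = rng.normal(scale=0.6, size=3)
            child = direction + jitter
            grow(q, child, level + 1, length * 0.7)

    grow(np.asarray(root, float), np.asarray(first_dir, float), 0, length0)
    return segments


def _build(spec: PhantomSpec, rng: np.random.Generator) -> LabelVolume:
    lab = spec.labels
    sp = float(spec.spacing_mm)
    shape = tuple(spec.shape)
    spacing = np.array([sp, sp, sp])
    origin = np.zeros(3)
    ax = [np.arange(n) * sp for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij", sparse=True)
    coords = (x, y, z)
    c = (np.array(shape, float) - 1) / 2 * sp  # grid centre, mm
    half = np.array(shape, float) * sp / 2

    rb = np.array([0.80, 0.64, 0.86]) * half  # body radii
    labels = np.zeros(shape, dtype=np.int32)
    body = _ellipsoid(coords, c, rb)
    labels[body] = lab["body"]

    # lungs: nodule host on +x side, the other mirrored and slightly smaller
    host_c = c + np.array([0.42 * rb[0], 0.0, 0.02 * rb[2]])
    host_r = np.array([0.42, 0.60, 0.72]) * rb
    other_c = c + np.array([-0.42 * rb[0], 0.0, 0.02 * rb[2]])
    other_r = np.array([0.38, 0.55, 0.68]) * rb
    host = _ellipsoid(coords, host_c, host_r)
    other = _ellipsoid(coords, other_c, other_r)
    labels[other] = lab["lobe_other"]

    # split the host lung into n_lobes slabs along a tilted anterior axis;
    # the most anterior (smallest y) slab hosts the nodule
    tilt = rng.uniform(-0.25, 0.25)
    u = np.broadcast_to(y + tilt * (z - c[2]), shape)[host]
    edges = np.quantile(u, np.linspace(0, 1, spec.n_lobes + 1))
    hi, hj, hk = np.nonzero(host)
    slab = np.searchsorted(edges[1:-1], u, side="right")
    labels[hi, hj, hk] = np.where(slab == 0, lab["lobe_target"], lab["lobe_other"])

    # heart: opaque blob, medial and slightly anterior-inferior
    heart_c = c + np.array([-0.28, -0.08, -0.18]) * rb + rng.normal(scale=1.5, size=3)
    heart_r = np.array([0.30, 0.32, 0.28]) * rb
    labels[_ellipsoid(coords, heart_c, heart_r)] = lab["heart"]

    # airway: vertical opaque tube from the top of the body to mid-chest
    airway = np.zeros(shape, bool)
    top = c + np.array([0.0, 0.08 * rb[1], 0.85 * rb[2]])
    mid = c + np.array([0.0, 0.08 * rb[1], 0.05 * rb[2]])
    _stamp_capsules(airway, coords, sp, [(top, mid, min(3.5, 0.06 * rb[0]))])
    labels[airway & body] = lab["airway"]

    # vessels: one branching tree per lung, rooted at the medial hilum
    vessels = np.zeros(shape, bool)
    for lung_c, lung_r, sign in ((host_c, host_r, 1.0), (other_c, other_r, -1.0)):
        root = lung_c - np.array([sign * 0.8 * lung_r[0], 0.0, 0.0])
        first = np.array([sign, 0.0, 0.0]) + rng.normal(scale=0.3, size=3)
        segs = _vessel_tree(rng, root, first, spec.vessel_radii_mm, 0.55 * lung_r[0])
        _stamp_capsules(vessels, coords, sp, segs)
    in_lung = host | other
    labels[vessels & in_lung] = lab["vessel"]

    # ribs: one closed ring per level, following the body cross-section,
    # opaque; puncture corridors run through the intercostal spaces, so
    # each inter-rib window projects to its own candidate region
    rib_centres = np.zeros(shape, bool)
    zs = c[2] + np.linspace(-0.5, 0.5, spec.n_ribs) * rb[2]
    thetas = np.deg2rad(np.arange(0.0, 360.0, 2.0))
    for zi in zs:
        f = np.sqrt(max(0.0, 1.0 - ((zi - c[2]) / rb[2]) ** 2))
        px = c[0] + 0.88 * rb[0] * f * np.cos(thetas)
        py = c[1] + 0.88 * rb[1] * f * np.sin(thetas)
        ii = np.round(px / sp).astype(int)
        jj = np.round(py / sp).astype(int)
        kk = np.full_like(ii, int(round(zi / sp)))
        ok = (
            (ii >= 0) & (ii < shape[0])
            & (jj >= 0) & (jj < shape[1])
            & (kk >= 0) & (kk < shape[2])
        )
        rib_centres[ii[ok], jj[ok], kk[ok]] = True
    dist = ndimage.distance_transform_edt(~rib_centres, sampling=spacing)
    ribs = (dist <= spec.rib_radius_mm) & _ellipsoid(coords, c, rb * 0.97)
    labels[ribs] = lab["bone"]

    # nodule: deep inside the target lobe, away from its boundary
    lobe = labels == lab["lobe_target"]
    depth = ndimage.distance_transform_edt(lobe, sampling=spacing)
    need = spec.nodule_radius_mm + sp
    cand = np.nonzero(depth >= need)
    if cand[0].size == 0:
        raise ValueError(
            "infeasible phantom spec: nodule radius exceeds the target lobe"
        )
    # draw among the deepest quintile so placement varies with the seed
    dvals = depth[cand]
    keep = dvals >= np.quantile(dvals, 0.8)
    pick = rng.integers(int(keep.sum()))
    sel = np.nonzero(keep)[0][pick]
    nod_c = np.array([cand[0][sel], cand[1][sel], cand[2][sel]]) * sp
    nod = (
        (x - nod_c[0]) ** 2 + (y - nod_c[1]) ** 2 + (z - nod_c[2]) ** 2
    ) <= spec.nodule_radius_mm**2
    labels[nod] = lab["nodule"]

    # skin: the one-voxel outer shell of the body component
    body_mask = labels != lab["background"]
    interior = ndimage.binary_erosion(body_mask, structure=np.ones((3, 3, 3)))
    labels[body_mask & ~interior] = lab["skin"]

    return LabelVolume(labels=labels, spacing=spacing, origin=origin)


def _has_corridor(vol: LabelVolume, spec: PhantomSpec, n_dirs: int = 400) -> bool:
    """Brute-force ray sweep: does any straight ray from the nodule centre
    reach the skin while touching only traversable labels?"""
    lab = spec.labels
    allowed = {
        lab["nodule"], lab["lobe_target"], lab["body"], lab["skin"], lab["vessel"],
    }
    labels = vol.labels
    shape = np.array(labels.shape)
    nod = np.argwhere(labels == lab["nodule"])
    if nod.size == 0:
        return False
    centre = nod.mean(axis=0)
    # Fibonacci sphere directions
    i = np.arange(n_dirs)
    phi = np.arccos(1 - 2 * (i + 0.5) / n_dirs)
    theta = np.pi * (1 + 5**0.5) * i
    dirs = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )
    max_t = float(shape.max())
    ts = np.arange(0.0, max_t, 0.4)
    for d in dirs:
        pts = centre + ts[:, None] * d
        idx = np.rint(pts).astype(int)
        inb = np.all((idx >= 0) & (idx < shape), axis=1)
        ok = True
        for m in range(len(ts)):
            if not inb[m]:
                ok = False
                break
            v = labels[idx[m, 0], idx[m, 1], idx[m, 2]]
            if v == lab["skin"]:
                break
            if v not in allowed:
                ok = False
                break
        else:
            ok = False
        if ok:
            return True
    return False


def generate_phantom(spec: PhantomSpec, max_attempts: int = 20) -> LabelVolume:
    """Generate a phantom; deterministic for a fixed spec (seed included).

    The sampled geometry is accepted only if a brute-force ray sweep finds
    an obstacle-free corridor from the nodule to the skin; otherwise the
    geometry is re-drawn (still seed-deterministic) up to ``max_attempts``.
    """
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([spec.seed, attempt])
        try:
            vol = _build(spec, rng)
        except ValueError as err:  # this draw's lobe too small for the nodule
            last_err = err
            continue
        if _has_corridor(vol, spec):
            return vol
    if last_err is not None:
        raise ValueError(str(last_err))
    raise RuntimeError(
        f"no corridor-containing phantom found in {max_attempts} attempts "
        f"for seed {spec.seed}"
    )


def annotate_regions_rulebased(
    regions,
    image_shape: tuple[int, int],
    flip_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Label exactly one candidate region positive by a fixed surrogate rule.

    The "surgeon" prefers the region maximizing area x mean green-channel
    intensity (large, shallow/low-absorbance windows); ties break toward
    the centroid closest to the image centre, then by list order.  Because
    the rule is fixed and documented, a classifier's ability to recover it
    is measurable.  ``flip_rate`` optionally flips labels independently at
    random for robustness experiments.
    """
    if len(regions) == 0:
        raise ValueError("no regions to annotate")
    centre = (np.array(image_shape, float) - 1) / 2
    scores = []
    for r in regions:
        green = float(np.mean(r.intensities[:, 1])) if r.intensities.size else 0.0
        dist = float(np.linalg.norm(np.asarray(r.centroid) - centre))
        scores.append((r.area * green, -dist))
    best = max(range(len(regions)), key=lambda i: (scores[i][0], scores[i][1], -i))
    out = np.zeros(len(regions), dtype=bool)
    out[best] = True
    if flip_rate > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(regions)) < flip_rate
        out = out ^ flip
    return out
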