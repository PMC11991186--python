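"""Label-volume I/O, isotropic resampling and tissue-role configuration.

The planner consumes multi-label segmentation masks (NIfTI or NRRD) in
which each integer label denotes an anatomical structure.  All geometry is
expressed in world millimetres with a voxel-center convention: voxel
``(0, 0, 0)`` is centred at ``origin`` and voxel ``(i, j, k)`` at
``origin + (i, j, k) * spacing``.  Arrays are indexed ``(x, y, z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import SimpleITK as sitk
import yaml

__all__ = [
    "LabelVolume",
    "TissueConfig",
    "read_label_volume",
    "write_label_volume",
    "resample_isotropic",
    "read_tissue_config",
    "tissue_config_from_dict",
]

#: Default per-mm absorption coefficients for the two translucent classes:
#: ordinary soft tissue attenuates lightly, pulmonary vessels more strongly
#: so that accumulated vessel thickness darkens a candidate direction.
DEFAULT_K_TISSUE = 0.02
DEFAULT_K_VESSEL = 0.1

_ROLES = frozenset({"opaque", "absorbing", "transparent", "target"})


@dataclass(frozen=True)
class LabelVolume:
    """A 3D integer label grid with world spacing and origin (mm)."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        spacing = np.asarray(self.spacing, dtype=float)
        origin = np.asarray(self.origin, dtype=float)
        if spacing.shape != (3,) or origin.shape != (3,):
            raise ValueError("spacing and origin must be length-3 vectors")
        if np.any(spacing <= 0):
            raise ValueError(f"spacing must be positive, got {spacing}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def index_to_world(self, index) -> np.ndarray:
        """World coordinate (mm) of a (possibly fractional) voxel index."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_to_index(self, point) -> np.ndarray:
        """Continuous voxel index of a world point (mm)."""
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def contains_world(self, point) -> bool:
        idx = self.world_to_index(point)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))

    def label_at_world(self, point) -> int:
        idx = np.rint(self.world_to_index(point)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            return 0
        return int(self.labels[tuple(idx)])

    def label_set(self) -> set[int]:
        return set(np.unique(self.labels).tolist())


def _from_sitk(img: sitk.Image) -> LabelVolume:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            "only axis-aligned volumes are supported (direction matrix must be identity); "
            "reorient the mask before planning"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if np.issubdtype(arr.dtype, np.floating):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-6):
            raise ValueError(
                "non-integer labels: file looks like a probability map, not a label mask"
            )
        arr = rounded.astype(np.int32)
    labels = np.ascontiguousarray(arr.transpose(2, 1, 0).astype(np.int32))
    return LabelVolume(
        labels=labels,
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
    )


def _to_sitk(vol: LabelVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.labels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI (``.nii``/``.nii.gz``) or NRRD label volume.

    Spacing and origin come from the image header.  Float-typed files are
    accepted only when every voxel is exactly integral.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _from_sitk(sitk.ReadImage(str(path)))


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a label volume to NIfTI or NRRD (chosen by file extension)."""
    sitk.WriteImage(_to_sitk(vol), str(Path(path)))


def resample_isotropic(vol: LabelVolume) -> LabelVolume:
    """Resample to isotropic voxels at the smallest input spacing.

    Nearest-neighbour interpolation is used so no label values can be
    invented.  Already-isotropic volumes are returned unchanged.
    """
    target = float(vol.spacing.min())
    if np.allclose(vol.spacing, target):
        return vol
    img = _to_sitk(vol)
    new_size = [
        int(round(n * s / target)) for n, s in zip(vol.shape, vol.spacing)
    ]
    resampler = sitk.ResampleImageFilter()
    resampler.SetInterpolator(sitk.sitkNearestNeighbor)
    resampler.SetOutputSpacing((target, target, target))
    resampler.SetOutputOrigin(img.GetOrigin())
    resampler.SetOutputDirection(img.GetDirection())
    resampler.SetSize(new_size)
    return _from_sitk(resampler.Execute(img))


@dataclass(frozen=True)
class TissueConfig:
    """Maps each label to an optical role and holds planner weights.

    Roles
    -----
    ``opaque``
        Hard obstacle (bone, heart, non-target lobes, airways, ...); blocks
        every ray that touches it.
    ``absorbing``
        Translucent; attenuates per the Beer-Lambert law with coefficient
        ``k`` (per mm).  Labels in ``vascular`` accumulate into the vessel
        attenuation channel, all others into the soft-tissue channel.
    ``transparent`` / ``target``
        No attenuation (``k = 0``).

    ``weights`` are the exponents (alpha, beta, gamma) applied to the
    tissue, reflection and vessel attenuation terms when composing the
    final intensity.
    """

    roles: Mapping[int, str]
    k: Mapping[int, float]
    vascular: frozenset = frozenset()
    skin_label: int | None = None
    obstacle_margin_mm: float = 2.0
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    thresholds: tuple[float, float, float] = (0.0, 0.05, 0.0)
    min_area: int = 25

    def __post_init__(self) -> None:
        for label, role in self.roles.items():
            if role not in _ROLES:
                raise ValueError(f"label {label}: unknown role {role!r}")
        for label, kk in self.k.items():
            if kk < 0:
                raise ValueError(f"label {label}: k must be >= 0, got {kk}")
        if self.obstacle_margin_mm < 0:
            raise ValueError("obstacle_margin_mm must be >= 0")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights (alpha, beta, gamma) must be >= 0")

    def validate_against(self, vol: LabelVolume) -> None:
        missing = sorted(vol.label_set() - set(self.roles))
        if missing:
            raise ValueError(
                f"labels present in volume but absent from tissue config: {missing}"
            )

    def role_of(self, label: int) -> str:
        return self.roles[label]

    def k_of(self, label: int) -> float:
        return self.k.get(label, 0.0)


def tissue_config_from_dict(doc: Mapping, vol: LabelVolume | None = None) -> TissueConfig:
    """Build a :class:`TissueConfig` from a parsed YAML/JSON document.

    Each entry of ``doc["labels"]`` is either a bare role string or a
    mapping ``{role: ..., k: ..., class: tissue|vessel}``.  The shorthand
    roles ``soft`` and ``vessel`` mean "absorbing" with the class-default
    coefficient (0.02 and 0.1 per mm respectively).
    """
    raw = doc.get("labels")
    if not isinstance(raw, Mapping):
        raise ValueError("tissue config must contain a 'labels' mapping")
    roles: dict[int, str] = {}
    k: dict[int, float] = {}
    vascular: set[int] = set()
    for label_key, entry in raw.items():
        label = int(label_key)
        if isinstance(entry, str):
            entry = {"role": entry}
        role = str(entry["role"]).lower()
        is_vessel = str(entry.get("class", "")).lower() == "vessel"
        if role == "soft":
            role = "absorbing"
        elif role == "vessel":
            role, is_vessel = "absorbing", True
        if role not in _ROLES:
            raise ValueError(f"label {label}: unknown role {role!r}")
        roles[label] = role
        if role == "absorbing":
            default = DEFAULT_K_VESSEL if is_vessel else DEFAULT_K_TISSUE
            k[label] = float(entry.get("k", default))
            if is_vessel:
                vascular.add(label)
        else:
            k[label] = 0.0
    weights = doc.get("weights", {})
    thresholds = doc.get("thresholds", {})
    cfg = TissueConfig(
        roles=roles,
        k=k,
        vascular=frozenset(vascular),
        skin_label=(int(doc["skin_label"]) if "skin_label" in doc else None),
        obstacle_margin_mm=float(doc.get("obstacle_margin_mm", 2.0)),
        weights=(
            float(weights.get("alpha", 1.0)),
            float(weights.get("beta", 1.0)),
            float(weights.get("gamma", 1.0)),
        ),
        thresholds=(
            float(thresholds.get("r", 0.0)),
            float(thresholds.get("g", 0.05)),
            float(thresholds.get("b", 0.0)),
        ),
        min_area=int(doc.get("min_area", 25)),
    )
    if vol is not None:
        cfg.validate_against(vol)
    return cfg


def read_tissue_config(path: str | Path, vol: LabelVolume | None = None) -> TissueConfig:
    """Read a YAML (or JSON, a YAML subset) tissue configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return tissue_config_from_dict(doc, vol)
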