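"""Surgeon-preference modelling and end-to-end trajectory assembly.

Candidate regions extracted from many projection images form an
imbalanced binary dataset (one preferred region among several per image).
Training follows the standard recipe for such data: a grouped 7:1:2
image-level split (regions of one image never straddle splits), SMOTE
oversampling of the minority class on the training split only, and a
100-tree depth-10 random forest with balanced class weights as the
default model (gradient-boosting and MLP alternatives share the same
interface).  At inference the region with the highest predicted
probability wins, is eroded to a single pixel, and the pixel is
reverse-mapped to a 3D skin entry point, giving the final straight
needle path with its clinical metrics (depth, skin angle, minimum
obstacle clearance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

from . import optics, projection, regions as regions_mod
from .geometry import SphereFrame
from .roi import NeedleQuery, crop_roi
from .volume_io import LabelVolume, TissueConfig, resample_isotropic

__all__ = [
    "RegionDataset",
    "NeedlePath",
    "PlanResult",
    "NoFeasiblePathError",
    "split_by_group",
    "balance_training_set",
    "train_region_classifier",
    "evaluate_classifier",
    "save_model",
    "load_model",
    "select_region",
    "plan_path",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionDataset:
    """Feature matrix with binary labels and per-image group ids."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: tuple[str, ...] = regions_mod.FEATURE_NAMES

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must have equal length")

    def subset(self, idx) -> "RegionDataset":
        return RegionDataset(self.X[idx], self.y[idx], self.groups[idx], self.feature_names)


def split_by_group(
    ds: RegionDataset,
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Leakage-free grouped split: whole images go to one subset.

    Unique group ids are shuffled and partitioned by the given ratios
    (default 7:1:2 train/val/test).  Returns index arrays; asserts that no
    group id spans two splits.
    """
    rng = np.random.default_rng(seed)
    uniq = np.unique(ds.groups)
    rng.shuffle(uniq)
    n = len(uniq)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    parts = {
        "train": set(uniq[:n_train].tolist()),
        "val": set(uniq[n_train:n_train + n_val].tolist()),
        "test": set(uniq[n_train + n_val:].tolist()),
    }
    out = {
        name: np.nonzero(np.isin(ds.groups, sorted(ids)))[0]
        for name, ids in parts.items()
    }
    for a in ("train", "val", "test"):
        for b in ("train", "val", "test"):
            if a < b:
                assert not (set(ds.groups[out[a]]) & set(ds.groups[out[b]]))
    return out


def balance_training_set(ds: RegionDataset, seed: int = 0, k_neighbors: int = 5) -> RegionDataset:
    """SMOTE-style minority oversampling to exact class parity.

    Synthetic minority samples are uniform interpolations between a
    minority sample and one of its k nearest minority neighbours.  Apply
    to the training split only.  Deterministic given the seed.
    """
    y = ds.y.astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == n_neg:
        return ds
    minority = y if n_pos < n_neg else ~y
    n_min, n_new = int(minority.sum()), abs(n_neg - n_pos)
    if n_min < 2:
        raise ValueError(
            "SMOTE needs at least 2 minority samples; use the rule-based "
            "fallback for degenerate training sets"
        )
    Xm = ds.X[minority]
    gm = ds.groups[minority]
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, nbr = nn.kneighbors(Xm)
    rng = np.random.default_rng(seed)
    base = rng.integers(n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)  # skip self at column 0
    u = rng.random(n_new)[:, None]
    partner = nbr[base, pick]
    X_new = Xm[base] + u * (Xm[partner] - Xm[base])
    y_new = np.full(n_new, bool(n_pos < n_neg))
    return RegionDataset(
        np.vstack([ds.X, X_new]),
        np.concatenate([ds.y.astype(bool), y_new]),
        np.concatenate([ds.groups, gm[base]]),
        ds.feature_names,
    )


def _make_model(spec: str, seed: int):
    if spec == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, max_depth=10, class_weight="balanced",
            random_state=seed, n_jobs=1,
        )
    if spec == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=100, max_depth=6, random_state=seed)
    mlp_layers = {
        "mlp_simple": (100,),
        "mlp_deep": (100, 50),
        "mlp_wide": (200,),
        "mlp_complex": (150, 75, 30),
    }
    if spec in mlp_layers:
        return MLPClassifier(
            hidden_layer_sizes=mlp_layers[spec], activation="relu",
            solver="adam", max_iter=300, random_state=seed,
        )
    raise ValueError(f"unknown model spec {spec!r}")


@dataclass
class TrainedRecommender:
    """A fitted region classifier bound to a frozen feature list."""

    model: object
    feature_names: tuple[str, ...]
    feature_version: int = regions_mod.FEATURE_VERSION
    metrics: dict = dc_field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, float))[:, 1]


def evaluate_classifier(model, X, y) -> dict:
    """AUC-ROC, precision/recall/F1, specificity and the confusion matrix."""
    prob = model.predict_proba(np.asarray(X, float))[:, 1]
    pred = prob >= 0.5
    y = np.asarray(y, bool)
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[False, True]).ravel()
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "auc_roc": float(roc_auc_score(y, prob)) if 0 < y.sum() < len(y) else float("nan"),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "specificity": float(tn / (tn + fp)) if tn + fp else 0.0,
        "confusion": {"tp": int(tp), "fp": int(fp), "tn": int(tn), "fn": int(fn)},
    }


def train_region_classifier(
    train: RegionDataset,
    val: RegionDataset | None = None,
    model: str = "random_forest",
    seed: int = 0,
) -> TrainedRecommender:
    """Fit a region classifier on a (balanced) training split."""
    y = train.y.astype(bool)
    if y.all() or not y.any():
        raise ValueError("training data contains a single class")
    clf = _make_model(model, seed)
    clf.fit(np.asarray(train.X, float), y)
    rec = TrainedRecommender(model=clf, feature_names=train.feature_names)
    if val is not None and len(val.y):
        rec.metrics = evaluate_classifier(clf, val.X, val.y)
    return rec


def save_model(rec: TrainedRecommender, path: str | Path) -> None:
    joblib.dump(
        {
            "format": "lumipath-recommender",
            "feature_version": rec.feature_version,
            "feature_names": list(rec.feature_names),
            "model": rec.model,
            "metrics": rec.metrics,
        },
        str(path),
    )


def load_model(path: str | Path) -> TrainedRecommender:
    doc = joblib.load(str(path))
    if doc.get("format") != "lumipath-recommender":
        raise ValueError(f"{path} is not a saved recommender")
    if doc["feature_version"] != regions_mod.FEATURE_VERSION:
        raise ValueError(
            f"model was trained on feature version {doc['feature_version']}, "
            f"this release provides version {regions_mod.FEATURE_VERSION}"
        )
    return TrainedRecommender(
        model=doc["model"],
        feature_names=tuple(doc["feature_names"]),
        feature_version=doc["feature_version"],
        metrics=doc.get("metrics", {}),
    )


def select_region(rec: TrainedRecommender | None, region_list: list) -> int:
    """Index of the winning region: argmax predicted probability.

    Ties break toward the larger area, then the centroid nearest the
    image centre.  With no model, the same area x mean-green heuristic
    used for rule-based annotation ranks the regions.
    """
    if not region_list:
        raise NoFeasiblePathError("no_region_above_thresholds")
    if rec is not None:
        X = np.stack([r.features for r in region_list])
        probs = rec.predict_proba(X)
    else:
        probs = np.array([r.area * float(r.intensities[:, 1].mean()) for r in region_list])
        if probs.max() > 0:
            probs = probs / probs.max()
    for r, p in zip(region_list, probs):
        r.probability = float(p)
    centre = (np.array(region_list[0].image_shape, float) - 1) / 2
    keys = [
        (
            round(float(p), 12),
            r.area,
            -float(np.linalg.norm(np.asarray(r.centroid) - centre)),
            -i,
        )
        for i, (r, p) in enumerate(zip(region_list, probs))
    ]
    return int(max(range(len(keys)), key=lambda i: keys[i]))


@dataclass(frozen=True)
class NeedlePath:
    """A straight trajectory with its clinical metrics."""

    entry_mm: np.ndarray
    target_mm: np.ndarray
    direction: np.ndarray      # unit vector, target -> entry
    depth_mm: float
    skin_angle_deg: float      # angle between needle and the skin plane
    min_obstacle_distance_mm: float

    def to_dict(self) -> dict:
        return {
            "entry_mm": [float(v) for v in self.entry_mm],
            "target_mm": [float(v) for v in self.target_mm],
            "direction": [float(v) for v in self.direction],
            "depth_mm": float(self.depth_mm),
            "skin_angle_deg": float(self.skin_angle_deg),
            "min_obstacle_distance_mm": float(self.min_obstacle_distance_mm),
        }


@dataclass
class PlanResult:
    """Full audit trail of one planning run."""

    path: NeedlePath
    shell: optics.ShellMap
    image: projection.ProjectionImage
    regions: list
    chosen_region: int
    entry_pixel: tuple[int, int]
    roi: object
    field: optics.AbsorptionField


class NoFeasiblePathError(RuntimeError):
    """Raised when no clinically feasible straight path exists.

    ``reason`` is one of ``no_skin_reach`` (needle cannot reach skin in
    any direction), ``full_occlusion`` (every skin-reaching direction is
    blocked by an obstacle) or ``no_region_above_thresholds``.
    """

    def __init__(self, reason: str):
        super().__init__(f"no feasible path: {reason}")
        self.reason = reason


def _min_obstacle_distance(field: optics.AbsorptionField, shell, i, j) -> float:
    """Minimum distance (mm) to un-dilated obstacles along entry->target,
    sampled every half voxel against the exact distance transform."""
    depth = float(shell.depth_mm[i, j])
    d = shell.frame.direction(shell.phi_deg[i], shell.lam_deg[j])
    step = 0.5 * field.spacing_mm
    ts = np.arange(0.0, depth + step, step)
    ts[-1] = min(ts[-1], depth)
    pos = field.center_index + ts[:, None] * d[None, :] / field.spacing_mm
    shape = np.array(field.labels.shape)
    idx = np.clip(np.rint(pos).astype(int), 0, shape - 1)
    return float(field.obstacle_distance[idx[:, 0], idx[:, 1], idx[:, 2]].min())


def plan_path(
    vol: LabelVolume,
    q: NeedleQuery,
    cfg: TissueConfig,
    model: TrainedRecommender | None = None,
    resolution_deg: float = 1.0,
    manual_region: int | None = None,
    frame: SphereFrame | None = None,
) -> PlanResult:
    """Run the full pipeline: masks -> illumination -> projection ->
    regions -> selection -> 3D entry point.

    ``manual_region`` replaces the classifier stage with an explicit
    region index (the manual-selection mode).  Raises
    :class:`NoFeasiblePathError` with a structured reason when no
    feasible trajectory exists.
    """
    vol = resample_isotropic(vol)
    cfg.validate_against(vol)
    t_role = cfg.roles.get(vol.label_at_world(q.target))
    if t_role not in ("target", "absorbing"):
        raise ValueError(
            f"target point lies in a voxel with role {t_role!r}; expected "
            "'target' or 'absorbing'"
        )
    roi = crop_roi(vol, q)
    field = optics.build_absorption_field(roi, cfg)
    field = optics.dilate_obstacles(field, cfg.obstacle_margin_mm)
    shell = optics.compute_shell_map(
        roi, field, resolution_deg=resolution_deg, weights=cfg.weights, frame=frame
    )
    if not shell.iobs.any():
        reachable = shell.skin_reachable
        reason = (
            "full_occlusion"
            if reachable is not None and reachable.any()
            else "no_skin_reach"
        )
        raise NoFeasiblePathError(reason)
    img = projection.project_sinusoidal(shell)
    region_list = regions_mod.segment_safe_regions(
        img, thresholds=cfg.thresholds, min_area=cfg.min_area
    )
    if not region_list:
        raise NoFeasiblePathError("no_region_above_thresholds")
    if manual_region is not None:
        if not 0 <= manual_region < len(region_list):
            raise ValueError(f"manual region index {manual_region} out of range")
        chosen = manual_region
    else:
        chosen = select_region(model, region_list)
    entry_pixel = regions_mod.erode_to_point(region_list[chosen])
    entry = projection.pixel_to_entry_point(img, shell, entry_pixel)

    i, j = img.node_index[entry_pixel[0], entry_pixel[1]]
    target = roi.center_world  # target snapped to the grid used for casting
    delta = entry - target
    depth = float(np.linalg.norm(delta))
    direction = delta / depth
    cos_theta = float(shell.cos_theta[i, j])
    skin_angle = float(np.degrees(np.arcsin(np.clip(cos_theta, 0.0, 1.0))))
    min_dist = _min_obstacle_distance(field, shell, i, j)
    path = NeedlePath(
        entry_mm=entry,
        target_mm=target,
        direction=direction,
        depth_mm=depth,
        skin_angle_deg=skin_angle,
        min_obstacle_distance_mm=min_dist,
    )
    return PlanResult(
        path=path, shell=shell, image=img, regions=region_list,
        chosen_region=chosen, entry_pixel=entry_pixel, roi=roi, field=field,
    )
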