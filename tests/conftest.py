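import numpy as np
import pytest

import lumipath as lp
from lumipath import optics


#: Miniature 48 mm phantom used throughout the optics tests: structure
#: sizes are scaled so ribs/vessels/nodule stay resolvable at 1 mm voxels.
MINI = dict(
    shape=(48, 48, 48),
    spacing_mm=1.0,
    n_ribs=3,
    rib_radius_mm=2.0,
    nodule_radius_mm=3.0,
    vessel_radii_mm=(2.0, 1.4, 1.0),
)


def mini_spec(seed: int = 0) -> lp.PhantomSpec:
    return lp.PhantomSpec(seed=seed, **MINI)


def nodule_target(vol: lp.LabelVolume, spec: lp.PhantomSpec) -> np.ndarray:
    nod = np.argwhere(vol.labels == spec.labels["nodule"])
    return vol.index_to_world(nod.mean(axis=0))


def uniform_field(
    half_voxels: int = 50,
    spacing_mm: float = 2.0,
    k_tissue: float = 0.02,
    k_vessel: float = 0.0,
    label: int = 1,
) -> optics.AbsorptionField:
    """A homogeneous absorbing cube (no obstacles, no skin)."""
    side = 2 * half_voxels + 1
    labels = np.full((side, side, side), label, dtype=np.int32)
    shape = labels.shape
    return optics.AbsorptionField(
        labels=labels,
        spacing_mm=spacing_mm,
        center_index=half_voxels,
        origin_world=np.zeros(3),
        k_tissue=np.full(shape, k_tissue),
        k_vessel=np.full(shape, k_vessel),
        opaque=np.zeros(shape, bool),
        opaque_original=np.zeros(shape, bool),
        obstacle_distance=np.full(shape, np.inf),
        skin_label=None,
    )


@pytest.fixture(scope="session")
def mini_phantom():
    spec = mini_spec(seed=0)
    vol = lp.generate_phantom(spec)
    return spec, vol


@pytest.fixture(scope="session")
def mini_roi_field(mini_phantom):
    """ROI (R = 20 mm) and absorption field around the mini phantom's nodule."""
    spec, vol = mini_phantom
    cfg = lp.default_tissue_config(spec)
    target = nodule_target(vol, spec)
    roi = lp.crop_roi(vol, lp.NeedleQuery(target=target, needle_mm=20.0))
    field = optics.build_absorption_field(roi, cfg)
    return spec, vol, cfg, roi, field
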