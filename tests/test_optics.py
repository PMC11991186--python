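import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage

import lumipath as lp
from lumipath import optics
from lumipath.optics import _cast_batch

from conftest import uniform_field


def _layered_field(layers, spacing=1.0):
    """Planar layers along +x from the centre voxel outwards.

    ``layers`` is a list of (n_voxels, k, is_vessel); the centre voxel
    belongs to the first layer.  Returns (field, expected per-class
    absorbances for a +x ray of length (sum n - 0.5) * spacing).
    """
    total = sum(n for n, _, _ in layers)
    half = total + 2
    side = 2 * half + 1
    labels = np.ones((side, side, side), np.int32)
    kt = np.zeros((side, side, side))
    kv = np.zeros((side, side, side))
    x = half  # centre
    exp_t = exp_v = 0.0
    first = True
    for n, k, vessel in layers:
        sl = slice(x, x + n)
        (kv if vessel else kt)[sl, :, :] = k
        length = (n - 0.5) * spacing if first else n * spacing
        if vessel:
            exp_v += k * length
        else:
            exp_t += k * length
        x += n
        first = False
    field = optics.AbsorptionField(
        labels=labels, spacing_mm=spacing, center_index=half,
        origin_world=np.zeros(3), k_tissue=kt, k_vessel=kv,
        opaque=np.zeros_like(labels, bool), opaque_original=np.zeros_like(labels, bool),
        obstacle_distance=np.full(labels.shape, np.inf),
    )
    return field, (total - 0.5) * spacing, exp_t, exp_v


class TestBeerLambert:
    @pytest.mark.parametrize("k", [0.0, 0.02, 0.1])
    @pytest.mark.parametrize("L", [0.0, 10.0, 100.0])
    def test_homogeneous_closed_form(self, k, L):
        field = uniform_field(half_voxels=50, spacing_mm=2.0, k_tissue=k)
        r = optics.cast_ray(field, [1.0, 0, 0], radius_mm=L)
        assert r.absorbance_tissue == pytest.approx(k * L, abs=1e-12)
        assert r.atra == pytest.approx(10.0 ** (-k * L), rel=1e-12)

    def test_per_class_separation_tissue_then_vessel(self):
        # ~50 mm of soft tissue followed by 10 mm of vessel
        field, L, exp_t, exp_v = _layered_field([(51, 0.02, False), (10, 0.1, True)])
        r = optics.cast_ray(field, [1.0, 0, 0], radius_mm=L)
        assert r.absorbance_tissue == pytest.approx(exp_t, abs=1e-9)
        assert r.absorbance_vessel == pytest.approx(exp_v, abs=1e-9)
        assert exp_v == pytest.approx(1.0)          # 10 mm at 0.1/mm
        assert r.avas == pytest.approx(0.1, rel=1e-9)

    def test_multiplicativity_over_concatenated_layers(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            nlay = rng.integers(2, 6)
            layers = [
                (int(rng.integers(3, 12)), float(rng.choice([0.0, 0.02, 0.05, 0.1])), bool(rng.integers(2)))
                for _ in range(nlay)
            ]
            field, L, exp_t, exp_v = _layered_field(layers)
            r = optics.cast_ray(field, [1.0, 0, 0], radius_mm=L)
            # product of per-layer attenuations == attenuation of the whole path
            assert r.atra * r.avas == pytest.approx(10.0 ** (-(exp_t + exp_v)), abs=1e-9)
            assert r.absorbance_tissue == pytest.approx(exp_t, abs=1e-9)
            assert r.absorbance_vessel == pytest.approx(exp_v, abs=1e-9)

    def test_opaque_voxel_stops_the_march(self):
        field = uniform_field(half_voxels=50, spacing_mm=1.0, k_tissue=0.02)
        field.opaque[80:, :, :] = True  # wall 29.5 mm from the centre face
        field.opaque_original = field.opaque.copy()
        r = optics.cast_ray(field, [1.0, 0, 0], radius_mm=50.0)
        assert r.iobs == 0
        assert r.stop_mm == pytest.approx(29.5)
        assert r.absorbance_tissue == pytest.approx(0.02 * 29.5, abs=1e-9)


class TestOracleEquivalence:
    def test_absorbance_matches_dense_line_integral(self, mini_roi_field):
        """500 random directions vs a brute-force dense sampler on the
        mini phantom's absorption field (opacity disabled so both sides
        integrate the full [0, R] segment)."""
        *_, roi, field = mini_roi_field
        clear = replace(field, opaque=np.zeros_like(field.opaque))
        R = roi.radius_mm
        rng = np.random.default_rng(1)
        d = rng.normal(size=(500, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]
        res = _cast_batch(clear, d, R)

        step = 0.01 * clear.spacing_mm
        n = int(round(R / step))
        t = (np.arange(n) + 0.5) * step
        pos = clear.center_index + t[None, :, None] * d[:, None, :] / clear.spacing_mm
        idx = np.rint(pos).astype(int)
        shape = np.array(clear.labels.shape)
        inb = np.all((idx >= 0) & (idx < shape), axis=2)
        idx = np.clip(idx, 0, shape - 1)
        kt = np.where(inb, clear.k_tissue[idx[..., 0], idx[..., 1], idx[..., 2]], 0)
        kv = np.where(inb, clear.k_vessel[idx[..., 0], idx[..., 1], idx[..., 2]], 0)
        A_t = (kt * step).sum(axis=1)
        A_v = (kv * step).sum(axis=1)
        for impl, oracle in [(res["absorbance_tissue"], A_t), (res["absorbance_vessel"], A_v)]:
            rel = np.abs(10.0 ** -impl - 10.0 ** -oracle) / 10.0 ** -oracle
            assert rel.max() < 0.01

    def test_optimization_toggles_change_nothing(self, mini_roi_field):
        *_, roi, field = mini_roi_field
        rng = np.random.default_rng(2)
        dirs = rng.normal(size=(60, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        for d in dirs:
            fast = optics.cast_ray(field, d, roi.radius_mm)
            slow = optics.cast_ray(
                field, d, roi.radius_mm, early_termination=False, skip_empty=False
            )
            assert abs(fast.absorbance_tissue - slow.absorbance_tissue) < 1e-12
            assert abs(fast.absorbance_vessel - slow.absorbance_vessel) < 1e-12
            assert fast.iobs == slow.iobs
            assert fast.depth_mm == slow.depth_mm or (
                np.isnan(fast.depth_mm) and np.isnan(slow.depth_mm)
            )

    def test_batch_equals_scalar_rays(self, mini_roi_field):
        *_, roi, field = mini_roi_field
        rng = np.random.default_rng(3)
        dirs = rng.normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        batch = _cast_batch(field, dirs, roi.radius_mm)
        for i, d in enumerate(dirs):
            one = optics.cast_ray(field, d, roi.radius_mm)
            assert abs(batch["absorbance_tissue"][i] - one.absorbance_tissue) < 1e-12
            assert abs(batch["absorbance_vessel"][i] - one.absorbance_vessel) < 1e-12
            assert bool(batch["iobs"][i]) == bool(one.iobs)


class TestLambertianAndComposition:
    @pytest.mark.parametrize(
        "theta_deg,expected", [(0.0, 1.0), (60.0, 0.5), (90.0, 0.0), (120.0, 0.0)]
    )
    def test_lambertian_cosine_law(self, theta_deg, expected):
        assert optics.lambertian(np.cos(np.deg2rad(theta_deg))) == pytest.approx(
            expected, abs=1e-12
        )

    def test_blocked_ray_has_zero_intensity(self):
        assert optics.compose_intensity(0.9, 0.9, 0.9, iobs=0) == 0.0

    def test_zero_exponents_reduce_to_feasibility_indicator(self):
        assert optics.compose_intensity(0.3, 0.2, 0.1, iobs=1, alpha=0, beta=0, gamma=0) == 1.0
        assert optics.compose_intensity(0.0, 0.0, 0.0, iobs=1, alpha=0, beta=0, gamma=0) == 1.0

    def test_exponent_arithmetic(self):
        assert optics.compose_intensity(0.5, 1.0, 1.0, iobs=1, alpha=2, beta=0, gamma=0) == pytest.approx(0.25)

    def test_monotone_in_each_term_and_exponent(self):
        rng = np.random.default_rng(0)
        a, r, v = rng.random((3, 10_000)) * 0.999 + 0.0005
        e = rng.random((3, 10_000)) * 3
        base = optics.compose_intensity(a, r, v, 1.0, *e.mean(axis=1))
        shrunk = optics.compose_intensity(a * 0.9, r, v, 1.0, *e.mean(axis=1))
        assert np.all(shrunk <= base + 1e-15)
        harder = optics.compose_intensity(a, r, v, 1.0, e.mean(axis=1)[0] + 1, e.mean(axis=1)[1], e.mean(axis=1)[2])
        assert np.all(harder <= base + 1e-15)  # terms < 1, larger exponent penalizes

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            optics.compose_intensity(0.5, 0.5, 0.5, 1, alpha=-1)


class TestSkinNormal:
    def test_flat_skin_plane_normal(self):
        side = 31
        labels = np.zeros((side, side, side), np.int32)
        labels[:, :, :20] = 1  # body below z = 20
        field = optics.AbsorptionField(
            labels=labels, spacing_mm=1.0, center_index=15, origin_world=np.zeros(3),
            k_tissue=np.zeros_like(labels, float), k_vessel=np.zeros_like(labels, float),
            opaque=np.zeros_like(labels, bool), opaque_original=np.zeros_like(labels, bool),
            obstacle_distance=np.full(labels.shape, np.inf),
        )
        n = optics.estimate_skin_normal(field, [15, 15, 19])
        np.testing.assert_allclose(n, [0, 0, 1], atol=1e-6)

    def test_spherical_body_normal_is_radial(self):
        side = 61
        c = (side - 1) / 2
        ax = np.arange(side)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
        labels = (r <= 25).astype(np.int32)
        field = optics.AbsorptionField(
            labels=labels, spacing_mm=1.0, center_index=int(c), origin_world=np.zeros(3),
            k_tissue=np.zeros_like(labels, float), k_vessel=np.zeros_like(labels, float),
            opaque=np.zeros_like(labels, bool), opaque_original=np.zeros_like(labels, bool),
            obstacle_distance=np.full(labels.shape, np.inf),
        )
        rng = np.random.default_rng(5)
        d = rng.normal(size=(200, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]
        worst = 0.0
        for di in d:
            p = np.array([c, c, c]) + 24.5 * di
            n = optics.estimate_skin_normal(field, p)
            ang = np.degrees(np.arccos(np.clip(n @ di, -1, 1)))
            worst = max(worst, ang)
        assert worst < 5.0

    def test_degenerate_gradient_returns_zero_vector(self):
        labels = np.ones((11, 11, 11), np.int32)  # no surface anywhere
        field = optics.AbsorptionField(
            labels=labels, spacing_mm=1.0, center_index=5, origin_world=np.zeros(3),
            k_tissue=np.zeros_like(labels, float), k_vessel=np.zeros_like(labels, float),
            opaque=np.zeros_like(labels, bool), opaque_original=np.zeros_like(labels, bool),
            obstacle_distance=np.full(labels.shape, np.inf),
        )
        assert not optics.estimate_skin_normal(field, [5, 5, 5]).any()


class TestObstacleDilation:
    def test_single_voxel_grows_to_euclidean_ball(self):
        field = uniform_field(half_voxels=10, spacing_mm=1.0, k_tissue=0.0)
        field.opaque[10, 10, 10] = True
        field.opaque_original = field.opaque.copy()
        field.obstacle_distance = ndimage.distance_transform_edt(~field.opaque, sampling=1.0)
        out = optics.dilate_obstacles(field, 2.0)
        ax = np.arange(21) - 10
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        ball = x**2 + y**2 + z**2 <= 4.0
        np.testing.assert_array_equal(out.opaque, ball)
        # distances stay relative to the original single voxel
        np.testing.assert_array_equal(out.obstacle_distance, field.obstacle_distance)

    def test_zero_margin_is_identity(self, mini_roi_field):
        *_, field = mini_roi_field
        out = optics.dilate_obstacles(field, 0.0)
        np.testing.assert_array_equal(out.opaque, field.opaque_original)

    def test_surviving_rays_keep_margin_clearance(self, mini_roi_field):
        *_, roi, field = mini_roi_field
        margin = 2.0
        dil = optics.dilate_obstacles(field, margin)
        rng = np.random.default_rng(11)
        dirs = rng.normal(size=(1000, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        res = _cast_batch(dil, dirs, roi.radius_mm)
        ok = np.nonzero(res["iobs"])[0]
        assert len(ok) > 10
        for i in ok:
            depth = res["depth"][i]
            ts = np.arange(0, depth, 0.25 * dil.spacing_mm)
            pos = dil.center_index + ts[:, None] * dirs[i] / dil.spacing_mm
            idx = np.rint(pos).astype(int)
            dmin = dil.obstacle_distance[idx[:, 0], idx[:, 1], idx[:, 2]].min()
            assert dmin > margin


class TestShellMap:
    def test_fully_encased_target_is_dark(self):
        side = 41
        labels = np.ones((side, side, side), np.int32)
        ax = np.arange(side) - 20
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        r2 = x**2 + y**2 + z**2
        labels[(r2 > 8**2) & (r2 <= 12**2)] = 6  # bone shell
        labels[(r2 > 15**2) & (r2 <= 16**2)] = 2  # skin
        labels[r2 > 16**2] = 0
        vol = lp.LabelVolume(labels=labels, spacing=np.ones(3), origin=np.zeros(3))
        cfg = lp.tissue_config_from_dict(
            {"labels": {0: "transparent", 1: "soft", 2: "soft", 6: "opaque"},
             "skin_label": 2},
        )
        roi = lp.crop_roi(vol, lp.NeedleQuery(target=np.full(3, 20.0), needle_mm=18.0))
        field = optics.build_absorption_field(roi, cfg)
        shell = optics.compute_shell_map(roi, field, resolution_deg=10.0)
        assert not shell.iobs.any()
        assert (shell.intensity == 0).all()

    def test_intensity_zero_wherever_infeasible(self, mini_roi_field):
        *_, roi, field = mini_roi_field
        shell = optics.compute_shell_map(roi, field, resolution_deg=6.0)
        assert shell.intensity.min() >= 0 and shell.intensity.max() <= 1
        assert (shell.intensity[~shell.iobs] == 0).all()
        assert np.isfinite(shell.depth_mm[shell.iobs]).all()
        assert (shell.depth_mm[shell.iobs] <= roi.radius_mm).all()

    def test_resolution_refinement_keeps_bright_fraction_stable(self, mini_roi_field):
        *_, roi, field = mini_roi_field
        fracs = {}
        for res in (4.0, 2.0):
            shell = optics.compute_shell_map(roi, field, resolution_deg=res)
            w = np.cos(np.deg2rad(shell.phi_deg))[:, None] * np.ones_like(shell.iobs, float)
            fracs[res] = float((w * shell.iobs).sum() / w.sum())
        assert fracs[2.0] == pytest.approx(fracs[4.0], abs=0.02)

    def test_build_field_roles(self, mini_roi_field):
        spec, _, cfg, roi, field = mini_roi_field
        lab = spec.labels
        assert field.opaque_original[roi.labels == lab["heart"]].all()
        assert (field.k_tissue[roi.labels == lab["body"]] == 0.02).all()
        assert (field.k_vessel[roi.labels == lab["vessel"]] == 0.1).all()
        assert (field.k_tissue[roi.labels == 0] == 0).all()
        assert not field.opaque_original[roi.labels == 0].any()
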