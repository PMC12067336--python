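"""Thresholding, lacuna labeling, KDE modes, calibration, paired stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import n2ibone.quantify as q
from n2ibone.metrics import percent_change


# ---------------------------------------------------------------- thresholds


def brute_force_yen(image: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive scan of Yen's maximum-correlation criterion."""
    hist, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    S1 = np.cumsum(p**2)
    S2 = S1[-1] - S1
    best, best_t = -np.inf, centers[0]
    for t in range(nbins - 1):
        if P1[t] in (0.0, 1.0) or S1[t] == 0 or S2[t] == 0:
            continue
        crit = np.log((P1[t] * (1 - P1[t])) ** 2 / (S1[t] * S2[t]))
        if crit > best:
            best, best_t = crit, centers[t]
    return best_t


def brute_force_otsu(image: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive scan of the between-class variance."""
    hist, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    w0 = np.cumsum(p)
    mu_cum = np.cumsum(p * centers)
    mu_tot = mu_cum[-1]
    best, best_t = -np.inf, centers[0]
    for t in range(nbins - 1):
        w1 = 1 - w0[t]
        if w0[t] == 0 or w1 == 0:
            continue
        m0 = mu_cum[t] / w0[t]
        m1 = (mu_tot - mu_cum[t]) / w1
        crit = w0[t] * w1 * (m0 - m1) ** 2
        if crit > best:
            best, best_t = crit, centers[t]
    return best_t


def two_gaussian_image(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    a = rng.normal(60, 12, 2000)
    b = rng.normal(180, 20, 3000)
    return np.concatenate([a, b]).reshape(50, 100)


class TestThreshold:
    def test_two_delta_histogram_separated(self):
        img = np.concatenate([np.full(60, 10.0), np.full(40, 200.0)]).reshape(10, 10)
        for method in ("yen", "otsu"):
            thr = q.threshold(img, method)
            assert 10.0 < thr < 200.0

    @pytest.mark.parametrize("seed", range(10))
    def test_yen_matches_brute_force(self, seed):
        img = two_gaussian_image(seed)
        bin_w = np.ptp(img) / 256
        assert q.threshold(img, "yen") == pytest.approx(
            brute_force_yen(img), abs=bin_w
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_otsu_matches_brute_force(self, seed):
        img = two_gaussian_image(seed)
        bin_w = np.ptp(img) / 256
        assert q.threshold(img, "otsu") == pytest.approx(
            brute_force_otsu(img), abs=bin_w
        )

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            q.threshold(np.ones((5, 5)))


# ------------------------------------------------------------------ labeling


class TestLabelLacunae:
    def test_single_voxel_filtered_out(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True  # 1.6³ = 4.096 µm³ < 50 µm³
        table = q.label_lacunae(mask, 1.6)
        assert len(table) == 0
        assert table.attrs["n_components_total"] == 1
        assert table.attrs["n_rejected"] == 1

    def test_hundred_voxel_blob_kept(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:7, 2:7, 2:6] = True  # 100 voxels → 409.6 µm³
        table = q.label_lacunae(mask, 1.6)
        assert len(table) == 1
        assert table.volume_um3.iloc[0] == pytest.approx(409.6)
        assert table.voxel_count.iloc[0] == 100

    def test_volume_equals_count_times_voxel_cubed(self):
        rng = np.random.default_rng(1)
        mask = ndimage.binary_dilation(rng.random((20, 20, 20)) > 0.97, iterations=2)
        table = q.label_lacunae(mask, 1.6, volume_range_um3=(0.0, np.inf))
        assert np.allclose(table.volume_um3, table.voxel_count * 1.6**3)

    def test_digital_ball_aspect_is_one(self):
        zz, yy, xx = np.ogrid[-8:9, -8:9, -8:9]
        ball = (zz**2 + yy**2 + xx**2 <= 25).astype(bool)
        table = q.label_lacunae(ball, 1.0, volume_range_um3=(0.0, np.inf))
        assert table.aspect_ratio.iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_digital_2_1_1_ellipsoid_aspect_is_half(self):
        zz, yy, xx = np.ogrid[-12:13, -7:8, -7:8]
        ell = ((zz / 12.0) ** 2 + (yy / 6.0) ** 2 + (xx / 6.0) ** 2 <= 1).astype(bool)
        table = q.label_lacunae(ell, 1.0, volume_range_um3=(0.0, np.inf))
        assert table.aspect_ratio.iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_aspect_invariant_under_rotation(self):
        zz, yy, xx = np.ogrid[-12:13, -7:8, -7:8]
        ell = ((zz / 10.0) ** 2 + (yy / 5.0) ** 2 + (xx / 5.0) ** 2 <= 1).astype(float)
        rot = ndimage.rotate(ell, 37, axes=(0, 1), order=0, reshape=True)
        a0 = q.label_lacunae(ell.astype(bool), 1.0, (0.0, np.inf)).aspect_ratio.iloc[0]
        a1 = q.label_lacunae(rot > 0.5, 1.0, (0.0, np.inf)).aspect_ratio.iloc[0]
        assert a1 == pytest.approx(a0, abs=0.05)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError):
            q.label_lacunae(np.full((3, 3, 3), 2), 1.6)

    def test_filter_conservation(self):
        rng = np.random.default_rng(2)
        mask = ndimage.binary_dilation(rng.random((24, 24, 24)) > 0.98, iterations=2)
        table = q.label_lacunae(mask, 1.6)
        assert len(table) + table.attrs["n_rejected"] == table.attrs["n_components_total"]


# ------------------------------------------------------------------ KDE mode


class TestDistributionMode:
    def test_constant_sample(self):
        assert q.distribution_mode([7.0, 7.0, 7.0]) == 7.0

    def test_single_value(self):
        assert q.distribution_mode([42.0]) == 42.0

    def test_mixture_mode_near_dominant_peak(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate(
            [rng.normal(400, 50, 8000), rng.normal(1200, 100, 2000)]
        )
        assert q.distribution_mode(vals) == pytest.approx(400, abs=25)

    def test_invariant_under_duplication_with_fixed_bandwidth(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(100, 10, 500)
        m1 = q.distribution_mode(vals, bandwidth=0.3)
        m2 = q.distribution_mode(np.tile(vals, 2), bandwidth=0.3)
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q.distribution_mode([])


# --------------------------------------------------------------- calibration


def _fake_recon(grays: dict[str, float], shape=(4, 10, 10)):
    """A volume with labeled constant regions for calibration tests."""
    vol = np.zeros(shape)
    masks = {}
    names = list(grays)
    for i, name in enumerate(names):
        m = np.zeros(shape, dtype=bool)
        m[:, :, i * 3 : i * 3 + 3] = True
        vol[m] = grays[name]
        masks[name] = m
    return vol, masks


class TestCalibration:
    def test_identity_when_apparent_equals_known(self):
        from n2ibone.constants import MASS_ATTENUATION_24KEV

        grays = {
            "water": MASS_ATTENUATION_24KEV["water"] * 1.0 / 10,
            "alumina": MASS_ATTENUATION_24KEV["alumina"] * 3.95 / 10,
        }
        vol, masks = _fake_recon(grays)
        _, cal = q.calibrate_mineralization(
            vol, masks, {"water": 1.0, "alumina": 3.95}
        )
        assert cal.slope == pytest.approx(1.0, abs=1e-9)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_two_point_fit_reproduces_knowns_exactly(self):
        # apparent (0.8, 3.2) → known (1.0, 3.95): hand-solved line
        # slope = 2.95/2.4, intercept = 1 − slope·0.8
        from n2ibone.constants import MASS_ATTENUATION_24KEV

        grays = {
            "water": 0.8 * MASS_ATTENUATION_24KEV["water"] / 10,
            "alumina": 3.2 * MASS_ATTENUATION_24KEV["alumina"] / 10,
        }
        vol, masks = _fake_recon(grays)
        _, cal = q.calibrate_mineralization(vol, masks, {"water": 1.0, "alumina": 3.95})
        slope = 2.95 / 2.4
        assert cal.slope == pytest.approx(slope, rel=1e-9)
        assert cal.intercept == pytest.approx(1.0 - slope * 0.8, rel=1e-9)
        # both reference grays map back to their known densities
        for name, gray, known in [("water", grays["water"], 1.0),
                                  ("alumina", grays["alumina"], 3.95)]:
            apparent = 10 * gray / MASS_ATTENUATION_24KEV[name]
            assert cal.slope * apparent + cal.intercept == pytest.approx(known, rel=1e-9)

    def test_matrix_gray_maps_to_reference_density(self):
        from n2ibone.constants import MASS_ATTENUATION_24KEV
        import n2ibone as nb

        spec = nb.default_bone_spec()
        grays = {
            "water": MASS_ATTENUATION_24KEV["water"] / 10,
            "alumina": MASS_ATTENUATION_24KEV["alumina"] * 3.95 / 10,
        }
        vol, masks = _fake_recon(grays)
        _, cal = q.calibrate_mineralization(vol, masks, {"water": 1.0, "alumina": 3.95})
        density = cal.apply(np.array(spec.matrix_attenuation))
        assert float(density) == pytest.approx(1226.0, rel=1e-6)

    def test_degenerate_references_rejected(self):
        vol, masks = _fake_recon({"water": 0.05, "alumina": 0.05 * 1.376 / 0.573})
        with pytest.raises(ValueError, match="degenerate"):
            q.calibrate_mineralization(vol, masks, {"water": 1.0, "alumina": 3.95})

    def test_too_few_references_rejected(self):
        vol, masks = _fake_recon({"water": 0.06})
        with pytest.raises(ValueError):
            q.calibrate_mineralization(vol, masks, {"water": 1.0})


class TestPairedComparison:
    def test_identical_groups_flagged_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = q.compare_paired(a, a)
        assert res.degenerate
        assert np.isnan(res.t_statistic)

    def test_clear_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(100, 5, 8)
        d = rng.normal(0, 1, 8)
        b = a + d + 3 * d.std()
        res = q.compare_paired(a, b)
        assert res.p_value < 0.01
        assert not res.degenerate

    def test_t_statistic_antisymmetric(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 6)
        b = a + rng.normal(0.5, 0.2, 6)
        assert q.compare_paired(a, b).t_statistic == pytest.approx(
            -q.compare_paired(b, a).t_statistic
        )

    def test_short_groups_rejected(self):
        with pytest.raises(ValueError):
            q.compare_paired([1.0, 2.0], [1.0, 2.0])


def test_percent_change_worked_examples():
    assert round(percent_change(1202.0, 1226.0), 1) == -2.0
    assert round(percent_change(287.0, 393.0), 0) == -27.0
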