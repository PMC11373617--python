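"""SUV phantoms, conventional SUV metrics, discretization, GLCM,
first-order features and isotropic resampling."""

import itertools
import math

import numpy as np
import pytest

from psma_multiomics.cohort import generate_suv_phantom
from psma_multiomics.radiomics import (
    SuvVolume,
    VoiMask,
    discretize_fixed_bin_width,
    extract_features,
    first_order_features,
    glcm_features,
    resample_isotropic,
    suv_metrics,
)


SHAPE = (20, 20, 20)
SPACING = (2.0, 2.0, 2.0)
CENTER = (20.0, 20.0, 20.0)


def _phantom(**kw):
    args = dict(
        shape=SHAPE, spacing=SPACING, lesion_center_mm=CENTER,
        lesion_radius_mm=8.0, lesion_suv=5.0, background_suv=1.0,
        noise_sd=0.0, seed=9,
    )
    args.update(kw)
    return generate_suv_phantom(**args)


class TestPhantom:
    def test_noiseless_lesion_voxels_equal_lesion_suv(self):
        vol, mask = _phantom()
        assert (vol.data[mask.data] == 5.0).all()
        assert (vol.data[~mask.data] == 1.0).all()

    def test_mask_volume_close_to_analytic_sphere(self):
        vol, mask = _phantom(lesion_radius_mm=10.0)
        voxel_mm3 = np.prod(SPACING)
        analytic = 4.0 / 3.0 * math.pi * 10.0**3
        shell = 4.0 * math.pi * 10.0**2 * max(SPACING)  # one voxel shell
        assert abs(mask.n_voxels * voxel_mm3 - analytic) < shell

    def test_seed_reproducibility(self):
        v1, _ = _phantom(noise_sd=0.5, seed=3)
        v2, _ = _phantom(noise_sd=0.5, seed=3)
        assert np.array_equal(v1.data, v2.data)

    def test_lesion_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            _phantom(lesion_center_mm=(2.0, 20.0, 20.0), lesion_radius_mm=8.0)


class TestSuvMetrics:
    def test_constant_voi(self):
        vol, mask = _phantom()
        m = suv_metrics(vol, mask)
        # in-mask voxels are all 5; the peak sphere may straddle background
        assert m["SUVmin"] == m["SUVmax"] == m["SUVmean"] == 5.0
        assert m["SUVpeak"] <= 5.0

    def test_volume_arithmetic_at_2mm(self):
        # 8 voxels at 2 mm isotropic = 0.064 ml; SUVmean 5 -> TL-PSMA 0.32
        data = np.ones((6, 6, 6))
        data[2:4, 2:4, 2:4] = 5.0
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        m = suv_metrics(SuvVolume(data, (2.0, 2.0, 2.0)), VoiMask(mask))
        assert m["PSMA_TV"] == pytest.approx(0.064)
        assert m["TL_PSMA"] == pytest.approx(0.32)

    def test_peak_below_max_and_tlpsma_identity_on_random_voi(self, rng):
        data = rng.normal(3.0, 1.0, size=SHAPE)
        _, mask = _phantom()
        m = suv_metrics(SuvVolume(data, SPACING), mask)
        assert m["SUVpeak"] <= m["SUVmax"] + 1e-12
        assert m["TL_PSMA"] == pytest.approx(m["SUVmean"] * m["PSMA_TV"], rel=1e-13)

    def test_peak_matches_brute_force_sphere_average(self, rng):
        data = rng.normal(3.0, 1.0, size=(10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[3:7, 3:7, 3:7] = True
        vol = SuvVolume(data, (2.0, 2.0, 2.0))
        m = suv_metrics(vol, VoiMask(mask))
        radius = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1 / 3)
        best = -np.inf
        for c in itertools.product(range(10), repeat=3):
            if not mask[c]:
                continue
            vals = []
            for v in itertools.product(range(10), repeat=3):
                d2 = sum((2.0 * (a - b)) ** 2 for a, b in zip(c, v))
                if d2 <= radius**2:
                    vals.append(data[v])
            best = max(best, np.mean(vals))
        assert m["SUVpeak"] == pytest.approx(best, rel=1e-10)

    def test_empty_mask_errors(self):
        vol, _ = _phantom()
        with pytest.raises(ValueError):
            suv_metrics(vol, VoiMask(np.zeros(SHAPE, dtype=bool)))


class TestDiscretization:
    def test_constant_voi_single_bin(self):
        vol, mask = _phantom()
        assert set(discretize_fixed_bin_width(vol, mask)) == {1}

    def test_bin_edges(self):
        data = np.array([[[0.0, 0.30, 0.61]]])
        mask = VoiMask(np.ones((1, 1, 3), dtype=bool))
        labels = discretize_fixed_bin_width(SuvVolume(data, (1, 1, 1)), mask)
        assert labels.tolist() == [1, 2, 3]

    def test_shift_invariance(self, rng):
        data = rng.normal(3.0, 1.0, size=SHAPE)
        _, mask = _phantom()
        a = discretize_fixed_bin_width(SuvVolume(data, SPACING), mask)
        b = discretize_fixed_bin_width(SuvVolume(data + 10.0, SPACING), mask)
        assert np.array_equal(a, b)


def _brute_force_glcm(grid, n_levels):
    """Exhaustive pair enumeration over the 13 directions, symmetrized."""
    dirs = [
        (0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 1), (0, 1, -1), (1, 0, 1),
        (1, 0, -1), (1, 1, 0), (1, -1, 0), (1, 1, 1), (1, 1, -1),
        (1, -1, 1), (1, -1, -1),
    ]
    mats = []
    nz, ny, nx = grid.shape
    for d in dirs:
        mat = np.zeros((n_levels, n_levels))
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    if grid[z, y, x] == 0:
                        continue
                    z2, y2, x2 = z + d[0], y + d[1], x + d[2]
                    if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and grid[z2, y2, x2] > 0:
                        mat[grid[z, y, x] - 1, grid[z2, y2, x2] - 1] += 1
        mat = mat + mat.T
        if mat.sum() > 0:
            mats.append(mat / mat.sum())
    return mats


class TestGlcm:
    def test_constant_voi_joint_energy_one(self):
        vol, mask = _phantom()
        feats = glcm_features(vol, mask)
        assert feats["JointEnergy"] == pytest.approx(1.0)

    def test_joint_energy_in_unit_interval_and_drops_for_checkerboard(self, rng):
        vol, mask = _phantom()
        noisy = SuvVolume(vol.data + rng.normal(0, 1.0, SHAPE), SPACING)
        je_noisy = glcm_features(noisy, mask)["JointEnergy"]
        assert 0.0 < je_noisy <= 1.0
        assert je_noisy < glcm_features(vol, mask)["JointEnergy"]

    def test_matches_exhaustive_pair_enumeration_oracle(self, rng):
        data = rng.uniform(0.0, 1.5, size=(5, 5, 5))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:5, 0:4, 1:4] = True
        vol = SuvVolume(data, (2.0, 2.0, 2.0))
        feats = glcm_features(vol, VoiMask(mask), bin_width=0.3)
        grid = np.zeros((5, 5, 5), dtype=int)
        vals = data[mask]
        grid[mask] = np.floor((vals - vals.min()) / 0.3).astype(int) + 1
        mats = _brute_force_glcm(grid, grid.max())
        oracle_je = np.mean([(p**2).sum() for p in mats])
        oracle_contrast = np.mean(
            [
                sum(
                    p[i, j] * (i - j) ** 2
                    for i in range(p.shape[0])
                    for j in range(p.shape[1])
                )
                for p in mats
            ]
        )
        assert feats["JointEnergy"] == pytest.approx(oracle_je, abs=1e-12)
        assert feats["Contrast"] == pytest.approx(oracle_contrast, abs=1e-12)

    def test_single_voxel_voi_missing_with_warning(self):
        vol, _ = _phantom()
        mask = np.zeros(SHAPE, dtype=bool)
        mask[10, 10, 10] = True
        assert glcm_features(vol, VoiMask(mask)) == {}


class TestFirstOrder:
    def test_constant_voi_zero_variance_rules(self):
        vol, mask = _phantom()
        f = first_order_features(vol, mask)
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0
        assert f["Entropy"] == 0.0 and f["Uniformity"] == 1.0

    def test_maximum_equals_suvmax(self, rng):
        _, mask = _phantom()
        for _ in range(20):
            vol = SuvVolume(rng.normal(3, 1, SHAPE), SPACING)
            assert first_order_features(vol, mask)["Maximum"] == suv_metrics(vol, mask)["SUVmax"]

    def test_moments_on_standard_normal_sample(self, rng):
        n = 10_000
        data = rng.normal(0.0, 1.0, size=(n, 1, 1))
        mask = VoiMask(np.ones((n, 1, 1), dtype=bool))
        f = first_order_features(SuvVolume(data, (1, 1, 1)), mask)
        assert abs(f["Mean"]) < 3 / math.sqrt(n)
        assert abs(f["Variance"] - 1.0) < 3 * math.sqrt(2.0 / n)


class TestResampling:
    def test_constant_volume_stays_constant(self):
        vol = SuvVolume(np.full((8, 8, 8), 4.0), (1.0, 1.0, 1.0))
        mask = VoiMask(np.ones((8, 8, 8), dtype=bool))
        out_vol, out_mask = resample_isotropic(vol, mask, 2.0)
        assert out_vol.spacing == (2.0, 2.0, 2.0)
        assert np.allclose(out_vol.data, 4.0, atol=1e-6)
        assert out_mask.data.any()

    def test_linear_ramp_preserved(self):
        z = np.arange(16, dtype=float)
        data = np.broadcast_to(z[:, None, None], (16, 16, 16)).copy()
        vol = SuvVolume(data, (1.0, 1.0, 1.0))
        mask = VoiMask(np.ones((16, 16, 16), dtype=bool))
        out_vol, _ = resample_isotropic(vol, mask, 2.0)
        interior = out_vol.data[1:-1]
        expected = (2.0 * np.arange(out_vol.data.shape[0]))[1:-1]
        assert np.allclose(interior, expected[:, None, None], atol=1e-6)

    def test_empty_mask_after_resampling_errors(self):
        vol = SuvVolume(np.zeros((12, 12, 12)), (1.0, 1.0, 1.0))
        m = np.zeros((12, 12, 12), dtype=bool)
        vol2 = SuvVolume(np.zeros((3, 3, 3)), (0.5, 0.5, 0.5))
        m2 = np.zeros((3, 3, 3), dtype=bool)
        m2[2, 2, 2] = True  # off-grid after 0.5 mm -> 2 mm downsampling
        with pytest.raises(ValueError):
            resample_isotropic(vol2, VoiMask(m2), 2.0)
        with pytest.raises(ValueError):
            resample_isotropic(vol, VoiMask(m), 2.0)


def test_extract_features_finite_and_prefixed(default_cohort):
    pid = default_cohort.patients[0]
    feats = extract_features(
        default_cohort.suv_volumes[pid], default_cohort.voi_masks[pid], resample=False
    )
    assert all(k.startswith("rad::") for k in feats)
    assert all(np.isfinite(v) for v in feats.values())
    assert feats["rad::firstorder::Maximum"] == feats["rad::suv::SUVmax"]
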