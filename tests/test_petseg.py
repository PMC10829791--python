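"""BARCIST segmentation: SUV normalisation, masking rules, metrics, I/O."""

import itertools

import numpy as np
import pytest

from batkinetics.petseg import (
    PetCtVolume,
    bat_mask,
    bat_metrics,
    decay_correct,
    load_volume_pair,
    roi_summary,
    save_mask,
    suv_lbm,
)
from batkinetics.synthetic import PhantomConfig, generate_phantom


def make_volume(hu, activity, dose=185e6, bm=80.0, lbm=40.0, voxel=(10.0, 10.0, 10.0)):
    return PetCtVolume(
        hu=hu, activity=activity, voxel_size=voxel,
        injected_dose=dose, body_mass=bm, lean_body_mass=lbm,
    )


class TestSuvLbm:
    def test_definitional_unit_case(self):
        # voxel concentration equal to dose per gram LBM -> SUV 1.0
        dose, lbm = 185e6, 50.0
        assert suv_lbm(dose / (lbm * 1000.0), dose, lbm) == pytest.approx(1.0)

    def test_linear_in_lbm(self):
        assert suv_lbm(100.0, 1e6, 80.0) == pytest.approx(2 * suv_lbm(100.0, 1e6, 40.0))

    def test_grid_equals_scalar_loop(self):
        rng = np.random.default_rng(1)
        act = rng.uniform(0, 5000, size=(4, 5, 6))
        grid = suv_lbm(act, 185e6, 47.0)
        for idx in itertools.product(range(4), range(5), range(6)):
            assert grid[idx] == pytest.approx(
                act[idx] * 47.0 * 1000.0 / 185e6, rel=1e-12
            )


class TestMask:
    def test_soft_tissue_hu_gives_empty_mask(self):
        vol = make_volume(np.zeros((3, 3, 3)), np.full((3, 3, 3), 1e5))
        assert not bat_mask(vol).any()

    def test_center_voxel_phantom(self):
        hu = np.full((3, 3, 3), -90.0)
        dose, lbm, bm = 185e6, 40.0, 80.0
        threshold = 1.2 / (lbm / bm)  # 2.4 g/mL
        act = np.full((3, 3, 3), 0.5 * threshold * dose / (lbm * 1000.0))
        act[1, 1, 1] = 2.0 * threshold * dose / (lbm * 1000.0)
        vol = make_volume(hu, act, dose, bm, lbm)
        mask = bat_mask(vol)
        expected = np.zeros((3, 3, 3), bool)
        expected[1, 1, 1] = True
        assert np.array_equal(mask, expected)

    def test_suv_threshold_is_strict_and_hu_endpoints_inclusive(self):
        dose, lbm, bm = 1e6, 40.0, 80.0  # LBM/BM = 0.5 -> threshold 2.4
        act_at = 2.4 * dose / (lbm * 1000.0)
        hu = np.array([[[-190.0, -10.0, -9.99], [-190.01, -90.0, -90.0], [0.0, 0.0, 0.0]]])
        act = np.full(hu.shape, act_at)
        act[0, 1, 1] = act_at * 1.001
        vol = make_volume(hu, act, dose, bm, lbm)
        mask = bat_mask(vol)
        # exactly-at-threshold SUV excluded everywhere; only the voxel
        # strictly above threshold with in-range HU survives
        expected = np.zeros(hu.shape, bool)
        expected[0, 1, 1] = True
        assert np.array_equal(mask, expected)

    def test_mask_subset_of_fat_window_and_antimonotone_in_threshold(self):
        vol, _ = generate_phantom(PhantomConfig(seed=9))
        m1 = bat_mask(vol, suv_base=1.2)
        m2 = bat_mask(vol, suv_base=2.0)
        fat = (vol.hu >= -190) & (vol.hu <= -10)
        assert np.all(~m1 | fat)
        assert np.all(~m2 | m1)

    def test_axis_permutation_equivariance(self):
        vol, _ = generate_phantom(PhantomConfig(seed=4))
        mask = bat_mask(vol)
        perm = (2, 0, 1)
        vol_p = make_volume(
            np.transpose(vol.hu, perm), np.transpose(vol.activity, perm),
            vol.injected_dose, vol.body_mass, vol.lean_body_mass,
        )
        assert np.array_equal(bat_mask(vol_p), np.transpose(mask, perm))

    def test_z_range_slab_restriction(self):
        vol, truth = generate_phantom(PhantomConfig(seed=5))
        nz = vol.hu.shape[2]
        half = bat_mask(vol, z_range=(0, nz // 2))
        assert np.array_equal(half, bat_mask(vol)[:, :, :] & np.concatenate(
            [np.ones((1, 1, nz // 2), bool).repeat(vol.hu.shape[0], 0).repeat(vol.hu.shape[1], 1),
             np.zeros((vol.hu.shape[0], vol.hu.shape[1], nz - nz // 2), bool)], axis=2))

    def test_min_cluster_filter_removes_single_voxels(self):
        hu = np.full((6, 6, 6), -90.0)
        dose, lbm, bm = 1e6, 40.0, 80.0
        lo = 1.0 * dose / (lbm * 1000.0)
        hi = 3.0 * dose / (lbm * 1000.0)
        act = np.full(hu.shape, lo)
        act[0, 0, 0] = hi  # isolated voxel
        act[3:5, 3, 3] = hi  # 2-voxel cluster
        vol = make_volume(hu, act, dose, bm, lbm)
        assert bat_mask(vol).sum() == 3
        filtered = bat_mask(vol, min_cluster=2)
        assert filtered.sum() == 2 and not filtered[0, 0, 0]

    def test_lbm_vs_body_mass_invariant(self):
        with pytest.raises(ValueError):
            make_volume(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), lbm=85.0, bm=80.0)


class TestMetrics:
    def test_forced_uniform_case(self):
        hu = np.full((2, 2, 2), -90.0)
        dose, lbm = 1e6, 40.0
        act = np.full((2, 2, 2), 2.0 * dose / (lbm * 1000.0))  # SUV 2 everywhere
        vol = make_volume(hu, act, dose, 80.0, lbm)
        m = bat_metrics(np.ones((2, 2, 2), bool), vol)
        assert m.volume == pytest.approx(8.0)  # 8 voxels x 1 mL
        assert m.suv_mean == pytest.approx(2.0)
        assert m.activity == pytest.approx(16.0)
        assert m.suv_mean <= m.suv_max

    def test_empty_mask_reports_undefined_not_zero(self):
        vol = make_volume(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))
        m = bat_metrics(np.zeros((2, 2, 2), bool), vol)
        assert m.volume == 0.0 and m.voxel_count == 0
        assert m.suv_mean is None and m.suv_max is None
        assert m.activity is None and m.radiodensity_mean is None

    def test_random_phantom_matches_bruteforce_loops(self):
        vol, _ = generate_phantom(PhantomConfig(seed=12))
        mask = bat_mask(vol)
        m = bat_metrics(mask, vol)
        tot_suv, mx, tot_hu, n = 0.0, -np.inf, 0.0, 0
        for idx in zip(*np.nonzero(mask)):
            s = vol.activity[idx] * vol.lean_body_mass * 1000.0 / vol.injected_dose
            tot_suv += s
            mx = max(mx, s)
            tot_hu += vol.hu[idx]
            n += 1
        assert n == m.voxel_count
        assert m.suv_mean == pytest.approx(tot_suv / n, abs=1e-10)
        assert m.suv_max == pytest.approx(mx, abs=1e-10)
        assert m.radiodensity_mean == pytest.approx(tot_hu / n, abs=1e-10)
        assert m.volume == pytest.approx(n * vol.voxel_volume_ml, abs=1e-10)
        assert m.activity == pytest.approx(m.volume * m.suv_mean, rel=1e-12)

    def test_roi_summary_consistent_with_bat_metrics(self):
        vol, _ = generate_phantom(PhantomConfig(seed=13))
        mask = bat_mask(vol)
        m = bat_metrics(mask, vol)
        roi = roi_summary(vol, mask)
        assert roi["suv_mean"] == pytest.approx(m.suv_mean)
        assert roi["radiodensity_mean"] == pytest.approx(m.radiodensity_mean)
        with pytest.raises(ValueError, match="non-empty"):
            roi_summary(vol, np.zeros_like(mask))


class TestHelpers:
    def test_decay_correction_halves_at_half_life(self):
        assert decay_correct(1000.0, 109.77) == pytest.approx(500.0)
        assert decay_correct(1000.0, 0.0) == 1000.0

    def test_volume_io_roundtrip(self, tmp_path):
        vol, truth = generate_phantom(PhantomConfig(seed=2, shape=(8, 8, 4)))
        # NIfTI route for the mask
        save_mask(truth, tmp_path / "mask.nii.gz", vol.voxel_size)
        import nibabel as nib

        back = np.asarray(nib.load(str(tmp_path / "mask.nii.gz")).dataobj)
        assert np.array_equal(back.astype(bool), truth)
        # JSON + raw fallback route for the grids
        import json

        for name, arr in [("hu", vol.hu), ("act", vol.activity)]:
            (tmp_path / f"{name}.json").write_text(
                json.dumps({"shape": list(arr.shape), "voxel_size": list(vol.voxel_size), "dtype": "<f8"})
            )
            arr.astype("<f8").tofile(tmp_path / f"{name}.raw")
        vol2 = load_volume_pair(
            tmp_path / "hu.json", tmp_path / "act.json",
            vol.injected_dose, vol.body_mass, vol.lean_body_mass,
        )
        assert np.array_equal(vol2.hu, vol.hu)
        assert np.array_equal(bat_mask(vol2), bat_mask(vol))
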