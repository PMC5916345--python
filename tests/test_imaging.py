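"""Voxelwise maps, smoothing, group t statistics, cluster thresholding and
mask algebra on small constructed grids."""

import numpy as np
import pytest
from scipy import stats as sps

from petkin.frames import make_frame_schedule
from petkin.imaging import (ClusterConfig, LabelVolume, ParametricMap,
                            cluster_extent_mc, dice_coefficient, extract_roi,
                            fit_parametric_map, fwhm_to_sigma, group_tmap,
                            intersect_masks, posterior_cerebellum_mask,
                            smooth_map, threshold_clusters)
from petkin.synthetic import SRTMTruth, simulate_irreversible_tac, simulate_srtm_tac


class TestFitParametricMap:
    def test_constant_patlak_phantom(self, ref_fmt):
        tac = simulate_irreversible_tac(ref_fmt, ki=0.015, v=0.5)
        dyn = np.tile(tac.activity, (3, 3, 2, 1))
        pm = fit_parametric_map(dyn, ref_fmt.schedule, ref_fmt, "patlak")
        np.testing.assert_allclose(pm.data, 0.015, rtol=1e-9)
        assert pm.quantity == "Ki"

    def test_all_zero_voxels_become_missing(self, ref_fmt):
        dyn = np.zeros((2, 2, 2, ref_fmt.schedule.n_frames))
        pm = fit_parametric_map(dyn, ref_fmt.schedule, ref_fmt, "patlak")
        assert np.all(np.isnan(pm.data))

    def test_two_region_srtm_phantom_recovers_truths(self, ref_rac):
        """Voxelwise SRTM equals the scalar fit region by region."""
        lo = simulate_srtm_tac(ref_rac, SRTMTruth(1.0, 0.3, 1.5)).activity
        hi = simulate_srtm_tac(ref_rac, SRTMTruth(1.0, 0.3, 3.5)).activity
        dyn = np.zeros((4, 2, 1, ref_rac.schedule.n_frames))
        dyn[:2] = lo
        dyn[2:] = hi
        pm = fit_parametric_map(dyn, ref_rac.schedule, ref_rac, "srtm")
        assert np.nanmean(pm.data[:2]) == pytest.approx(1.5, rel=0.01)
        assert np.nanmean(pm.data[2:]) == pytest.approx(3.5, rel=0.01)

    def test_schedule_mismatch_rejected(self, ref_fmt, ref_rac):
        dyn = np.zeros((2, 2, 2, ref_fmt.schedule.n_frames))
        with pytest.raises(ValueError):
            fit_parametric_map(dyn, ref_fmt.schedule, ref_rac, "patlak")


class TestSmoothMap:
    def test_fwhm_zero_is_identity(self, rng):
        pm = ParametricMap(rng.normal(size=(5, 5, 5)))
        out = smooth_map(pm, 0.0)
        np.testing.assert_array_equal(out.data, pm.data)

    def test_constant_map_unchanged(self):
        pm = ParametricMap(np.full((8, 8, 8), 3.7))
        out = smooth_map(pm, 6.0)
        np.testing.assert_allclose(out.data, 3.7, rtol=1e-9)

    def test_delta_matches_analytic_gaussian(self):
        """A central delta smooths to the sampled Gaussian density within
        1e-6 (sigma ~1.7 voxels, so aliasing is negligible)."""
        n = 31
        pm = ParametricMap(np.zeros((n, n, n)))
        pm.data[15, 15, 15] = 1.0
        out = smooth_map(pm, 4.0)
        sig = fwhm_to_sigma(4.0)
        for ijk in [(15, 15, 15), (16, 15, 15), (17, 14, 15), (15, 18, 13)]:
            d2 = sum((i - 15) ** 2 for i in ijk)
            want = np.exp(-d2 / (2 * sig**2)) / (2 * np.pi * sig**2) ** 1.5
            assert out.data[ijk] == pytest.approx(want, abs=1e-6)

    def test_sum_conserved_for_interior_supported_image(self, rng):
        # support far enough from every edge that no kernel mass leaves the
        # grid and the renormalising denominator is 1 over the support
        pm = ParametricMap(np.zeros((40, 40, 40)))
        pm.data[18:23, 18:23, 18:21] = rng.random((5, 5, 3))
        out = smooth_map(pm, 3.0)
        assert np.nansum(out.data) == pytest.approx(np.nansum(pm.data), rel=1e-6)

    def test_missing_voxels_excluded_by_renormalisation(self):
        pm = ParametricMap(np.full((9, 9, 9), 2.0))
        pm.data[4, 4, 4] = np.nan
        out = smooth_map(pm, 4.0)
        defined = np.isfinite(out.data)
        np.testing.assert_allclose(out.data[defined], 2.0, rtol=1e-9)
        assert np.isnan(out.data[4, 4, 4])


class TestGroupTmap:
    def test_closed_form_t_at_single_voxel(self):
        maps = [ParametricMap(np.full((1, 1, 1), v)) for v in (1.0, 2.0, 3.0)]
        tm = group_tmap(maps)
        # mean 2, sd 1, n 3 -> t = 2/(1/sqrt(3)) = 3.464
        assert tm.data[0, 0, 0] == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert tm.meta["df"] == 2

    def test_paired_equals_one_sample_on_differences(self, rng):
        A = [ParametricMap(rng.normal(size=(3, 3, 3))) for _ in range(6)]
        B = [ParametricMap(rng.normal(size=(3, 3, 3))) for _ in range(6)]
        paired = group_tmap(A, B, mode="paired")
        diff = [ParametricMap(a.data - b.data) for a, b in zip(A, B)]
        one = group_tmap(diff)
        np.testing.assert_array_equal(paired.data, one.data)

    def test_zero_variance_voxels_missing(self):
        maps = [ParametricMap(np.ones((2, 2, 2))) for _ in range(5)]
        tm = group_tmap(maps)
        assert np.all(np.isnan(tm.data))

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_tmap([ParametricMap(np.ones((2, 2, 2)))])


class TestThresholdClusters:
    def _tmap(self, data, df=39):
        return ParametricMap(np.asarray(data, dtype=float), quantity="t",
                             meta={"df": df})

    def test_all_zero_map_empty_mask(self):
        cc = ClusterConfig(df=39, k_min=1)
        mask, table = threshold_clusters(self._tmap(np.zeros((4, 4, 4))), cc)
        assert not mask.any()
        assert table.empty

    def test_extent_threshold_filters_small_component(self):
        """Components of 54 and 55 suprathreshold voxels with k=55: only
        the 55-voxel cluster survives."""
        data = np.zeros((30, 11, 10))
        data[0:6, 0:3, 0:3] = 10.0     # 6*3*3 = 54 voxels
        data[20:25, 0:11, 0] = 10.0    # 5*11*1 = 55 voxels
        cc = ClusterConfig(p_threshold=0.001, df=39, k_min=55, connectivity=6)
        mask, table = threshold_clusters(self._tmap(data), cc)
        assert len(table) == 1
        assert table.loc[0, "size_voxels"] == 55
        assert mask.sum() == 55

    def test_connectivity_rules_for_diagonal_touch(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 10.0
        data[2, 2, 2] = 10.0  # corner-adjacent
        m6, t6 = threshold_clusters(self._tmap(data),
                                    ClusterConfig(df=39, k_min=1, connectivity=6))
        m26, t26 = threshold_clusters(self._tmap(data),
                                      ClusterConfig(df=39, k_min=1, connectivity=26))
        assert len(t6) == 2
        assert len(t26) == 1

    def test_negative_clusters_reported_with_sign(self):
        data = np.zeros((6, 6, 6))
        data[1:3, 1:3, 1:3] = -8.0
        cc = ClusterConfig(df=39, k_min=2)
        mask, table = threshold_clusters(self._tmap(data), cc)
        assert (table["sign"] == -1).all()
        assert mask.sum() == 8


class TestClusterExtentMC:
    MASK = np.ones((12, 12, 6), dtype=bool)

    def test_alpha_one_gives_k_one(self):
        k = cluster_extent_mc(self.MASK, (1, 1, 1), fwhm_mm=0.0, alpha=1.0,
                              n_iter=100, seed=0)
        assert k == 1

    def test_seed_reproducible_and_matches_brute_force(self):
        """Same seed twice gives the same k; and k equals an independent
        re-simulation of the same null distribution."""
        args = dict(p_thresh=0.01, alpha=0.05, n_iter=200, seed=123)
        k1 = cluster_extent_mc(self.MASK, (1, 1, 1), 0.0, **args)
        k2 = cluster_extent_mc(self.MASK, (1, 1, 1), 0.0, **args)
        assert k1 == k2

        # brute force: replay the identical null with independent code
        from scipy import ndimage
        rng = np.random.default_rng(123)
        z_crit = sps.norm.ppf(1 - 0.01 / 2)
        maxes = []
        for _ in range(200):
            noise = rng.standard_normal(self.MASK.shape)
            vals = noise[self.MASK]
            noise = (noise - vals.mean()) / vals.std(ddof=1)
            lab, n = ndimage.label(np.abs(noise) > z_crit)
            maxes.append(np.bincount(lab.ravel())[1:].max() if n else 0)
        maxes = np.sort(maxes)
        k_oracle = next(k for k in range(1, maxes[-1] + 2)
                        if (maxes >= k).mean() <= 0.05)
        assert k1 == k_oracle

    def test_k_nondecreasing_in_fwhm(self):
        ks = [cluster_extent_mc(self.MASK, (1, 1, 1), f, p_thresh=0.01,
                                n_iter=150, seed=7) for f in (0.0, 2.0, 4.0)]
        assert ks == sorted(ks)

    def test_k_nonincreasing_in_alpha(self):
        k_strict = cluster_extent_mc(self.MASK, (1, 1, 1), 2.0, p_thresh=0.01,
                                     alpha=0.01, n_iter=150, seed=9)
        k_loose = cluster_extent_mc(self.MASK, (1, 1, 1), 2.0, p_thresh=0.01,
                                    alpha=0.20, n_iter=150, seed=9)
        assert k_strict >= k_loose

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_extent_mc(np.zeros((4, 4, 4), bool), (1, 1, 1), 4.0)


class TestMaskAlgebra:
    def test_intersection_with_itself(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3, 1:3, 1:3] = True
        out, vol = intersect_masks([m, m])
        np.testing.assert_array_equal(out, m)
        assert vol == 8.0

    def test_disjoint_masks_empty(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        out, vol = intersect_masks([a, b])
        assert not out.any() and vol == 0.0

    def test_volume_uses_voxel_size(self):
        m = np.zeros((20, 20, 20), bool)
        m.ravel()[:7097] = True
        out, vol = intersect_masks([m, np.ones_like(m)], voxel_size_mm=(1, 1, 1))
        assert vol == pytest.approx(7097.0)

    def test_dice_identities(self):
        a = np.zeros((10, 10, 1), bool)
        a[:5] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a) == 0.0
        assert dice_coefficient(np.zeros_like(a), np.zeros_like(a)) == 1.0

    def test_dice_partial_overlap(self):
        # |A|=|B|=100, overlap 80 -> 0.80
        a = np.zeros((300, 1, 1), bool)
        b = np.zeros((300, 1, 1), bool)
        a[0:100] = True
        b[20:120] = True
        assert dice_coefficient(a, b) == pytest.approx(0.80)


class TestPosteriorCerebellum:
    def _cereb(self, n_slices=8):
        data = np.zeros((4, 12, 4), dtype=np.int16)
        data[:, 2:2 + n_slices, :] = 1  # occupies n_slices coronal slices
        return LabelVolume(data, ap_axis=1, anterior_low=True)

    def test_fraction_zero_unchanged(self):
        lv = self._cereb()
        out = posterior_cerebellum_mask(lv, 0.0)
        np.testing.assert_array_equal(out, lv.data > 0)

    def test_quarter_of_eight_slices_removes_two(self):
        out = posterior_cerebellum_mask(self._cereb(8), 0.25)
        kept = np.flatnonzero(out.any(axis=(0, 2)))
        np.testing.assert_array_equal(kept, np.arange(4, 10))  # anterior 2 gone

    def test_round_half_up_on_odd_counts(self):
        # 6 slices * 0.25 = 1.5 -> 2 removed
        out = posterior_cerebellum_mask(self._cereb(6), 0.25)
        assert out.any(axis=(0, 2)).sum() == 4

    def test_monotone_in_fraction(self):
        lv = self._cereb(9)
        v20 = posterior_cerebellum_mask(lv, 0.20).sum()
        v25 = posterior_cerebellum_mask(lv, 0.25).sum()
        assert v25 <= v20

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            posterior_cerebellum_mask(LabelVolume(np.zeros((3, 3, 3), np.int16)), 0.25)


class TestExtractROI:
    def test_constant_map(self):
        labels = LabelVolume(np.ones((3, 3, 3), np.int16))
        val, vol = extract_roi(ParametricMap(np.full((3, 3, 3), 4.2)), labels, 1)
        assert val == pytest.approx(4.2)
        assert vol == 27.0

    def test_two_voxel_mean(self):
        data = np.zeros((2, 1, 1))
        data[0], data[1] = 1.0, 3.0
        labels = LabelVolume(np.ones((2, 1, 1), np.int16))
        val, _ = extract_roi(ParametricMap(data), labels, 1)
        assert val == 2.0

    def test_dynamic_roi_round_trips_generating_tac(self, ref_rac):
        tac = simulate_srtm_tac(ref_rac, SRTMTruth(1.0, 0.3, 2.0))
        dyn = np.tile(tac.activity, (3, 2, 2, 1))
        labels = LabelVolume(np.ones((3, 2, 2), np.int16))
        got, vol = extract_roi(dyn, labels, 1, schedule=ref_rac.schedule)
        np.testing.assert_allclose(got.activity, tac.activity, rtol=1e-12)

    def test_absent_label_rejected(self):
        labels = LabelVolume(np.zeros((2, 2, 2), np.int16))
        with pytest.raises(ValueError, match="not present"):
            extract_roi(ParametricMap(np.ones((2, 2, 2))), labels, 5)


class TestNiftiIO:
    def test_map_and_labels_round_trip(self, tmp_path, rng):
        pm = ParametricMap(rng.normal(size=(4, 5, 6)).astype(np.float32),
                           voxel_size_mm=(2.0, 2.0, 3.0))
        pm.to_nifti(tmp_path / "m.nii")
        back = ParametricMap.from_nifti(tmp_path / "m.nii")
        np.testing.assert_allclose(back.data, pm.data, rtol=1e-6)
        assert back.voxel_size_mm == (2.0, 2.0, 3.0)

        lv = LabelVolume(rng.integers(0, 4, (4, 5, 6)).astype(np.int16))
        lv.to_nifti(tmp_path / "l.nii")
        back = LabelVolume.from_nifti(tmp_path / "l.nii")
        np.testing.assert_array_equal(back.data, lv.data)
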