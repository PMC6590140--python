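"""Cohort statistics tests: normative maps, Z-maps, voxelwise Spearman,
histograms, ROI exclusion logic and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from qmyelin.popstats import (CohortStats, cohort_mean_sd, group_difference,
                              mann_whitney_group_test, roi_summary,
                              spearman_critical_value, tissue_histograms,
                              voxelwise_spearman, zmap)


class TestCohortMeanSd:
    def test_identical_subjects_zero_sd(self):
        maps = [np.full((4, 4, 4), 3.0)] * 5
        st_ = cohort_mean_sd(maps)
        np.testing.assert_array_equal(st_.sd, 0.0)
        np.testing.assert_array_equal(st_.mean, 3.0)

    def test_two_subject_closed_form(self):
        a, b = 1.0, 4.0
        st_ = cohort_mean_sd([np.full((2, 2), a), np.full((2, 2), b)])
        assert st_.mean.flat[0] == pytest.approx((a + b) / 2)
        assert st_.sd.flat[0] == pytest.approx(abs(a - b) / np.sqrt(2))

    def test_matches_streaming_moments_oracle(self, rng):
        maps = [rng.normal(size=(6, 6, 6)) for _ in range(38)]
        st_ = cohort_mean_sd(maps)
        mean_o, sd_o = oracles.streaming_mean_sd(maps)
        np.testing.assert_allclose(st_.mean, mean_o, atol=1e-12)
        np.testing.assert_allclose(st_.sd, sd_o, atol=1e-12)

    def test_invalid_voxels_propagate(self, rng):
        maps = [rng.normal(size=(3, 3)) for _ in range(4)]
        maps[2][1, 1] = np.nan
        st_ = cohort_mean_sd(maps)
        assert np.isnan(st_.mean[1, 1]) and np.isnan(st_.sd[1, 1])

    def test_grid_mismatch(self, rng):
        with pytest.raises(ValueError):
            cohort_mean_sd([rng.normal(size=(3, 3))] * 3,
                           mask=np.ones((4, 4), bool))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            cohort_mean_sd([np.ones((2, 2))])


class TestZmap:
    stats = CohortStats(mean=np.full((3, 3), 10.0), sd=np.full((3, 3), 2.0),
                        n_subjects=10)

    def test_mean_gives_zero(self):
        z = zmap(np.full((3, 3), 10.0), self.stats)
        np.testing.assert_array_equal(z.z, 0.0)

    def test_two_sd_gives_two(self):
        z = zmap(np.full((3, 3), 14.0), self.stats)
        np.testing.assert_array_equal(z.z, 2.0)

    def test_zero_sd_masked(self):
        st_ = CohortStats(mean=np.zeros((2, 2)), sd=np.zeros((2, 2)),
                          n_subjects=5)
        z = zmap(np.ones((2, 2)), st_)
        assert np.all(np.isnan(z.z))

    def test_affine_equivariance(self, rng):
        """Rescaling a modality's units leaves Z unchanged."""
        maps = [rng.normal(10, 2, size=(4, 4)) for _ in range(10)]
        subj = rng.normal(10, 2, size=(4, 4))
        z1 = zmap(subj, cohort_mean_sd(maps)).z
        z2 = zmap(1000 * subj + 5, cohort_mean_sd(
            [1000 * m + 5 for m in maps])).z
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_held_out_control_coverage(self, rng):
        """~95% of held-out control Z-values fall inside +/-2."""
        n_vox = 10_000
        controls = rng.normal(0.12, 0.01, size=(38, n_vox))
        held_out = rng.normal(0.12, 0.01, size=n_vox)
        z = zmap(held_out, cohort_mean_sd(list(controls)))
        frac = np.mean(np.abs(z.z) <= 2)
        assert frac == pytest.approx(0.95, abs=0.02)


class TestVoxelwiseSpearman:
    def test_monotone_transform_gives_one(self, rng):
        a = [rng.normal(size=(4, 4)) for _ in range(8)]
        b = [np.exp(m) for m in a]
        rho = voxelwise_spearman(a, b).rho
        np.testing.assert_allclose(rho, 1.0, atol=1e-12)

    def test_negation_gives_minus_one(self, rng):
        a = [rng.normal(size=(4, 4)) for _ in range(8)]
        rho = voxelwise_spearman(a, [-m for m in a]).rho
        np.testing.assert_allclose(rho, -1.0, atol=1e-12)

    def test_null_calibration(self, rng):
        n, n_vox = 38, 10_000
        a = rng.normal(size=(n, n_vox, 1))
        b = rng.normal(size=(n, n_vox, 1))
        rho = voxelwise_spearman(list(a), list(b)).rho
        crit = spearman_critical_value(n, 0.05)
        frac = np.mean(np.abs(rho) > crit)
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_constant_voxel_masked(self, rng):
        a = [np.ones((2, 2)) for _ in range(6)]
        b = [rng.normal(size=(2, 2)) for _ in range(6)]
        rho = voxelwise_spearman(a, b).rho
        assert np.all(np.isnan(rho))

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            voxelwise_spearman([np.ones((2, 2))] * 3, [np.ones((2, 2))] * 3)

    def test_matches_scipy_per_voxel(self, rng):
        import scipy.stats
        a = rng.normal(size=(12, 5))
        b = rng.normal(size=(12, 5))
        rho = voxelwise_spearman(list(a[:, :, None]),
                                 list(b[:, :, None])).rho[:, 0]
        for v in range(5):
            want = scipy.stats.spearmanr(a[:, v], b[:, v]).statistic
            assert rho[v] == pytest.approx(want, abs=1e-12)


class TestSpearmanCritical:
    def test_published_threshold_n38(self):
        assert spearman_critical_value(38, 0.05) == pytest.approx(0.321,
                                                                  abs=0.002)

    def test_alpha_to_one_limit(self):
        assert spearman_critical_value(38, 0.999) < 0.05

    def test_exact_small_n_values(self):
        # standard exact-table values for two-tailed alpha = 0.05
        assert spearman_critical_value(5, 0.05) == pytest.approx(1.0)
        assert spearman_critical_value(6, 0.05) == pytest.approx(0.886,
                                                                 abs=1e-3)

    def test_exact_enumeration_consistency(self):
        """Independent brute force over all 5! permutations at n=5."""
        import itertools
        import scipy.stats
        n, alpha = 5, 0.05
        base = np.arange(1, n + 1)
        rhos = np.array([scipy.stats.pearsonr(
            base, np.array(p)).statistic
            for p in itertools.permutations(base)])
        crit = spearman_critical_value(n, alpha)
        assert np.mean(np.abs(rhos) >= crit - 1e-9) <= alpha
        smaller = np.unique(np.abs(np.round(rhos, 12)))
        smaller = smaller[smaller < crit - 1e-9]
        if len(smaller):
            assert np.mean(np.abs(rhos) >= smaller[-1] - 1e-9) > alpha

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            spearman_critical_value(3, 0.05)
        with pytest.raises(ValueError):
            spearman_critical_value(38, 0.0)


class TestTissueHistograms:
    def _corr(self, arr):
        from qmyelin.popstats import CorrelationMap
        return CorrelationMap(rho=np.asarray(arr, dtype=float))

    def test_single_voxel_spike(self):
        rho = np.full((3, 3), np.nan)
        rho[1, 1] = 0.5
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        df = tissue_histograms(self._corr(rho), {"wm": mask}, bins=10)
        areas = df.density * (df.bin_right - df.bin_left)
        assert areas.sum() == pytest.approx(1.0)
        assert (df.density > 0).sum() == 1

    def test_unit_area_per_class(self, rng):
        rho = rng.uniform(-1, 1, size=(8, 8))
        masks = {"wm": np.zeros((8, 8), bool), "gm": np.zeros((8, 8), bool)}
        masks["wm"][:4] = True
        masks["gm"][4:] = True
        df = tissue_histograms(self._corr(rho), masks, bins=20)
        for name, sub in df.groupby("tissue"):
            area = (sub.density * (sub.bin_right - sub.bin_left)).sum()
            assert area == pytest.approx(1.0)

    def test_pooled_mixture_identity(self, rng):
        rho = rng.uniform(-1, 1, size=(10, 10))
        m1 = np.zeros((10, 10), bool)
        m1[:3] = True
        m2 = np.zeros((10, 10), bool)
        m2[3:] = True
        df = tissue_histograms(self._corr(rho), {"a": m1, "b": m2}, bins=15)
        pooled = tissue_histograms(self._corr(rho),
                                   {"all": m1 | m2}, bins=15)
        na, nb = m1.sum(), m2.sum()
        mix = (df[df.tissue == "a"].density.to_numpy() * na
               + df[df.tissue == "b"].density.to_numpy() * nb) / (na + nb)
        np.testing.assert_allclose(pooled.density.to_numpy(), mix,
                                   atol=1e-12)

    def test_overlapping_masks_rejected(self, rng):
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            tissue_histograms(self._corr(rng.uniform(-1, 1, (4, 4))),
                              {"a": m, "b": m})

    def test_empty_mask_warns(self, rng):
        with pytest.warns(UserWarning):
            tissue_histograms(self._corr(rng.uniform(-1, 1, (4, 4))),
                              {"a": np.zeros((4, 4), bool)})


class TestRoiSummary:
    def test_control_uses_full_roi(self):
        vol = np.arange(27.0).reshape(3, 3, 3)
        roi = np.ones((3, 3, 3), bool)
        empty = np.zeros((3, 3, 3), bool)
        df = roi_summary({"qt1": vol}, {"wm": roi}, empty, empty, "control",
                         "c1")
        row = df[df.region == "wm"].iloc[0]
        assert row["mean"] == pytest.approx(vol.mean())
        assert row["n_voxels"] == 27

    def test_lesion_exclusion_exactness(self):
        vol = np.zeros((2, 2, 2))
        roi = np.ones((2, 2, 2), bool)
        lesion = np.zeros((2, 2, 2), bool)
        lesion[0] = True       # half the ROI is lesion at value 5
        vol[lesion] = 5.0
        vol[~lesion] = 2.0
        empty = np.zeros((2, 2, 2), bool)
        df = roi_summary({"m": vol}, {"wm": roi}, lesion, empty, "patient")
        nawm = df[df.region == "wm"].iloc[0]
        assert nawm["mean"] == pytest.approx(2.0)
        les = df[df.region == "lesion"].iloc[0]
        assert les["mean"] == pytest.approx(5.0)

    def test_partition_identity(self, rng):
        vol = rng.normal(size=(4, 4, 4))
        m1 = np.zeros((4, 4, 4), bool)
        m1[:2] = True
        m2 = ~m1
        empty = np.zeros((4, 4, 4), bool)
        df = roi_summary({"m": vol}, {"a": m1, "b": m2}, empty, empty,
                         "control")
        means = df.set_index("region")["mean"]
        ns = df.set_index("region")["n_voxels"]
        pooled = (means["a"] * ns["a"] + means["b"] * ns["b"]) / (
            ns["a"] + ns["b"])
        assert pooled == pytest.approx(vol.mean())

    def test_emptied_roi_flagged(self):
        vol = np.ones((2, 2, 2))
        roi = np.zeros((2, 2, 2), bool)
        roi[0, 0, 0] = True
        lesion = roi.copy()
        empty = np.zeros((2, 2, 2), bool)
        df = roi_summary({"m": vol}, {"wm": roi}, lesion, empty, "patient")
        row = df[df.region == "wm"].iloc[0]
        assert row["empty"] and np.isnan(row["mean"])


def _roi_table(ctl_vals, pat_vals, regions=("r1",), modality="m"):
    rows = []
    for region in regions:
        for i, v in enumerate(ctl_vals):
            rows.append({"subject_id": f"c{i}", "group": "control",
                         "region": region, "modality": modality,
                         "mean": v, "n_voxels": 10, "empty": False})
        for i, v in enumerate(pat_vals):
            rows.append({"subject_id": f"p{i}", "group": "patient",
                         "region": region, "modality": modality,
                         "mean": v, "n_voxels": 10, "empty": False})
    return pd.DataFrame(rows)


class TestGroupDifference:
    def test_all_tied_gives_p_one(self):
        _, p = mann_whitney_group_test(np.ones(5), np.ones(5))
        assert p == 1.0

    def test_single_region_no_correction(self, rng):
        tbl = _roi_table(rng.normal(size=10), rng.normal(size=10))
        out = group_difference(tbl)
        assert len(out) == 1
        assert out.p_adjusted.iloc[0] == pytest.approx(out.p_raw.iloc[0])

    def test_power_with_large_shift(self, rng):
        regions = [f"r{i}" for i in range(8)]
        frames = []
        for region in regions:
            ctl = rng.normal(0, 1, 20)
            pat = rng.normal(3, 1, 20)  # 3 control SDs
            frames.append(_roi_table(ctl, pat, (region,)))
        out = group_difference(pd.concat(frames, ignore_index=True))
        assert len(out) == 8
        assert (out.p_adjusted < 0.05).all()

    def test_null_calibration_smoke(self, rng):
        """Quick type-I check; the full 1e4-replicate calibration lives in
        the acceptance suite."""
        hits = sum(mann_whitney_group_test(rng.normal(size=20),
                                           rng.normal(size=20))[1] < 0.05
                   for _ in range(500))
        assert hits / 500 == pytest.approx(0.05, abs=0.03)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=12))
def test_holm_is_bounded_by_bonferroni(p_raw):
    from qmyelin.lesion_roc import holm_correct
    adj = holm_correct(p_raw)
    m = len(p_raw)
    assert np.all(adj >= np.asarray(p_raw) - 1e-15)
    assert np.all(adj <= np.minimum(1.0, m * np.asarray(p_raw)) + 1e-12)
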