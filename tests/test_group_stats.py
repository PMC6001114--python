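"""Smoothing, voxelwise t statistics, FWE thresholds, ANOVA and Fisher ratio."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gmsuvr.group_stats as gs
from gmsuvr import SUVRTable, fisher_ratio, region_anova, region_coverage
from gmsuvr.volume import Volume

from conftest import two_region_atlas


def vol(data, voxel=1.5):
    return Volume(np.asarray(data, dtype=float), np.diag([voxel] * 3 + [1.0]))


def suvr_table(values: dict[str, list[float]]) -> SUVRTable:
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(len(next(iter(values.values()))))])
    return SUVRTable(values=df, mode="all_voxels")


class TestSmoothing:
    def test_sigma_from_fwhm(self):
        sigma = gs.fwhm_to_sigma(8.0, 1.5)
        assert sigma[0] == pytest.approx(2.2649, abs=1e-4)

    def test_constant_volume_unchanged(self):
        const = vol(np.full((12, 12, 12), 3.3))
        out = gs.smooth_volume(const, 8.0)
        np.testing.assert_allclose(out.data, 3.3, atol=1e-12)

    def test_interior_impulse_mass_conserved(self):
        data = np.zeros((30, 30, 30))
        data[15, 15, 15] = 1.0
        out = gs.smooth_volume(vol(data), 8.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)
        assert out.data.max() < 1.0  # actually spread out

    def test_anisotropic_voxels_get_per_axis_sigma(self):
        affine = np.diag([1.0, 2.0, 4.0, 1.0])
        v = Volume(np.zeros((20, 20, 20)), affine)
        v.data[10, 10, 10] = 1.0
        out = gs.smooth_volume(v, 8.0)
        # spread (in voxels) must shrink as voxel size grows
        prof_x = (out.data[:, 10, 10] > 1e-6).sum()
        prof_z = (out.data[10, 10, :] > 1e-6).sum()
        assert prof_x > prof_z

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gs.smooth_volume(vol(np.zeros((5, 5, 5))), 0.0)


class TestVoxelwiseT:
    def test_single_voxel_hand_computed(self):
        a = [vol(np.full((1, 1, 1), x)) for x in (1.0, 2.0, 3.0)]
        b = [vol(np.full((1, 1, 1), x)) for x in (3.0, 4.0, 5.0)]
        mask = np.ones((1, 1, 1), dtype=bool)
        t = gs.voxelwise_t_map(a, b, mask, direction=gs.A_GT_B)
        assert t.data[0, 0, 0] == pytest.approx(-2.4495, abs=1e-4)

    def test_agrees_with_scipy_ttest(self):
        rng = np.random.default_rng(3)
        a = [vol(rng.normal(size=(4, 4, 4))) for _ in range(5)]
        b = [vol(rng.normal(0.3, size=(4, 4, 4))) for _ in range(7)]
        mask = np.ones((4, 4, 4), dtype=bool)
        t = gs.voxelwise_t_map(a, b, mask)
        sa = np.stack([v.data for v in a]).reshape(5, -1)
        sb = np.stack([v.data for v in b]).reshape(7, -1)
        expected = stats.ttest_ind(sa, sb, axis=0).statistic
        np.testing.assert_allclose(t.data.ravel(), expected, atol=1e-10)

    def test_direction_flip_is_antisymmetric(self):
        rng = np.random.default_rng(4)
        a = [vol(rng.normal(size=(3, 3, 3))) for _ in range(4)]
        b = [vol(rng.normal(size=(3, 3, 3))) for _ in range(4)]
        mask = np.ones((3, 3, 3), dtype=bool)
        t_ab = gs.voxelwise_t_map(a, b, mask, direction=gs.A_GT_B)
        t_ba = gs.voxelwise_t_map(a, b, mask, direction=gs.B_GT_A)
        np.testing.assert_allclose(t_ab.data, -t_ba.data, atol=1e-12)

    def test_duplicate_data_gives_zero_t(self):
        dup = [vol(np.arange(27.0).reshape(3, 3, 3)) for _ in range(3)]
        mask = np.ones((3, 3, 3), dtype=bool)
        t = gs.voxelwise_t_map(dup, dup, mask)
        np.testing.assert_array_equal(t.data, 0.0)


class TestFweThreshold:
    def _groups(self, rng, n=8, shape=(6, 6, 6), shift=0.0):
        a = [vol(rng.normal(size=shape)) for _ in range(n)]
        b = [vol(rng.normal(-shift, size=shape)) for _ in range(n)]
        return a, b

    def test_bonferroni_single_voxel_is_uncorrected(self):
        rng = np.random.default_rng(0)
        a = [vol(rng.normal(size=(1, 1, 1))) for _ in range(5)]
        b = [vol(rng.normal(size=(1, 1, 1))) for _ in range(5)]
        mask = np.ones((1, 1, 1), dtype=bool)
        res = gs.fwe_threshold(a, b, mask, method=gs.BONFERRONI, alpha=0.05)
        assert res.threshold == pytest.approx(stats.t.isf(0.05, 8))
        assert res.df == 8

    def test_bonferroni_conservative_vs_permutation(self):
        """Bonferroni threshold exceeds the permutation max-T threshold on
        average for smoothed (spatially correlated) maps, where the union
        bound overcounts the effective number of tests."""
        diffs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            a, b = self._groups(rng, n=7, shape=(10, 10, 10))
            a = [gs.smooth_volume(v, 6.0) for v in a]
            b = [gs.smooth_volume(v, 6.0) for v in b]
            mask = np.ones((10, 10, 10), dtype=bool)
            perm = gs.fwe_threshold(
                a, b, mask, method=gs.PERMUTATION_MAXT, n_permutations=300, seed=seed
            )
            bonf = gs.fwe_threshold(a, b, mask, method=gs.BONFERRONI)
            diffs.append(bonf.threshold - perm.threshold)
        assert np.mean(diffs) > 0

    def test_injected_effect_detected_in_its_region(self):
        rng = np.random.default_rng(11)
        shape = (8, 8, 8)
        box = (slice(1, 4), slice(1, 4), slice(1, 4))
        a = []
        for _ in range(10):
            d = rng.normal(size=shape)
            d[box] += 5.0
            a.append(vol(d))
        b = [vol(rng.normal(size=shape)) for _ in range(10)]
        mask = np.ones(shape, dtype=bool)
        res = gs.fwe_threshold(
            a, b, mask, method=gs.PERMUTATION_MAXT, n_permutations=300, seed=1
        )
        sig = res.sig_mask.data.astype(bool)
        assert sig.any()
        inside = sig[box].sum()
        assert inside / sig.sum() > 0.9

    def test_sig_mask_matches_threshold_invariant(self):
        rng = np.random.default_rng(2)
        a, b = self._groups(rng, shift=0.8)
        mask = np.ones((6, 6, 6), dtype=bool)
        res = gs.fwe_threshold(
            a, b, mask, method=gs.PERMUTATION_MAXT, n_permutations=200, seed=3
        )
        expected = np.zeros_like(mask, dtype=bool)
        expected[mask] = res.t_map.data[mask] >= res.threshold
        np.testing.assert_array_equal(res.sig_mask.data.astype(bool), expected)

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(0)
        a, b = self._groups(rng)
        with pytest.raises(ValueError, match="100"):
            gs.fwe_threshold(
                a, b, np.ones((6, 6, 6), dtype=bool),
                method=gs.PERMUTATION_MAXT, n_permutations=50,
            )


class TestRegionCoverage:
    def test_full_partial_empty(self):
        atlas = two_region_atlas()
        full = np.ones(atlas.labels.shape, dtype=bool)
        cov = region_coverage(full, atlas)
        assert cov.loc["target", "coverage_percent"] == 100.0
        empty = np.zeros(atlas.labels.shape, dtype=bool)
        assert region_coverage(empty, atlas)["coverage_percent"].eq(0.0).all()

    def test_partial_count_arithmetic(self):
        atlas = two_region_atlas()
        region = atlas.region_mask(1)  # 8 voxels
        sig = np.zeros(atlas.labels.shape, dtype=bool)
        idx = np.argwhere(region)[:3]
        sig[tuple(idx.T)] = True
        cov = region_coverage(sig, atlas)
        assert cov.loc["target", "coverage_percent"] == pytest.approx(100 * 3 / 8)
        assert cov.loc["target", "volume_mm3"] == pytest.approx(8 * 2.0**3)
        assert cov.loc["target", "sig_volume_mm3"] == pytest.approx(3 * 2.0**3)


class TestRegionAnova:
    def test_hand_computed_f(self):
        table = suvr_table({"r": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]})
        labels = ["A", "A", "A", "B", "B", "B"]
        out = region_anova(table, labels)
        assert out.loc["r", "F"] == pytest.approx(1.5)

    def test_equal_means_give_zero_f_unit_p(self):
        table = suvr_table({"r": [1.0, 2.0, 1.0, 2.0]})
        out = region_anova(table, ["A", "A", "B", "B"])
        assert out.loc["r", "F"] == pytest.approx(0.0)
        assert out.loc["r", "p"] == pytest.approx(1.0)

    def test_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(8)
        table = suvr_table({f"r{i}": rng.normal(size=20).tolist() for i in range(6)})
        labels = ["A"] * 11 + ["B"] * 9
        out = region_anova(table, labels)
        for region in table.region_names:
            v = table.values[region].to_numpy()
            t = stats.ttest_ind(v[:11], v[11:]).statistic
            assert out.loc[region, "F"] == pytest.approx(t**2, abs=1e-10)

    def test_missing_values_dropped_pairwise(self):
        table = suvr_table({"r": [1.0, np.nan, 3.0, 2.0, 3.0, 4.0]})
        out = region_anova(table, ["A", "A", "A", "B", "B", "B"])
        assert out.loc["r", "n_used"] == 5
        table2 = suvr_table({"r": [1.0, np.nan, np.nan, 2.0, 3.0, 4.0]})
        out2 = region_anova(table2, ["A", "A", "A", "B", "B", "B"])
        assert np.isnan(out2.loc["r", "F"])  # one usable A subject


class TestFisherRatio:
    def test_equal_means_zero(self):
        table = suvr_table({"r": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        out = fisher_ratio(table, ["A", "A", "A", "B", "B", "B"])
        assert out["r"] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # means 2 and 0, both sample sds 1 -> J = 4 / 2 = 2
        table = suvr_table({"r": [1.0, 2.0, 3.0, -1.0, 0.0, 1.0]})
        out = fisher_ratio(table, ["A", "A", "A", "B", "B", "B"])
        assert out["r"] == pytest.approx(2.0)

    @pytest.mark.parametrize("a,b", [(3.0, 0.0), (0.5, 1.2), (10.0, -4.0)])
    def test_invariant_to_common_affine_rescaling(self, a, b):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=14)
        labels = ["A"] * 7 + ["B"] * 7
        base = fisher_ratio(suvr_table({"r": vals.tolist()}), labels)["r"]
        moved = fisher_ratio(suvr_table({"r": (a * vals + b).tolist()}), labels)["r"]
        assert moved == pytest.approx(base, abs=1e-10)

    def test_zero_variance_degenerate_cases(self):
        equal = suvr_table({"r": [2.0, 2.0, 2.0, 2.0]})
        assert fisher_ratio(equal, ["A", "A", "B", "B"])["r"] == 0.0
        separated = suvr_table({"r": [1.0, 1.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            out = fisher_ratio(separated, ["A", "A", "B", "B"])
        assert np.isnan(out["r"])
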