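import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from dtiplast.phantom import EffectSpec
from dtiplast.pipeline import generate_cohort_maps
from dtiplast.simulate import CohortDesign
from dtiplast.stats import (DesignError, age_analysis, anova_map,
                            extract_clusters, fdr_correct, mixed_anova,
                            posthoc_regional, roi_volume_change,
                            splitplot_anova)

from _oracles import random_design, splitplot_oracle


class TestMixedAnova:
    def test_all_equal_data_degenerates_to_p_one(self):
        values = np.full((9, 2), 3.0)
        res = mixed_anova(values, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res["zero_variance"]
        assert all(p == 1.0 for p in res["p"].values())
        assert res["ss"]["total"] == 0.0

    def test_single_subject_group_rejected(self):
        with pytest.raises(DesignError, match="single subject"):
            mixed_anova(np.random.default_rng(0).normal(size=(4, 2)),
                        ["a", "a", "a", "b"])

    def test_interaction_equals_difference_score_oneway(self, rng):
        """Algebraic identity with two time points, balanced or not."""
        for balanced in (True, False):
            y, groups = random_design(rng, balanced)
            res = mixed_anova(y, groups)
            d = y[:, 1] - y[:, 0]
            f = sps.f_oneway(*[d[groups == g] for g in np.unique(groups)])
            assert res["F"]["interaction"] == pytest.approx(f.statistic, rel=1e-10)
            assert res["p"]["interaction"] == pytest.approx(f.pvalue, rel=1e-8)

    def test_matches_projection_glm_oracle_on_100_random_designs(self, rng):
        for i in range(100):
            y, groups = random_design(rng, balanced=(i % 2 == 0))
            res = mixed_anova(y, groups)
            ora = splitplot_oracle(y, groups)
            for eff in ("group", "time", "interaction"):
                assert res["F"][eff] == pytest.approx(ora["F"][eff], rel=1e-8), eff
                assert res["p"][eff] == pytest.approx(ora["p"][eff], rel=1e-6), eff
                assert res["df"][eff] == ora["df"][eff]

    def test_matches_pingouin_on_balanced_design(self, rng):
        pg = pytest.importorskip("pingouin")
        y, groups = random_design(rng, balanced=True)
        n = len(groups)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "group": np.repeat(groups, 2),
            "time": np.tile([1, 2], n),
            "dv": y.ravel(),
        })
        table = pg.mixed_anova(data=df, dv="dv", within="time",
                               subject="subject", between="group")
        res = mixed_anova(y, groups)
        by_src = table.set_index("Source")["F"]
        assert res["F"]["group"] == pytest.approx(by_src["group"], rel=1e-8)
        assert res["F"]["time"] == pytest.approx(by_src["time"], rel=1e-8)
        assert res["F"]["interaction"] == pytest.approx(by_src["Interaction"],
                                                        rel=1e-8)

    def test_sum_of_squares_decomposition_is_exact(self, rng):
        for i in range(25):
            y, groups = random_design(rng, balanced=(i % 2 == 0))
            ss = mixed_anova(y, groups)["ss"]
            parts = (ss["group"] + ss["subject(group)"] + ss["time"]
                     + ss["interaction"] + ss["time x subject(group)"])
            assert parts == pytest.approx(ss["total"], rel=1e-8)


class TestAnovaMap:
    @pytest.fixture(scope="class")
    def null_cohort(self):
        design = CohortDesign.balanced(n_per_group=8, seed=314)
        # Gaussian noise: the F-test null is exact, so uniformity is exact
        return design, generate_cohort_maps(design, effects=[],
                                            smooth_fwhm=0.0, indices=("ADC",),
                                            noise_model="gaussian")

    def test_null_interaction_p_values_uniform(self, null_cohort):
        """Under H0 the voxelwise p map is U(0,1): KS not rejected at 1%."""
        design, cohort = null_cohort
        res = anova_map(cohort.maps, design.groups, cohort.mask)["ADC"]
        pvals = res.effects["interaction"].p[res.mask]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_effect_cohort_peaks_inside_injected_roi(self):
        design = CohortDesign.balanced(n_per_group=8, seed=2718)
        effects = [EffectSpec(roi="DG", index="ADC", percent=-3.0)]
        cohort = generate_cohort_maps(design, effects=effects,
                                      smooth_fwhm=0.0, indices=("ADC",))
        res = anova_map(cohort.maps, design.groups, cohort.mask)["ADC"]
        F = np.nan_to_num(res.effects["interaction"].F)
        peak = np.unravel_index(np.argmax(F), F.shape)
        assert cohort.rois.mask_of("DG")[peak]

    def test_index_selection_restricts_output(self, null_cohort):
        design, cohort = null_cohort
        out = anova_map(cohort.maps, design.groups, cohort.mask,
                        indices=("ADC",))
        assert set(out) == {"ADC"}

    def test_shape_mismatch_rejected(self, null_cohort):
        design, cohort = null_cohort
        bad = {"ADC": cohort.maps["ADC"][:, :, :8]}
        with pytest.raises(DesignError):
            anova_map(bad, design.groups, cohort.mask)


class TestFDR:
    def test_bh_declares_all_when_all_small(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        q, sig = fdr_correct(p, q=0.05)
        assert sig.all()

    def test_all_ones_nothing_significant(self):
        q, sig = fdr_correct(np.ones(50), q=0.05)
        assert not sig.any()
        np.testing.assert_allclose(q, 1.0)

    def test_single_test_reduces_to_raw_threshold(self):
        _, sig = fdr_correct(np.array([0.04]), q=0.05)
        assert sig.all()

    def test_invariant_to_voxel_ordering(self, rng):
        p = rng.uniform(1e-6, 1, 300)
        perm = rng.permutation(300)
        q1, s1 = fdr_correct(p, q=0.05)
        q2, s2 = fdr_correct(p[perm], q=0.05)
        np.testing.assert_allclose(q1[perm], q2)
        np.testing.assert_array_equal(s1[perm], s2)

    def test_monotone_in_q(self, rng):
        p = rng.uniform(1e-6, 1, 300) ** 2
        discoveries = [int(fdr_correct(p, q=q)[1].sum())
                       for q in (0.01, 0.05, 0.10, 0.20)]
        assert discoveries == sorted(discoveries)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.0, 0.5]))
        with pytest.raises(ValueError, match="empty mask"):
            fdr_correct(np.array([0.5]), mask=np.array([False]))


class TestClusters:
    def test_two_disjoint_blobs(self):
        sig = np.zeros((10, 10, 3), bool)
        sig[1:3, 1:3, :] = True
        sig[6:9, 6:9, :] = True
        table, _ = extract_clusters(sig, min_size=5)
        assert len(table) == 2

    def test_empty_mask_empty_table(self):
        table, lab = extract_clusters(np.zeros((5, 5, 2), bool))
        assert len(table) == 0 and lab.max() == 0

    def test_corner_touch_connectivity(self):
        sig = np.zeros((6, 6, 2), bool)
        sig[1, 1, 0] = sig[2, 2, 1] = True          # touch only at a corner
        t26, _ = extract_clusters(sig, connectivity=26, min_size=1)
        t6, _ = extract_clusters(sig, connectivity=6, min_size=1)
        assert len(t26) == 1 and len(t6) == 2

    def test_small_clusters_dropped_but_counted(self):
        sig = np.zeros((10, 10, 2), bool)
        sig[1:3, 1:3, 0] = True                     # 4 voxels < min 5
        table, _ = extract_clusters(sig, min_size=5)
        assert len(table) == 0
        assert table.attrs["n_dropped"] == 1


class TestPosthoc:
    def test_percent_change_arithmetic(self):
        maps = np.zeros((6, 2, 4, 4, 2))
        maps[:3, 0] = 1.0
        maps[:3, 1] = 0.97
        maps[3:, 0] = 1.0
        maps[3:, 1] = 1.0
        maps += np.random.default_rng(0).normal(0, 1e-4, maps.shape)
        region = np.ones((4, 4, 2), bool)
        ph = posthoc_regional(region, maps, ["L"] * 3 + ["NL"] * 3)
        row = ph.table.set_index("group").loc["L"]
        assert row["pct_change"] == pytest.approx(-3.0, abs=0.05)
        assert ph.driving_group == "L"

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            posthoc_regional(np.zeros((4, 4, 2), bool),
                             np.zeros((4, 2, 4, 4, 2)), ["a"] * 4)


class TestAgeAnalysis:
    def test_identical_subgroups_give_uniform_interaction_p(self):
        """Age x time interaction p-values are U(0,1) when the age subgroups
        are statistically identical; pooled over three cohorts so the check
        reflects the distribution, not one noise realization."""
        pooled = []
        for seed in (1, 2, 3):
            design = CohortDesign.age_series(n_per_age=8, seed=seed)
            cohort = generate_cohort_maps(design, effects=[], smooth_fwhm=0.0,
                                          indices=("ADC",),
                                          noise_model="gaussian")
            results, _ = age_analysis(cohort.maps, design.ages, cohort.mask)
            pooled.append(results["ADC"].effects["interaction"].p[results["ADC"].mask])
        assert sps.kstest(np.concatenate(pooled), "uniform").pvalue > 0.01

    def test_missing_subgroup_rejected(self):
        with pytest.raises(DesignError, match="age"):
            age_analysis({"ADC": np.zeros((4, 2, 2, 2, 1))}, [4, 4, 4, 4],
                         np.ones((2, 2, 1), bool))


class TestVolumeChange:
    def test_identical_labels_zero_change(self):
        lab = np.zeros((8, 8, 3), int)
        lab[2:6, 2:6, :] = 1
        res = roi_volume_change([lab] * 5, [lab.copy() for _ in range(5)],
                                label=1, voxel_volume=0.048)
        assert res["pct_change_mean"] == 0.0

    def test_one_extra_voxel_on_thousand(self):
        lab1 = np.zeros((10, 10, 11), int)
        lab1.ravel()[:1000] = 1
        lab2 = lab1.copy()
        lab2.ravel()[1000] = 1
        res = roi_volume_change([lab1], [lab2], label=1, voxel_volume=1.0)
        assert res["pct_change_mean"] == pytest.approx(0.1)

    def test_null_cohort_ci_covers_zero(self, rng):
        labs1, labs2 = [], []
        for _ in range(12):
            for dest in (labs1, labs2):
                lab = np.zeros((12, 12, 4), int)
                lab[(rng.random((12, 12, 4)) < 0.4)] = 1
                dest.append(lab)
        res = roi_volume_change(labs1, labs2, label=1, voxel_volume=0.048)
        se = res["pct_change"].std(ddof=1) / np.sqrt(len(res["pct_change"]))
        assert abs(res["pct_change_mean"]) < 3 * se + 1e-9

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError):
            roi_volume_change([np.zeros((4, 4, 2), int)],
                              [np.zeros((4, 4, 2), int)], label=1,
                              voxel_volume=1.0)


@given(st.integers(0, 10_000))
def test_splitplot_vectorized_matches_scalar_path(seed):
    """The voxel-broadcast engine equals the single-voxel computation."""
    rng = np.random.default_rng(seed)
    y, groups = random_design(rng, balanced=bool(seed % 2))
    V = 4
    Y1 = np.tile(y[:, 0][:, None], (1, V)) + rng.normal(0, 0.1, (len(y), V))
    Y2 = np.tile(y[:, 1][:, None], (1, V)) + rng.normal(0, 0.1, (len(y), V))
    vec = splitplot_anova(Y1, Y2, groups)
    for v in range(V):
        single = mixed_anova(np.stack([Y1[:, v], Y2[:, v]], axis=1), groups)
        for eff in ("group", "time", "interaction"):
            assert vec["F"][eff][v] == pytest.approx(single["F"][eff], rel=1e-10)
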