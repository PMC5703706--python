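"""Group statistics: smoothing, paired cluster inference, ROI tests, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import curve_fit

import lagflow as lf
from lagflow import stats as gs
from lagflow.errors import DesignError


VS = 3.0  # mm, phantom voxel size


def synth_map(truth, field, noise_sd, rng, valid=None):
    lag = np.where(truth.mask, field + rng.normal(0, noise_sd, truth.mask.shape), 0.0)
    return lag


class TestSmoothing:
    def test_impulse_response_fwhm(self):
        img = np.zeros((31, 31, 31))
        img[15, 15, 15] = 1.0
        sm = gs.smooth_gaussian(img, fwhm=6.0, voxel_sizes=1.0)
        x = np.arange(31, dtype=float)
        prof = sm[:, 15, 15]
        popt, _ = curve_fit(
            lambda x, a, mu, sig: a * np.exp(-((x - mu) ** 2) / (2 * sig**2)),
            x, prof, p0=[prof.max(), 15, 2.5],
        )
        measured_fwhm = abs(popt[2]) / gs.FWHM_TO_SIGMA
        assert measured_fwhm == pytest.approx(6.0, abs=1.0)

    def test_constant_map_unchanged(self, truth):
        const = np.where(truth.mask, 3.25, 0.0)
        sm = gs.smooth_gaussian(const, fwhm=6.0, voxel_sizes=VS, valid=truth.mask)
        np.testing.assert_allclose(sm[truth.mask], 3.25, atol=1e-9)

    def test_fwhm_zero_identity(self, truth):
        rng = np.random.default_rng(0)
        img = rng.normal(size=truth.mask.shape)
        sm = gs.smooth_gaussian(img, fwhm=0.0, voxel_sizes=VS, valid=truth.mask)
        np.testing.assert_array_equal(sm[truth.mask], img[truth.mask])
        assert np.all(sm[~truth.mask] == 0)

    def test_invalid_voxels_isolated(self, truth):
        img = np.where(truth.mask, 1.0, 0.0)
        holes = truth.mask.copy()
        holes[8, 8, 4] = False
        img[8, 8, 4] = 1e6  # must not leak into the valid neighbourhood
        sm = gs.smooth_gaussian(img, fwhm=6.0, voxel_sizes=VS, valid=holes)
        assert sm[8, 8, 4] == 0.0
        np.testing.assert_allclose(sm[holes], 1.0, atol=1e-9)

    def test_in_mask_mean_approximately_preserved(self, truth):
        rng = np.random.default_rng(3)
        img = np.where(truth.mask, rng.normal(size=truth.mask.shape), 0.0)
        sm = gs.smooth_gaussian(img, fwhm=6.0, voxel_sizes=VS, valid=truth.mask)
        drift = abs(sm[truth.mask].mean() - img[truth.mask].mean())
        assert drift < 0.02 * img[truth.mask].std()

    def test_small_fwhm_warns(self, truth):
        img = np.zeros(truth.mask.shape)
        with pytest.warns(UserWarning, match="voxel size"):
            gs.smooth_gaussian(img, fwhm=1.0, voxel_sizes=VS, valid=truth.mask)


class TestPairedContrast:
    def _cohort_maps(self, truth, shift, n=10, noise=0.4, seed=0):
        rng = np.random.default_rng(seed)
        pre, post = [], []
        for _ in range(n):
            base = truth.delay_field + rng.normal(0, 0.3)  # subject offset
            pre.append(synth_map(truth, base, noise, rng))
            post.append(synth_map(truth, base + shift, noise, rng))
        return pre, post

    def test_two_pairs_cannot_reach_cluster_p(self, truth):
        pre, post = self._cohort_maps(truth, truth.shift_field, n=2)
        with pytest.raises(DesignError, match="minimum attainable"):
            gs.paired_contrast(pre, post, mask=truth.mask)

    def test_shift_detected_in_decrease_direction_only(self, truth):
        pre, post = self._cohort_maps(truth, truth.shift_field, n=10, seed=1)
        pre = [gs.smooth_gaussian(m, 6.0, VS, truth.mask) for m in pre]
        post = [gs.smooth_gaussian(m, 6.0, VS, truth.mask) for m in post]
        res = gs.paired_contrast(pre, post, mask=truth.mask)
        assert res.exhaustive and res.n_permutations == 1024
        assert res.decrease.n_significant == 1
        assert res.increase.n_significant == 0
        sig = res.decrease.significant_mask()
        target = truth.regions["target"]
        assert (sig & target).sum() / target.sum() > 0.9

    def test_sign_coherence_upstream_shift(self, truth):
        # injecting a positive (upstream) shift must flip the detecting contrast
        pre, post = self._cohort_maps(truth, -truth.shift_field, n=10, seed=2)
        pre = [gs.smooth_gaussian(m, 6.0, VS, truth.mask) for m in pre]
        post = [gs.smooth_gaussian(m, 6.0, VS, truth.mask) for m in post]
        res = gs.paired_contrast(pre, post, mask=truth.mask)
        assert res.increase.n_significant == 1
        assert res.decrease.n_significant == 0

    def test_null_rarely_significant(self, truth):
        hits = 0
        for seed in range(5):
            pre, post = self._cohort_maps(truth, 0.0, n=10, seed=seed + 10)
            pre = [gs.smooth_gaussian(m, 6.0, VS, truth.mask) for m in pre]
            post = [gs.smooth_gaussian(m, 6.0, VS, truth.mask) for m in post]
            res = gs.paired_contrast(pre, post, mask=truth.mask)
            hits += res.decrease.n_significant + res.increase.n_significant
        assert hits == 0  # P(any) ~ 2*0.005 per repeat; 5 repeats

    def test_unmatched_design_rejected(self, truth):
        pre, post = self._cohort_maps(truth, 0.0, n=4)
        design = pd.DataFrame(
            {"subject_id": ["a", "a", "b", "c"], "session": ["pre", "post", "pre", "pre"]}
        )
        with pytest.raises(DesignError, match="one pre and one post"):
            gs.paired_contrast(pre, post, design=design, mask=truth.mask)


class TestRoiCompare:
    def _maps(self, truth, phases, sd, rng):
        maps = []
        for ph in phases:
            lag = np.where(truth.regions["deep"], ph, truth.delay_field)
            lag = lag + rng.normal(0, sd, truth.mask.shape)
            lag = np.where(truth.mask, np.round(lag / 0.5) * 0.5, 0.0)
            maps.append(
                lf.LagMap(lag=lag, peak_r=np.full(truth.mask.shape, 0.8),
                          valid=truth.mask.copy(), mask=truth.mask, affine=np.eye(4))
            )
        return maps

    def test_group_difference_detected(self, truth):
        rng = np.random.default_rng(0)
        phases = np.r_[np.full(30, -2.0), np.full(30, 0.0)]
        maps = self._maps(truth, phases, 0.5, rng)
        design = pd.DataFrame({
            "group": ["young"] * 30 + ["elderly"] * 30,
            "session": "single", "subject_id": [f"s{i}" for i in range(60)],
        })
        res = gs.roi_group_compare(maps, truth.regions["deep"], design,
                                   ("young", "elderly"))
        assert res.p < 1e-5
        assert res.difference == pytest.approx(-2.0, abs=0.3)

    def test_identical_groups_null(self, truth):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(40):
            maps = self._maps(truth, np.zeros(8), 1.0, rng)
            design = pd.DataFrame({
                "group": ["a"] * 4 + ["b"] * 4, "session": "single",
                "subject_id": [f"s{i}" for i in range(8)],
            })
            pvals.append(gs.roi_group_compare(maps, truth.regions["deep"], design,
                                              ("a", "b")).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_subject_group_rejected(self, truth):
        rng = np.random.default_rng(2)
        maps = self._maps(truth, np.zeros(3), 0.5, rng)
        design = pd.DataFrame({
            "group": ["a", "b", "b"], "session": "single",
            "subject_id": ["x", "y", "z"],
        })
        with pytest.raises(DesignError, match="two subjects"):
            gs.roi_group_compare(maps, truth.regions["deep"], design, ("a", "b"))


class TestAgeRegression:
    def _cohort(self, truth, slope_field, n, seed, sd=0.6):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(20, 80, n)
        sexes = rng.choice(["F", "M"], n)
        maps = [
            synth_map(truth, truth.delay_field + (a - 50.0) * slope_field, sd, rng)
            for a in ages
        ]
        maps = [
            lf.LagMap(lag=m, peak_r=np.full(truth.mask.shape, 0.8),
                      valid=truth.mask.copy(), mask=truth.mask, affine=np.eye(4))
            for m in maps
        ]
        design = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)], "group": "control",
            "session": "single", "age": ages, "sex": sexes,
        })
        return maps, design

    def test_signed_regions_recovered(self, truth):
        maps, design = self._cohort(truth, truth.age_slope_field, 40, seed=0)
        mc = gs.cluster_voxels_for_volume(1600.0, VS)
        res = gs.age_regression(maps, design, min_cluster=mc)
        deep, sup = truth.regions["deep"], truth.regions["superficial"]
        pos, neg = res.positive.significant_mask(), res.negative.significant_mask()
        sens = ((pos & deep).sum() + (neg & sup).sum()) / (deep.sum() + sup.sum())
        outside = truth.mask & ~(deep | sup)
        fp = ((pos | neg) & outside).sum() / outside.sum()
        assert sens >= 0.8 and fp <= 0.05
        assert res.beta_age[deep & res.valid].mean() == pytest.approx(0.05, abs=0.01)

    def test_null_fdr_calibrated(self, truth):
        fracs = []
        for seed in range(3):
            maps, design = self._cohort(truth, np.zeros(truth.mask.shape), 25, seed=seed)
            res = gs.age_regression(maps, design, min_cluster=1)
            fracs.append(res.fdr_significant[res.valid].mean())
        assert np.mean(fracs) <= 0.05

    def test_min_cluster_filters_everything(self, truth):
        maps, design = self._cohort(truth, truth.age_slope_field, 40, seed=1)
        res = gs.age_regression(maps, design, min_cluster=10_000)
        assert res.fdr_significant.sum() > 0  # voxel-level hits exist
        assert not res.significant_mask().any()  # ...but no cluster survives

    def test_too_few_subjects_rejected(self, truth):
        maps, design = self._cohort(truth, truth.age_slope_field, 4, seed=2)
        with pytest.raises(DesignError, match="at least"):
            gs.age_regression(maps, design)

    def test_rank_deficient_design_names_columns(self, truth):
        maps, design = self._cohort(truth, truth.age_slope_field, 10, seed=3)
        design["sex"] = "F"  # constant column -> collinear with intercept
        with pytest.raises(DesignError, match="sex"):
            gs.age_regression(maps, design)


class TestClusterVolumeHelper:
    def test_canonical_definition(self):
        assert gs.cluster_voxels_for_volume(1600.0, 2.0) == 200
        assert gs.cluster_voxels_for_volume(1600.0, 3.0) == 59
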