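"""Group statistics: voxelwise t-tests, smoothness estimation, Monte-Carlo
cluster-extent thresholds, cluster extraction, partial correlation, FDR,
and the demographic-table tests."""

import numpy as np
import pingouin as pg
import pytest
from scipy import ndimage, stats as sstats

from fsfcd.core import mask_coordinates
from fsfcd.fcd import FWHM_TO_SIGMA, FcdMap
from fsfcd.stats import (
    CorrectionConfig,
    StatMap,
    contingency_chisq,
    estimate_smoothness,
    extract_clusters,
    fdr_bh,
    monte_carlo_cluster_threshold,
    partial_correlation,
    two_sample_ttest_scalar,
    voxelwise_ttest,
)

GRID = (8, 8, 8)
VOX = (3.0, 3.0, 3.0)
COORDS = mask_coordinates(np.ones(GRID, bool))
GEOM = (COORDS, GRID, VOX)


def as_maps(rows):
    return [
        FcdMap(values=r, voxel_index=COORDS, grid_shape=GRID, voxel_size_mm=VOX,
               kind="global", stage="zscored")
        for r in rows
    ]


class TestVoxelwiseTtest:
    def test_identical_groups_give_zero_t(self, rng):
        maps = rng.standard_normal((4, len(COORDS)))
        stat = voxelwise_ttest(as_maps(maps), as_maps(maps.copy()))
        assert np.allclose(stat.t_values[np.isfinite(stat.t_values)], 0)
        assert stat.df == 6

    def test_matches_independent_closed_form(self, rng):
        a = rng.standard_normal((6, 40))
        b = rng.standard_normal((5, 40))
        stat = voxelwise_ttest(a, b, geometry=(COORDS[:40], GRID, VOX))
        t_ref, _ = sstats.ttest_ind(a, b, axis=0, equal_var=True)
        assert np.allclose(stat.t_values, t_ref, atol=1e-12)

    def test_planted_shift_produces_expected_noncentrality(self, rng):
        # 1-SD mean shift at n=15/group: E[t] ~ sqrt(n/2) = 2.74
        n, v = 15, 300
        region = slice(0, 60)
        ts = []
        for _ in range(20):
            a = rng.standard_normal((n, v))
            b = rng.standard_normal((n, v))
            a[:, region] += 1.0
            stat = voxelwise_ttest(a, b, geometry=(COORDS[:v], GRID, VOX))
            ts.append(stat.t_values)
        ts = np.mean(ts, axis=0)
        assert abs(ts[region].mean() - np.sqrt(n / 2)) < 0.3
        assert abs(ts[60:].mean()) < 0.2

    def test_sign_convention_is_group_a_minus_group_b(self, rng):
        a = np.full((3, 10), 5.0) + 0.1 * rng.standard_normal((3, 10))
        b = np.zeros((3, 10)) + 0.1 * rng.standard_normal((3, 10))
        stat = voxelwise_ttest(a, b, geometry=(COORDS[:10], GRID, VOX))
        assert np.all(stat.t_values > 0)

    def test_too_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            voxelwise_ttest(rng.standard_normal((1, 5)),
                            rng.standard_normal((3, 5)),
                            geometry=(COORDS[:5], GRID, VOX))


class TestEstimateSmoothness:
    def test_recovers_known_kernel_within_tolerance(self, rng):
        fwhm_vox = 2.0
        sigma = fwhm_vox * FWHM_TO_SIGMA
        coords = mask_coordinates(np.ones((16, 16, 16), bool))
        maps = []
        for _ in range(12):
            n = ndimage.gaussian_filter(rng.standard_normal((16, 16, 16)), sigma,
                                        mode="constant")
            maps.append(FcdMap(values=n[tuple(coords.T)], voxel_index=coords,
                               grid_shape=(16, 16, 16), voxel_size_mm=VOX,
                               kind="global", stage="zscored"))
        est = estimate_smoothness(maps)
        for f in est:
            assert abs(f - fwhm_vox * 3.0) / (fwhm_vox * 3.0) < 0.2

    def test_unsmoothed_noise_estimates_near_zero(self, rng):
        maps = as_maps(rng.standard_normal((6, len(COORDS))))
        est = estimate_smoothness(maps)
        for f in est:
            assert f <= 1.2 * 3.0  # at most ~1.2 voxels per axis

    def test_user_supplied_triple_bypasses_estimation(self):
        cfg = CorrectionConfig(fwhm_mm=(14.22, 15.91, 15.69))
        assert cfg.fwhm_mm == (14.22, 15.91, 15.69)


class TestMonteCarloClusterThreshold:
    MASK = np.ones((8, 8, 8), bool)

    def test_alpha_one_returns_single_voxel(self):
        cfg = CorrectionConfig(alpha=1.0, n_sims=100, fwhm_mm=(6, 6, 6), seed=1)
        assert monte_carlo_cluster_threshold(self.MASK, cfg, VOX) == 1

    def test_unsmoothed_null_matches_poisson_oracle(self):
        # independent voxels at p=0.001 two-tailed on ~500 voxels:
        # P(any suprathreshold voxel) ~ 0.4, pairs vanishingly rare -> k in {1,2}
        mask = np.zeros((10, 10, 10), bool)
        mask[1:9, 1:9, 1:9] = True  # 512 voxels
        cfg = CorrectionConfig(voxel_p=0.001, alpha=0.05, n_sims=500,
                               fwhm_mm=(0.0, 0.0, 0.0), seed=3)
        k = monte_carlo_cluster_threshold(mask, cfg, VOX)
        assert k in (1, 2)

    def test_extent_nondecreasing_in_smoothness(self):
        mask = np.ones((14, 14, 14), bool)
        ks = []
        for f in (0.0, 6.0, 12.0):
            cfg = CorrectionConfig(n_sims=500, fwhm_mm=(f, f, f), seed=5)
            ks.append(monte_carlo_cluster_threshold(mask, cfg, VOX))
        assert ks == sorted(ks)
        assert ks[0] < ks[-1]

    def test_unresolvable_alpha_rejected(self):
        cfg = CorrectionConfig(alpha=0.001, n_sims=100, fwhm_mm=(6, 6, 6))
        with pytest.raises(ValueError, match="n_sims"):
            monte_carlo_cluster_threshold(self.MASK, cfg, VOX)


class TestExtractClusters:
    def _stat(self, tvol, df=28):
        return StatMap(t_values=tvol[tuple(COORDS.T)], df=df, voxel_index=COORDS,
                       grid_shape=GRID, voxel_size_mm=VOX)

    def test_zero_map_has_no_clusters(self):
        cfg = CorrectionConfig()
        assert extract_clusters(self._stat(np.zeros(GRID)), cfg, 1) == []

    def test_single_blob_survives_extent_threshold(self):
        tvol = np.zeros(GRID)
        tvol[1:6, 1:6, 1:6] = 10.0  # 125 voxels
        cfg = CorrectionConfig()
        recs = extract_clusters(self._stat(tvol), cfg, 100)
        assert len(recs) == 1
        assert recs[0].size == 125
        assert recs[0].sign == "increase"
        assert extract_clusters(self._stat(tvol), cfg, 126) == []

    def test_corner_touching_blobs_split_by_connectivity(self):
        tvol = np.zeros(GRID)
        tvol[0:2, 0:2, 0:2] = 8.0
        tvol[2:4, 2:4, 2:4] = 8.0  # touches the first only at a corner
        six = CorrectionConfig(connectivity=6)
        twentysix = CorrectionConfig(connectivity=26)
        assert len(extract_clusters(self._stat(tvol), six, 1)) == 2
        assert len(extract_clusters(self._stat(tvol), twentysix, 1)) == 1

    def test_signs_are_labeled_separately(self):
        tvol = np.zeros(GRID)
        tvol[0:2, 0:2, 0:2] = 8.0
        tvol[0:2, 0:2, 2:4] = -8.0  # adjacent but opposite sign
        recs = extract_clusters(self._stat(tvol), CorrectionConfig(), 1)
        assert {r.sign for r in recs} == {"increase", "decrease"}
        assert all(r.size == 8 for r in recs)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 40))
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sstats.pearsonr(x, y)
        assert np.isclose(r, r_ref)
        assert np.isclose(p, p_ref, atol=1e-10)

    def test_outcome_duplicated_as_covariate_kills_correlation(self, rng):
        x = rng.standard_normal(40)
        y = 0.8 * x + 0.1 * rng.standard_normal(40)
        # residualizing y on itself leaves only numerical noise
        r, _ = partial_correlation(x, y, covariates=y[:, None])
        assert abs(r) < 0.05

    def test_matches_inverse_correlation_oracle(self, rng):
        x, y = rng.standard_normal((2, 60))
        cov = rng.standard_normal((60, 2))
        r, p = partial_correlation(x, y, covariates=cov)
        import pandas as pd

        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert abs(r - ref["r"].iloc[0]) < 1e-10
        assert abs(p - ref["p_val"].iloc[0]) < 1e-8

    def test_collinear_covariates_rejected(self, rng):
        x, y = rng.standard_normal((2, 30))
        c = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, covariates=np.column_stack([c, 2 * c]))


class TestFdrBh:
    def test_all_tiny_p_rejected(self):
        assert fdr_bh([0.001] * 10, 0.05).all()

    def test_single_p_compares_to_q(self):
        assert fdr_bh([0.04], 0.05).all()
        assert not fdr_bh([0.06], 0.05).any()

    def test_step_up_rule_worked_by_hand(self):
        flags = fdr_bh([0.001, 0.01, 0.02, 0.8], 0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_empty_input(self):
        assert fdr_bh([], 0.05).size == 0


class TestDemographicTests:
    def test_gender_table_reproduces_published_p(self):
        chi2, p = contingency_chisq([[14, 17], [16, 12]])
        assert round(p, 2) == 0.36

    def test_balanced_table_has_no_association(self):
        chi2, p = contingency_chisq([[10, 10], [10, 10]])
        assert chi2 == 0 and p == 1

    def test_chisq_permutation_null_matches_exact_conditional_enumeration(self, rng):
        # permutation oracle: shuffle group labels, recompute the statistic.
        # Its reference is the exact margin-conditional null (hypergeometric
        # enumeration), NOT the asymptotic chi-square p: on a table this
        # small the two differ visibly (0.44 exact vs 0.36 asymptotic).
        table = np.array([[14, 17], [16, 12]])
        chi2_obs, _ = contingency_chisq(table)
        labels = np.repeat([0, 1], [31, 28])
        sex = np.concatenate([np.repeat([1, 0], [14, 17]),
                              np.repeat([1, 0], [16, 12])])
        total_m = int(sex.sum())
        n_perm = 20000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            m_pat = int(sex[perm == 0].sum())
            tab = np.array([[m_pat, 31 - m_pat],
                            [total_m - m_pat, 28 - (total_m - m_pat)]])
            chi2_perm, _ = contingency_chisq(tab)
            count += chi2_perm >= chi2_obs - 1e-12
        p_perm = count / n_perm
        p_exact = 0.0
        for m in range(max(0, total_m - 28), min(total_m, 31) + 1):
            tab = [[m, 31 - m], [total_m - m, 28 - (total_m - m)]]
            chi2_m, _ = contingency_chisq(tab)
            if chi2_m >= chi2_obs - 1e-12:
                p_exact += sstats.hypergeom.pmf(m, 59, total_m, 31)
        assert abs(p_perm - p_exact) < 0.015

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_chisq([[31, 0], [28, 0]])

    def test_identical_samples_give_t_zero(self):
        t, p = two_sample_ttest_scalar([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and np.isclose(p, 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_ttest_scalar([0.0, 0.0], [1.0, 1.0])

    def test_random_samples_match_pooled_formula(self, rng):
        a, b = rng.standard_normal(12) + 0.5, rng.standard_normal(15)
        t, p = two_sample_ttest_scalar(a, b)
        n1, n2 = len(a), len(b)
        sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
                     / (n1 + n2 - 2))
        t_ref = (a.mean() - b.mean()) / (sp * np.sqrt(1 / n1 + 1 / n2))
        assert abs(t - t_ref) < 1e-12
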