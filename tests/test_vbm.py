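"""Tests for the voxel-wise GLM, clustering, FDR and ROI analysis."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lingvbm.vbm import (
    GLMResult,
    build_design,
    fdr_correct,
    fit_voxelwise,
    group_difference_tmap,
    roi_analysis,
    threshold_and_cluster,
)
from lingvbm.volume_io import ROIMask, VolumeImage

from conftest import make_design, make_volumes


def make_result_from_t(t_map, df=33, mask=None, direction="positive"):
    """GLMResult stub with a given t map (p derived from it)."""
    t_map = np.asarray(t_map, dtype=float)
    if mask is None:
        mask = np.ones(t_map.shape, dtype=bool)
    p = stats.t.sf(t_map, df) if direction == "positive" else 2 * stats.t.sf(np.abs(t_map), df)
    return GLMResult(
        beta=t_map[None],
        t=t_map,
        p=p,
        df=df,
        mask=mask,
        affine=np.eye(4),
        columns=["score"],
        tested="score",
        direction=direction,
    )


class TestBuildDesign:
    def make_scores(self, table, rng):
        return pd.DataFrame(
            {
                "participant_id": table["participant_id"],
                "pp_1g": rng.normal(200, 30, len(table)),
                "pp_2g": rng.normal(115, 20, len(table)),
            }
        )

    def test_full_design_shape_and_order(self, cohort_table, rng):
        table = cohort_table.assign(tiv_ml=rng.normal(1400, 100, len(cohort_table)))
        design = build_design(table, self.make_scores(table, rng), tested="pp_1g")
        assert design.matrix.shape == (38, 5)
        assert design.columns == ["intercept", "pp_1g", "sex", "education_years", "tiv_ml"]
        assert design.tested_index == 1

    def test_constant_column_raises_naming_culprit(self, cohort_table, rng):
        table = cohort_table.assign(
            tiv_ml=rng.normal(1400, 100, len(cohort_table)), education_years=12.0
        )
        with pytest.raises(ValueError, match="education_years"):
            build_design(table, self.make_scores(table, rng), tested="pp_1g")

    def test_deterministic(self, cohort_table, rng):
        table = cohort_table.assign(tiv_ml=rng.normal(1400, 100, len(cohort_table)))
        scores = self.make_scores(table, rng)
        d1 = build_design(table, scores, tested="pp_2g")
        d2 = build_design(table, scores, tested="pp_2g")
        np.testing.assert_array_equal(d1.matrix, d2.matrix)

    def test_incomplete_rows_dropped(self, cohort_table, rng):
        table = cohort_table.assign(tiv_ml=rng.normal(1400, 100, len(cohort_table)))
        scores = self.make_scores(table, rng)
        scores.loc[0, "pp_1g"] = np.nan
        design = build_design(table, scores, tested="pp_1g")
        assert design.n == 37
        assert design.n_dropped == 1

    def test_missing_column_named(self, cohort_table, rng):
        with pytest.raises(ValueError, match="tiv_ml"):
            build_design(cohort_table, self.make_scores(cohort_table, rng), tested="pp_1g")


class TestFitVoxelwise:
    def test_no_covariate_t_equals_correlation_identity(self, rng):
        n = 38
        score = rng.normal(size=n)
        data = rng.normal(size=(n, 3, 3, 3))
        design = make_design(np.column_stack([np.ones(n), score]), ["intercept", "s"], "s")
        result = fit_voxelwise(make_volumes(data), design, mask=np.ones((3, 3, 3), bool))
        for idx in np.ndindex(3, 3, 3):
            r = np.corrcoef(score, data[(slice(None), *idx)])[0, 1]
            expected = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
            assert result.t[idx] == pytest.approx(expected, abs=1e-9)

    def test_exact_correlation_0841_gives_t_9327(self, rng):
        # construct data with sample correlation exactly 0.841 at n = 38
        n, r = 38, 0.841
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x  # orthogonalize
        z /= z.std()
        y = r * x + math.sqrt(1 - r * r) * z
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(r, abs=1e-12)
        data = np.tile(y[:, None, None, None], (1, 1, 1, 1))
        design = make_design(np.column_stack([np.ones(n), x]), ["intercept", "s"], "s")
        result = fit_voxelwise(make_volumes(data), design, mask=np.ones((1, 1, 1), bool))
        assert result.t[0, 0, 0] == pytest.approx(9.327, abs=1e-3)
        assert result.df == 36

    def test_matches_independent_per_voxel_ols(self, rng):
        import statsmodels.api as sm

        n = 20
        x = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        data = rng.normal(size=(n, 2, 2, 2))
        design = make_design(x, ["intercept", "s", "c"], "s")
        result = fit_voxelwise(make_volumes(data), design, mask=np.ones((2, 2, 2), bool))
        for idx in np.ndindex(2, 2, 2):
            fit = sm.OLS(data[(slice(None), *idx)], x).fit()
            assert result.t[idx] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert result.beta[(1, *idx)] == pytest.approx(fit.params[1], abs=1e-10)

    def test_zero_residual_voxel_inf_t_and_warning(self, rng, caplog):
        n = 10
        score = rng.normal(size=n)
        data = np.broadcast_to(
            (2.0 + 3.0 * score)[:, None, None, None], (n, 1, 1, 1)
        ).copy()
        design = make_design(np.column_stack([np.ones(n), score]), ["intercept", "s"], "s")
        with caplog.at_level(logging.WARNING):
            result = fit_voxelwise(make_volumes(data), design, mask=np.ones((1, 1, 1), bool))
        assert np.isinf(result.t[0, 0, 0]) and result.t[0, 0, 0] > 0
        assert result.p[0, 0, 0] == 0.0
        assert any("zero residual" in r.message for r in caplog.records)

    def test_participant_permutation_invariance(self, rng):
        n = 16
        x = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        data = rng.normal(size=(n, 4, 4, 3))
        design = make_design(x, ["intercept", "s", "c"], "s")
        mask = np.ones((4, 4, 3), bool)
        base = fit_voxelwise(make_volumes(data), design, mask=mask)
        perm = rng.permutation(n)
        design_p = make_design(x[perm], ["intercept", "s", "c"], "s")
        permuted = fit_voxelwise(make_volumes(data[perm]), design_p, mask=mask)
        np.testing.assert_allclose(base.t, permuted.t, atol=1e-10)


class TestThresholdAndCluster:
    def test_single_blob_of_129_voxels(self):
        t = np.zeros((20, 20, 10))
        blob = np.zeros_like(t, dtype=bool)
        count = 0
        for idx in np.ndindex(20, 20, 10):  # carve a connected 129-voxel blob
            if count < 129 and 4 <= idx[0] < 11 and 4 <= idx[1] < 11 and 3 <= idx[2] < 7:
                blob[idx] = True
                count += 1
        assert blob.sum() == 129
        t[blob] = 4.0
        t[7, 7, 5] = 4.24  # peak
        result = make_result_from_t(t)
        clusters = threshold_and_cluster(result, p_voxel=0.001, k_min=100)
        assert len(clusters) == 1
        assert clusters[0].n_voxels == 129
        assert clusters[0].peak_t == pytest.approx(4.24)
        assert clusters[0].peak_ijk == (7, 7, 5)

    def test_subthreshold_extent_cluster_dropped(self):
        t = np.zeros((20, 20, 12))
        t[1:7, 1:6, 1:5] = 5.0  # 120 voxels
        t[10:19, 9:20, 8:9] = 5.0  # 99 voxels (9*11*1)
        assert (t[10:19, 9:20, 8:9] > 0).sum() == 99
        clusters = threshold_and_cluster(make_result_from_t(t), k_min=100)
        assert len(clusters) == 1
        assert clusters[0].n_voxels == 120

    def test_single_voxel_cluster(self):
        t = np.zeros((5, 5, 5))
        t[2, 3, 1] = 6.0
        clusters = threshold_and_cluster(make_result_from_t(t), k_min=1)
        assert len(clusters) == 1
        assert clusters[0].peak_ijk == (2, 3, 1)
        assert clusters[0].peak_mm == (2.0, 3.0, 1.0)

    def test_connectivity_merges_edge_neighbours(self):
        t = np.zeros((6, 6, 6))
        t[2, 2, 2] = 5.0
        t[3, 3, 2] = 5.0  # edge-touching diagonal in-plane
        res = make_result_from_t(t)
        assert len(threshold_and_cluster(res, k_min=1, connectivity=6)) == 2
        assert len(threshold_and_cluster(res, k_min=1, connectivity=18)) == 1

    def test_sorted_by_peak_t(self):
        t = np.zeros((12, 12, 6))
        t[0:2, 0:2, 0:2] = 4.0
        t[8:10, 8:10, 3:5] = 7.0
        clusters = threshold_and_cluster(make_result_from_t(t), k_min=1)
        assert [c.peak_t for c in clusters] == sorted(
            (c.peak_t for c in clusters), reverse=True
        )

    def test_empty_suprathreshold_set(self):
        clusters = threshold_and_cluster(make_result_from_t(np.zeros((5, 5, 5))))
        assert clusters == []

    @pytest.mark.parametrize("kwargs", [{"p_voxel": 0.0}, {"k_min": 0}, {"connectivity": 5}])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            threshold_and_cluster(make_result_from_t(np.zeros((4, 4, 4))), **kwargs)


class TestClusteringOracle:
    def test_components_match_flood_fill_on_random_lattices(self):
        from lingvbm.validation import cluster_oracle_mismatches

        assert cluster_oracle_mismatches(seed=9, n_lattices=100) == 0


class TestFDR:
    def test_hand_example_rejects_all_four(self):
        reject, p_adj = fdr_correct(np.array([0.001, 0.01, 0.02, 0.05]), q=0.05)
        assert reject.sum() == 4
        assert np.all(np.diff(p_adj[np.argsort([0.001, 0.01, 0.02, 0.05])]) >= 0)

    def test_all_ones_rejects_none(self):
        reject, _ = fdr_correct(np.ones(10), q=0.05)
        assert reject.sum() == 0

    def test_single_p_reduces_to_raw_comparison(self):
        reject, _ = fdr_correct(np.array([0.04]), q=0.05)
        assert reject[0]

    def test_empty_input(self):
        reject, p_adj = fdr_correct(np.array([]), q=0.05)
        assert reject.size == 0 and p_adj.size == 0

    def test_bh_contains_bonferroni(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** 2
            bh, _ = fdr_correct(p, q=0.05)
            bonf = p <= 0.05 / m
            assert not np.any(bonf & ~bh)


class TestROIAnalysis:
    def test_single_peak_voxel_mask_matches_whole_brain_peak(self, rng):
        t = rng.normal(size=(8, 8, 8))
        result = make_result_from_t(t)
        peak = np.unravel_index(np.argmax(t), t.shape)
        mask = np.zeros_like(t, dtype=bool)
        mask[peak] = True
        report = roi_analysis(result, [ROIMask("peak", 1, mask)], p_voxel=0.001, k_min=1)
        assert report["peak_t"].iloc[0] == pytest.approx(t.max())

    def test_mask_outside_analysis_mask_rejected(self):
        t = np.zeros((6, 6, 6))
        analysis_mask = np.zeros_like(t, dtype=bool)
        analysis_mask[:3] = True
        result = make_result_from_t(t, mask=analysis_mask)
        roi = np.zeros_like(t, dtype=bool)
        roi[5, 5, 5] = True
        with pytest.raises(ValueError, match="analysis mask"):
            roi_analysis(result, [ROIMask("outside", 1, roi)])

    def test_significance_flag_follows_peak_p(self):
        t = np.zeros((6, 6, 6))
        t[1, 1, 1] = 10.0
        result = make_result_from_t(t)
        roi = np.zeros_like(t, dtype=bool)
        roi[:3, :3, :3] = True
        report = roi_analysis(result, [ROIMask("hot", 1, roi)])
        assert bool(report["significant"].iloc[0])
        cold = np.zeros_like(t, dtype=bool)
        cold[4:, 4:, 4:] = True
        report = roi_analysis(result, [ROIMask("cold", 2, cold)])
        assert not bool(report["significant"].iloc[0])


class TestGroupDifference:
    def test_identical_groups_give_zero_t(self, rng):
        data = rng.random((1, 4, 4, 4))
        vols = make_volumes(np.tile(data, (8, 1, 1, 1)))
        result = group_difference_tmap(vols, ["HC"] * 4 + ["MCI"] * 4)
        assert np.nanmax(np.abs(result.t)) == 0.0

    def test_planted_atrophy_peak_inside_lesioned_box(self, rng):
        n = 20
        groups = ["HC"] * 12 + ["MCI"] * 8
        data = rng.normal(1.0, 0.05, size=(n, 10, 10, 10))
        for i in range(12, 20):
            data[i, 2:6, 2:6, 2:6] -= 0.4
        result = group_difference_tmap(make_volumes(data), groups)
        peak = np.unravel_index(np.nanargmax(np.abs(result.t)), result.t.shape)
        assert all(2 <= v < 6 for v in peak)

    def test_single_group_rejected(self, rng):
        vols = make_volumes(rng.random((4, 4, 4, 4)))
        with pytest.raises(ValueError, match="2 groups"):
            group_difference_tmap(vols, ["HC"] * 4)
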