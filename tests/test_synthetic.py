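"""Tests for the synthetic cohort / transcript / brain-volume generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lingvbm.cohort_stats import partial_r
from lingvbm.ngram import loocv_perplexity, scores_to_frame
from lingvbm.synthetic import (
    BrainSimConfig,
    CohortConfig,
    LanguageProfile,
    RoiSpec,
    default_profiles,
    simulate_brain_volumes,
    simulate_cohort_table,
    simulate_transcripts,
)
from lingvbm.volume_io import compute_tiv


class TestCohortTable:
    def test_default_sizes_and_groups(self, cohort_table):
        assert len(cohort_table) == 38
        assert (cohort_table["group"] == "HC").sum() == 26
        assert (cohort_table["group"] == "MCI").sum() == 12
        assert cohort_table["participant_id"].is_unique

    def test_same_seed_identical_tables(self):
        cfg = CohortConfig(seed=7)
        t1 = simulate_cohort_table(cfg)
        t2 = simulate_cohort_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_sd_collapses_to_mean(self):
        cfg = CohortConfig(seed=0)
        for g in ("HC", "MCI"):
            cfg.group_params[g]["education_years"] = (12.0, 0.0)
        table = simulate_cohort_table(cfg)
        assert (table["education_years"] == 12.0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            CohortConfig(n_hc=1)
        with pytest.raises(ValueError, match="proportion"):
            CohortConfig(sex_male_p={"HC": 1.5, "MCI": 0.4})


class TestTranscripts:
    def test_one_transcript_per_participant(self, cohort_table):
        transcripts = simulate_transcripts(cohort_table, seed=1)
        assert len(transcripts) == len(cohort_table)
        profile = default_profiles()["HC"]
        lo, hi = profile.length_range
        assert all(lo <= len(t.tokens) <= hi for t in transcripts)

    def test_high_repetition_small_vocabulary_dominated_by_repeats(self, cohort_table):
        prof = LanguageProfile(
            vocabulary_size=2, repetition_rate=0.95, repetition_jitter=0.0,
            length_range=(200, 200),
        )
        transcripts = simulate_transcripts(
            cohort_table, {"HC": prof, "MCI": prof}, seed=3
        )
        toks = transcripts[0].tokens
        repeats = sum(a == b for a, b in zip(toks, toks[1:])) / (len(toks) - 1)
        assert repeats > 0.85

    def test_impoverished_profile_lowers_perplexity(self, cohort_table):
        rich = LanguageProfile(vocabulary_size=1500, repetition_rate=0.02,
                               repetition_jitter=0.0, length_range=(300, 400))
        poor = LanguageProfile(vocabulary_size=150, repetition_rate=0.3,
                               repetition_jitter=0.0, length_range=(300, 400),
                               zipf_exponent=1.2)
        transcripts = simulate_transcripts(
            cohort_table, {"HC": rich, "MCI": poor}, seed=4
        )
        scores = scores_to_frame(loocv_perplexity(transcripts))
        hc = scores["pp_1g"][(cohort_table["group"] == "HC").values]
        mci = scores["pp_1g"][(cohort_table["group"] == "MCI").values]
        assert mci.mean() < hc.mean()

    def test_identical_profiles_statistically_indistinguishable(self):
        # under the null (same profile for both groups) the pooled group
        # perplexity distributions should not differ (t-test p > 0.01)
        prof = LanguageProfile(vocabulary_size=300, length_range=(100, 150),
                               repetition_jitter=0.0)
        hc_all, mci_all = [], []
        for rep in range(20):
            cfg = CohortConfig(n_hc=8, n_mci=8, seed=rep)
            table = simulate_cohort_table(cfg)
            transcripts = simulate_transcripts(table, {"HC": prof, "MCI": prof},
                                               seed=1000 + rep)
            scores = scores_to_frame(loocv_perplexity(transcripts))
            hc_all.extend(scores["pp_1g"][(table["group"] == "HC").values])
            mci_all.extend(scores["pp_1g"][(table["group"] == "MCI").values])
        assert stats.ttest_ind(hc_all, mci_all).pvalue > 0.01

    def test_errors(self, cohort_table):
        with pytest.raises(ValueError, match="empty"):
            simulate_transcripts(cohort_table.iloc[:0], seed=0)
        with pytest.raises(ValueError, match="vocabulary_size"):
            LanguageProfile(vocabulary_size=1)
        with pytest.raises(ValueError, match="profile"):
            simulate_transcripts(cohort_table, {"HC": LanguageProfile()}, seed=0)


def make_scores(table, rng):
    return pd.DataFrame(
        {
            "participant_id": table["participant_id"],
            "pp_1g": rng.normal(200, 30, len(table)),
            "pp_2g": rng.normal(115, 20, len(table)),
        }
    )


class TestBrainVolumes:
    def test_determinism(self, cohort_table, rng):
        scores = make_scores(cohort_table, rng)
        cfg = BrainSimConfig()
        v1, a1, _ = simulate_brain_volumes(cohort_table, scores, cfg, seed=5)
        v2, a2, _ = simulate_brain_volumes(cohort_table, scores, cfg, seed=5)
        np.testing.assert_array_equal(a1.data, a2.data)
        for x, y in zip(v1, v2):
            np.testing.assert_array_equal(x.data, y.data)

    def test_geometry_defaults(self, cohort_table, rng):
        vols, atlas, _ = simulate_brain_volumes(
            cohort_table, make_scores(cohort_table, rng), BrainSimConfig(), seed=0
        )
        assert vols[0].shape == (32, 32, 24)
        np.testing.assert_allclose(np.diag(vols[0].affine)[:3], (0.98, 0.98, 1.8))

    def test_overlapping_rois_rejected(self, cohort_table, rng):
        cfg = BrainSimConfig(
            roi_specs=(
                RoiSpec(1, "a", "pp_1g", 0.5, (14, 16, 12)),
                RoiSpec(2, "b", "pp_1g", 0.5, (16, 16, 12)),
            )
        )
        with pytest.raises(ValueError, match="overlaps"):
            simulate_brain_volumes(cohort_table, make_scores(cohort_table, rng), cfg, seed=0)

    def test_extreme_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            RoiSpec(1, "a", "pp_1g", 1.0, (9, 16, 12))

    def test_strong_effect_low_noise_high_correlation(self, cohort_table, rng):
        scores = make_scores(cohort_table, rng)
        cfg = BrainSimConfig(
            roi_specs=(RoiSpec(1, "a", "pp_1g", 0.9, (9, 16, 12)),),
            noise_sd=1e-4,
            sex_effect=0.0,
            education_effect=0.0,
            global_effect=0.0,
        )
        vols, atlas, _ = simulate_brain_volumes(cohort_table, scores, cfg, seed=2)
        box = atlas.data == 1
        # the atlas region encloses the painted box; use the box core
        spec = cfg.roi_specs[0]
        core = np.zeros(cfg.shape, bool)
        core[spec.box(cfg.shape)] = True
        means = [v.data[core].mean() for v in vols]
        assert np.corrcoef(means, scores["pp_1g"])[0, 1] > 0.8

    def test_planted_partial_correlation_near_target(self, cohort_table):
        # averaged over seeds, the partial correlation given the constructed
        # covariates should sit within 0.15 of the target rho
        rng = np.random.default_rng(0)
        vals = []
        for seed in range(8):
            scores = make_scores(cohort_table, rng)
            cfg = BrainSimConfig()
            vols, atlas, _ = simulate_brain_volumes(
                cohort_table, scores, cfg, seed=1000 + seed
            )
            spec = cfg.roi_specs[0]
            core = np.zeros(cfg.shape, bool)
            core[spec.box(cfg.shape)] = True
            means = np.array([v.data[core].mean() for v in vols])
            tiv = np.array([compute_tiv([v]) for v in vols])
            cov = np.vstack(
                [cohort_table["sex"], cohort_table["education_years"], tiv]
            )
            vals.append(partial_r(scores["pp_1g"], means, cov).statistic)
        assert abs(np.mean(vals) - 0.6) < 0.15

    def test_atlas_labels_whole_brain(self, cohort_table, rng):
        vols, atlas, label_map = simulate_brain_volumes(
            cohort_table, make_scores(cohort_table, rng), BrainSimConfig(), seed=0
        )
        labels = np.unique(atlas.data[atlas.data > 0]).astype(int)
        assert set(labels) <= set(label_map)
        # brain voxels are labelled, background is 0
        brain = vols[0].data != 0
        assert (atlas.data[brain] > 0).mean() > 0.99

    def test_unjoinable_scores_rejected(self, cohort_table, rng):
        scores = make_scores(cohort_table, rng).iloc[:10]
        with pytest.raises(ValueError, match="joinable"):
            simulate_brain_volumes(cohort_table, scores, BrainSimConfig(), seed=0)

    def test_null_pvalues_uniform(self):
        # no planted effects: downstream voxel-wise one-sided p-values are
        # uniform on (0, 1) (pooled KS test over seeds)
        from lingvbm.validation import null_pvalue_uniformity

        assert null_pvalue_uniformity(seed=17, n_seeds=5) > 0.01

    def test_tiv_positive(self, cohort_table, rng):
        vols, _, _ = simulate_brain_volumes(
            cohort_table, make_scores(cohort_table, rng), BrainSimConfig(), seed=0
        )
        assert all(compute_tiv([v]) > 0 for v in vols)
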