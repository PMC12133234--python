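"""Published cohort summary statistics used as simulation targets.

These are the per-group means and standard deviations reported for an
elderly two-group interview/MRI cohort (26 cognitively healthy participants,
12 with mild cognitive impairment) whose speech was scored with 1-g and 2-g
cross-validated perplexity.  They serve two roles here: as the default
distribution parameters of the synthetic cohort generator, and as inputs to
summary-statistic t-tests (means/SDs/ns are sufficient statistics for the
pooled two-sample t).

Units: age and education in years, trail-making tests in seconds, logical
memory in points, perplexity dimensionless.  The logical-memory rows have
reduced N (one and two missing cases); the missing cases are assigned to
the healthy group, the only split consistent with the reported degrees of
freedom.
"""

from __future__ import annotations

from .cohort_stats import GroupSummary

N_HC = 26
N_MCI = 12

#: variable -> (healthy-control summary, MCI summary)
GROUP_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "age": (GroupSummary(73.85, 0.97, 26), GroupSummary(74.08, 0.90, 12)),
    "education_years": (GroupSummary(13.00, 3.43, 26), GroupSummary(10.17, 1.47, 12)),
    "mmse": (GroupSummary(28.96, 1.18, 26), GroupSummary(28.50, 1.09, 12)),
    "tmt_a": (GroupSummary(32.49, 7.83, 26), GroupSummary(41.24, 12.41, 12)),
    "tmt_b": (GroupSummary(83.98, 24.15, 26), GroupSummary(123.38, 46.90, 12)),
    "lm_immediate": (GroupSummary(25.56, 5.40, 25), GroupSummary(16.67, 4.70, 12)),
    "lm_delayed": (GroupSummary(21.46, 5.23, 24), GroupSummary(11.50, 2.71, 12)),
    "pp_1g": (GroupSummary(202.01, 32.28, 26), GroupSummary(188.93, 19.92, 12)),
    "pp_2g": (GroupSummary(117.59, 23.56, 26), GroupSummary(107.67, 14.80, 12)),
}

#: (male, female) counts per group
SEX_COUNTS = {"HC": (12, 14), "MCI": (5, 7)}

#: number of between-group tests in the demographic/cognitive table
N_TABLE1_TESTS = 10

#: reported correlation between the two perplexity measures
R_PP1G_PP2G = 0.841
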