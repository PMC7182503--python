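"""Run the full analysis pipeline, including outlier correction and flags.

Uses a study with one grossly pleiotropic instrument (direct effect of 10
outcome-SEs) and a binary outcome, so the run exercises PRESSO outlier
removal, re-estimation, odds-ratio conversion and the reporting rules.
"""

import dataclasses

from summr import (
    AnalysisConfig,
    InstrumentSet,
    run_analysis,
    scenario,
    simulate_two_sample,
)

cfg = dataclasses.replace(scenario("single_outlier", seed=3), binary_outcome=True)
study = simulate_two_sample(cfg)
instruments = InstrumentSet(snp_ids=study.exposure.snp_ids)

report = run_analysis(
    study.exposure, study.outcome, instruments,
    AnalysisConfig(seed=3, n_comparisons=20),
)

print("PRESSO global p:", round(report.presso.global_pval, 4),
      "| outliers:", report.presso.outlier_ids)
print("heterogeneity Q raw -> corrected:",
      round(report.heterogeneity_raw.Q, 1), "->",
      round(report.heterogeneity_corrected.Q, 1))

ivw_est = report.estimates_reported.ivw
print(f"outlier-corrected IVW: OR={ivw_est.odds_ratio:.3f} "
      f"[{ivw_est.or_ci_low:.3f}, {ivw_est.or_ci_high:.3f}] p={ivw_est.pval:.3g}")
print("flags:", report.flags)
# The planted outlier is detected and removed, and the corrected estimates
# recover the true log-OR of 0.2 (OR ~ 1.22).  Note the honest bookkeeping:
# no_horizontal_pleiotropy stays False because the global test is computed
# on the raw instrument set, where the pleiotropic SNP really was present;
# the corrected Q shows the heterogeneity it caused is resolved.
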