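"""Bidirectional analysis: distinguish cause from consequence.

Simulates a study where trait B causes trait A, then runs the analysis in
both directions.  Instruments for the downstream trait are really the
causal trait's instruments seen through the causal effect, so the naive
reverse regression can look "significant" — the Steiger directionality
test is what separates the two directions.
"""

from summr import AnalysisConfig, run_bidirectional, scenario, simulate_two_sample

study = simulate_two_sample(scenario("reverse_causal", seed=5))
print("true direction:", study.truth["true_direction"])

ab, ba = run_bidirectional(
    study.exposure, study.outcome, config=AnalysisConfig(seed=5)
)

for label, rep in [("A -> B", ab), ("B -> A", ba)]:
    if not rep.estimable:
        print(f"{label}: not estimable ({rep.reason})")
        continue
    est = rep.estimates_reported.ivw
    print(f"{label}: IVW beta={est.theta:+.3f} p={est.pval:.3g} | "
          f"ivw_significant={rep.flags['ivw_significant']} "
          f"direction_supported={rep.flags['direction_supported']}")
# Only the true direction (B -> A) ends up with both a significant IVW
# estimate and Steiger support.
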