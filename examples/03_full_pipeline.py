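"""End-to-end drug-utilisation analysis on a simulated cohort.

Simulates 500 patients, builds the AF/DOAC cohort, and computes the full
measurement suite — discontinuation and cessation rates under 28- and
56-day admissible gaps, anniversary-method persistence, adherence
medians — plus Kaplan-Meier time to discontinuation and the pathway flow
of discontinuers.
"""

from oacdur import GeneratorConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    generator=GeneratorConfig(n_patients=500, seed=7),
    sensitivity_gaps=(28, 56),
    seed=7,
)
bundle = run_pipeline(config)

m = bundle.measures
overall = m[(m["scope"] == "any_DOAC") & (m["drug"] == "all") & (m["window"] == "overall")]
print(
    overall[
        ["measure", "gap_days", "n", "value", "iqr_lower", "iqr_upper",
         "proportion_above_threshold"]
    ].to_string(index=False)
)
print()
print("KM median time to discontinuation (days), per index drug:")
print(
    bundle.survival[bundle.survival["scope"] == "any_DOAC"][
        ["drug", "n", "n_events", "median_days", "median_ci_lower", "median_ci_upper"]
    ].to_string(index=False)
)
print()
print("what discontinuers did next:")
print(
    bundle.pathway_flow[bundle.pathway_flow["scope"] == "any_DOAC"][
        ["pathway", "n", "percent"]
    ].to_string(index=False)
)
# Note how the discontinuation rate falls when the admissible gap is
# widened from 28 to 56 days, while cessation (which tolerates
# reinitiation) barely moves — short treatment interruptions, not
# permanent stops, drive most refill gaps.
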