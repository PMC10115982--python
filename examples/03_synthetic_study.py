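"""A full simulated contouring study: two arms, 19 cases, report tables.

One arm is generated with small perturbations of the gold standard (a
well-revised model output), the other with larger inter-observer-scale
perturbations (a manual workflow).  The report's paired statistics should
recover that ordering, and the timing analysis the configured ~76% savings.
"""

from oareval import (
    ArmModel,
    PhantomSpec,
    TimingModel,
    compare_structure_sets,
    generate_cohort,
    results_to_dataframe,
    study_report,
)

arms = {
    "DL+RO": ArmModel(translation_sd_mm=0.5, dilation_sd_mm=0.3,
                      noise_amp_mm=0.6, absence_p=0.01),
    "MDA+RO": ArmModel(translation_sd_mm=1.2, dilation_sd_mm=0.8,
                       noise_amp_mm=1.5, absence_p=0.04),
}
cohort = generate_cohort(
    n_cases=19,
    phantom=PhantomSpec.default(n_structures=8, shape=(48, 48, 24)),
    arms=arms,
    timing=TimingModel(savings_mean_pct=76.0, savings_sd_pct=12.0),
    seed=7,
)

rows = []
for case in cohort.cases:
    for arm_set in case.arms.values():
        rows.extend(compare_structure_sets(arm_set, case.gs))
table = results_to_dataframe(rows)
rep = study_report(metric_table=table, timing_table=cohort.timing)

print("pooled per-arm means (95% CI), case x structure pairing")
sel = rep.pooled[rep.pooled.metric.isin(["VDSC", "HD95", "SDSC-1mm", "APL-1mm"])]
print(sel.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\npaired tests between arms")
tests = rep.pooled_tests[rep.pooled_tests.metric.isin(["VDSC", "HD95"])]
print(tests.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

print("\ntiming summary (hours; last row = relative savings %)")
print(rep.timing.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

print(f"\nhypothesis tests performed (no multiplicity correction): {rep.n_tests}")
print("The arm built with smaller perturbations should win the significant"
      " comparisons, and the savings row should sit near the configured 76%.")
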