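"""Generate a synthetic primary-care cohort and write it to CSV.

The generator emulates the structure a risk-assessment cohort needs for
prediction-under-intervention work: calibrated risk-factor marginals,
covariate-dependent return-to-follow-up, confounded treatment uptake, and
proportional-hazards CVD outcomes with a known true intervention effect.
"""

from counterrisk import GeneratorConfig, generate_cohort, write_cohort

config = GeneratorConfig(n_participants=20_000, seed=1)
baseline, followups, truth = generate_cohort(config)
write_cohort(baseline, followups, "scratch_example_cohort")

print(f"participants: {len(baseline)}")
print(f"current smokers: {(baseline.smoking == 'current').mean():.1%}")
print(f"five-year CVD incidence: "
      f"{((baseline.event_type == 'cvd') & (baseline.event_time <= 60)).mean():.1%}")
print(f"returned for follow-up within 2 years: "
      f"{baseline.id.isin(followups.id).mean():.1%}")
print(f"embedded true 5-year RR of quitting (scenario {truth['scenario']}): "
      f"{truth['true_rr']} (hazard ratio {truth['hazard_ratio']:.3f})")
# The marginals match the emulated cohort; the hazard ratio is the step
# change applied from the first follow-up visit for adopters.
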