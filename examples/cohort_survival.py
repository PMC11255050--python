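"""Simulate an ablation cohort and run the full outcome analysis.

The generator draws AF type, fat dispersion (location differs by AF type),
covariates, and 1-year recurrence with a 90-day blanking period. The
analysis re-derives endpoints, dichotomizes dispersion at the cohort mean,
and produces Kaplan-Meier event rates and Cox hazard ratios.
"""

from eatkit import CohortSpec, RunConfig, generate_cohort, run_cohort

cohort = generate_cohort(CohortSpec(n=208, seed=5))
tables = run_cohort(RunConfig(), cohort)

rates = tables["km_event_rates"]
print("1-year Kaplan-Meier event rates by stratum:")
combo = rates[rates["grouping"] == "af_type_x_dispersion"]
for _, row in combo.sort_values("group").iterrows():
    print(f"  {row['group']:22s} {row['event_rate_365_pct']:5.1f} %")

print("\nmultivariable Cox model (HR, 95% CI, p):")
for _, row in tables["cox_multivariable"].iterrows():
    print(f"  {row['term']:28s} {row['hr']:4.2f} "
          f"({row['ci_low']:4.2f}-{row['ci_high']:4.2f})  p={row['p']:.3f}")
# At n = 208 the stratum rates scatter a few points around the generator's
# 22/37/35/71% truth; the dispersion indicator should carry a hazard ratio
# well above 1 after adjustment for AF type and the other covariates.
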