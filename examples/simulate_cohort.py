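"""Generate a synthetic surgical cohort and look at what it contains.

Prints the patient table head, the class mix, and the trace cadence: each
patient carries SAP/DAP/MAP cuff readings every ~3 minutes with artifacts
and gaps injected on top of a mean-reverting pressure process.
"""

from apclust import SimConfig, generate_cohort

cfg = SimConfig(n_patients=200, seed=7, effect_coefs={"DropPP": 0.5})
cohort = generate_cohort(cfg)

print(cohort.patients.head().to_string())
print("\nclass mix:")
print(cohort.patients["surgery_class"].value_counts(normalize=True).round(3).to_string())
print(f"\ntrace records: {len(cohort.traces)} "
      f"({len(cohort.traces) / (3 * len(cohort.patients)):.0f} readings per signal per patient)")
print(f"median LOS: {cohort.patients['los_days'].median():.0f} days "
      "(days from surgery to discharge; the outcome below is a stay beyond "
      "the subgroup median)")
print(f"planted log-odds per SD: {cohort.truth['effect_coefs']}")
print(f"artifacts injected: {len(cohort.truth['artifacts'])}, "
      f"gaps: {len(cohort.truth['gaps'])}")
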