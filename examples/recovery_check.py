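"""Does the pipeline find exactly the planted variables?

Replicates the full pipeline on seeded cohorts whose prolonged-stay risk is
driven by three known features in different correlation blocks, then counts
how often the final independent set equals those three names and how close
the refit log-odds are to the planted values.
"""

from apclust.experiments import recovery_experiment
from apclust.simulate import RECOVERY_EFFECTS

df = recovery_experiment(n_replicates=3, n_patients=1000, seed=1)
print(df[["seed", "chosen_k", "exact_recovery", "final"]].to_string(index=False))
print(f"\nexact recovery rate: {df['exact_recovery'].mean():.0%}")
for f, beta in RECOVERY_EFFECTS.items():
    est = df[f"coef_{f}"].mean()
    print(f"{f}: planted {beta:+.2f} log-odds/SD, mean refit estimate {est:+.2f}")
print("\n(increase n_replicates / n_patients for a sharper estimate; the "
      "acceptance script runs 10 replicates at n=2000)")
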