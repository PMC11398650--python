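# apclust

Clustering-based selection of intraoperative arterial-pressure variables
that explain prolonged postoperative length of stay (pLOS).

## The problem

Intraoperative hypotension is linked to postoperative complications, but
there are dozens of candidate blood-pressure summaries — minimum MAP,
pulse-pressure swings, cumulative time below any threshold — and they are
heavily collinear, which breaks naive multivariable regression and makes
LASSO-style selection arbitrary among near-duplicates. `apclust` implements
a cluster-then-select pipeline for this setting:

1. **Trace cleaning** — raw cuff SAP/DAP/MAP readings are paired through a
   Cantor key π(t, id) = (t+id)(t+id+1)/2 + id, artifacts removed with a
   global Hampel rule (|x − median| > 5·MAD), traces with interior gaps
   > 10 min rejected (leading/trailing gaps exempt), missing values imputed
   with a 40 %-span loess, and every channel resampled to a 30-s grid with
   shape-preserving pchip interpolation. PP = SAP − DAP.
2. **Feature family** — per signal s ∈ {MAP, SAP, DAP, PP}: Min, Max, Mean,
   Median, Std, Var = Std/Mean, Drop = Max − Min, plus CumTime s<θ and
   CumTime s>θ for every integer θ between the cohort P5 and P85 of s.
3. **Outcome** — pLOS = 1 iff LOS (days to discharge) strictly exceeds the
   median (or P75/P90) of the patient's subgroup — surgery class × intra-class
   duration quartile (7 × 4 = 28 subgroups); when a subgroup's median equals
   its Q3 the cut becomes median + 1; deaths count as prolonged.
4. **Variable clustering** — Ward linkage on the dissimilarity 1 − |τ_b|
   from the pairwise tie-corrected Kendall correlation of the variables.
5. **Representatives** — within each cluster, variables are ranked by the
   absolute standardized mean difference aSMD = |μ₁ − μ₀| / σ₁ (σ₁ = SD of
   the pLOS group), with 1000-draw bootstrap CIs; the top variable represents
   the cluster.
6. **Model selection** — for k = 1..10 the k representatives enter a
   logistic model of pLOS; the penalized criterion
   mBIC = k ln N − 2 ln L + (#{p ≥ 0.05}) ln N picks k; predictors with
   p ≥ 0.05 are then dropped (independence filter) and the reduced model is
   refitted to report per-SD odds ratios.

A seeded synthetic-cohort generator (`apclust.simulate`) produces cuff-cadence
traces from mean-reverting pressure processes, with artifacts, gaps,
class-specific durations, negative-binomial LOS and *planted* logistic
feature effects, so the whole pipeline is testable without clinical data.

## Worked example

```bash
python examples/full_selection.py
```

runs the full pipeline on 500 synthetic patients with three planted
effects (MinDAP −0.60, DropPP +0.55, MaxPP +0.45 log-odds per SD) and
prints:

```
per-k model scan (mBIC = k ln N - 2 ln L + n_insignificant ln N):
 k     llf    bic  n_insig   mbic
 1 -265.69 537.48        0 537.48
 2 -261.44 535.10        0 535.10
 3 -259.94 538.20        2 550.42
 ...
chosen k = 2 (smallest mBIC)
final independent set (p < 0.05): ['MaxPP', 'MinDAP']

feature  coef_per_sd  or_per_sd  or_lo  or_hi  p_value
  MaxPP        0.339      1.403  1.113  1.769    0.004
 MinDAP       -0.530      0.589  0.464  0.747    0.000
```

Each extra cluster costs ln N plus another ln N for every insignificant
predictor, so k stops growing as soon as new clusters stop adding
significant signal. At n = 500 the pipeline finds two of the three planted
variables with per-SD odds ratios close to exp of the planted log-odds
(e.g. exp(−0.60) = 0.55 vs the fitted 0.59 for MinDAP); at n = 2000 it
recovers all three in ≈90 % of replicates (`examples/recovery_check.py`,
scaled down to 3 replicates, shows the machinery).

Other entry points: `examples/simulate_cohort.py`,
`examples/clean_and_featurise.py`, and the `apclust` CLI
(`simulate | preprocess | features | outcomes | cluster | rank | select | run-all`)
for shell-driven runs on CSV inputs.

## Layout

- `src/apclust/` — `simulate`, `preprocess`, `features`, `outcomes`,
  `clustering`, `ranking`, `inference`, `pipeline`, `experiments`,
  `benchmark`, `cli`
- `docs/methods.md` — model, assumptions, parameter choices, limitations
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and acceptance suites
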