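# Methods

## The selection pipeline

The package identifies which intraoperative arterial-pressure variables are
independently associated with a prolonged postoperative stay when the
candidate pool is large and highly collinear. Rather than regularized
regression — which picks arbitrarily among near-duplicate predictors — it
clusters the *variables* by rank correlation, keeps one representative per
cluster, and lets a penalized information criterion decide how many
clusters are worth keeping.

### Trace cleaning

Raw input is a long table of timestamped cuff readings (patient id, integer
seconds from intervention start, signal ∈ {SAP, DAP, MAP}, mmHg). Steps,
in order:

1. **Pairing.** SAP and DAP records are joined on a Cantor pairing key
   π(t, id); pulse pressure PP = SAP − DAP exists where both channels share
   a timestamp. The Cantor key requires non-negative integers, hence the
   integer-second time coding.
2. **Hampel artifact rule.** For each patient-signal series (including the
   paired PP series), x is flagged missing iff |x − median| > 5·MAD, with
   median and MAD computed *globally* over the series — not in a sliding
   window, and not pooled across patients, which would mix set-points. MAD
   is unscaled (no 1.4826 normality constant); both choices are config
   switches (`PreprocessConfig.mad_constant`, `mad_threshold`). The fence
   is strict: a value exactly at 5 MAD survives. Flags raised on PP
   propagate to the SAP and DAP points that produced them, which keeps the
   grid identity pp = sap − dap exact.
3. **Gap rule.** After flagging (flagged points count as missing), a trace
   is rejected when two consecutive surviving measurements are more than 10
   minutes apart; gaps before the first or after the last surviving
   measurement are exempt.
4. **Imputation.** Interior missing values are filled by a loess fit
   (tricube weights, local linear, 40 % span, no robustifying iterations —
   artifacts are already gone) evaluated at the missing timestamps. On
   short series the smoothing window is floored at 4 points: a 40 % span of
   fewer than ~10 points can leave a single non-zero weight, which defines
   no local line. If a window is still degenerate the point falls back to
   linear interpolation between neighbours.
5. **Resampling.** Each channel is interpolated onto a uniform 30-s grid
   spanning the overlap of the three channels with a piecewise cubic
   Hermite polynomial (pchip): it passes through the knots, preserves
   monotonicity and never overshoots local extrema. PP on the grid is
   recomputed as SAP − DAP.

Exclusion reasons (`GAP_GT_10MIN`, `TOO_FEW_POINTS`, `ALL_MISSING`) are
logged per patient.

### Feature family

Per signal: Min, Max, Mean, Median, Std (sample, n−1), Var = Std/Mean
(coefficient of variation) and Drop = Max − Min over the whole intervention
(28 summary features), plus cumulative-time features at every integer mmHg
threshold θ between the cohort-pooled 5th and 85th percentiles of that
signal (linear-interpolation percentile rule). "Below" counts samples
strictly < θ; equality goes to "above", so below + above equals the total
intervention time exactly. Both minutes and fraction-of-intervention forms
exist; the fraction form is the default matrix because durations differ
across patients. Thresholds use the pooled cohort distribution (not
per-patient) so a column means the same thing for everyone.
Area-below-threshold (∫ max(θ − v, 0) dt) is computed on request but
excluded from the default matrix: it is nearly redundant with cumulative
time and only adds interpretation noise.

### Outcome

pLOS is subgroup-relative: within each of the 7 surgery classes, patients
are split at the intra-class duration quartiles (ties collapse toward
quartile 1), giving up to 28 subgroups; the label is 1 iff LOS strictly
exceeds the subgroup's median (main definition) or P75/P90 (secondary).
Under the median definition, when median = Q3 — tightly clustered LOS —
the cut is raised by one day, which caps the labelled fraction at one half.
Deaths are always labelled prolonged. The same percentile rule is used as
everywhere else.

### Clustering, ranking, selection

- **Similarity**: |τ_b| (tie-corrected Kendall) per variable pair, computed
  with a numba-compiled O(n log n) merge-sort algorithm (Knight's method);
  the test suite checks every entry against a brute-force O(n²)
  concordance count. Constant columns get similarity 0 and are excluded
  from clustering with a warning.
- **Dendrogram**: Ward linkage (scipy, Lance–Williams update on the
  precomputed condensed distances) on d = 1 − |τ| (√(1−|τ|) available).
  The tree is cut at any k; cluster ids are renumbered by smallest member
  index so assignments are stable.
- **aSMD**: |μ₁ − μ₀| / σ₁ with σ₁ the sample SD of the outcome-positive
  group (pooled-SD variant available). A constant feature has aSMD 0; a
  zero-σ₁ feature with non-zero mean difference raises an explicit
  degenerate-result error rather than returning infinity. CIs come from a
  seeded patient-level percentile bootstrap (1000 draws by default,
  stratification optional); replicates with an unusable resample are
  redrawn and >10 % failures abort. Ties in the within-cluster ranking
  break by feature name — note the below/above forms of the same threshold
  are exact complements with identical aSMD, so the below form wins such
  ties deterministically.
- **mBIC**: k ln N − 2 ln L + n_insig ln N, with k the *cluster count* (not
  the parameter count — a config switch offers the textbook variant) and
  n_insig the number of Wald p ≥ 0.05 in the k-representative logistic
  model on column-standardized predictors. k* minimizes mBIC over 1..10,
  ties to the smaller k; fits that fail (separation, non-convergence) are
  skipped with a warning and excluded from the argmin. After choosing k*,
  predictors with p ≥ 0.05 are dropped and the model refitted once on the
  retained set — the reported odds ratios come from that reduced refit,
  which is the cleaner of the two defensible conventions. Clinical
  covariates are deliberately absent from every model.
- **Reporting**: per-SD odds ratios exp(β) with Wald 95 % intervals.
  `apply_coding` implements threshold-style recodings for odds-ratio
  presentation (dichotomize a cumulative time at 50 minutes; floor a drop
  at 25 mmHg and scale per SD). `descriptive_tables` mirrors the standard
  characteristics table: median [IQR] + Mann–Whitney for continuous
  covariates, counts + Fisher (2×2) or chi-square (R×C) for categorical.

## The synthetic cohort generator

The generator emulates a mixed non-cardiac surgical registry with
non-invasive monitoring. Defaults (all in `SimConfig`):

- **Class mix** 20.8/13.7/13.6/21.5/10.7/15.3/4.5 % across digestive,
  thoracic, gynecological, neurosurgical, ENT, urological, vascular;
  class-specific lognormal durations (medians 70–150 min), floored at
  21 min so every generated patient clears the 20-min eligibility rule.
- **Hemodynamics**: per-patient MAP set-point N(84, 8) mmHg; latent MAP
  follows a mean-reverting (Ornstein–Uhlenbeck) diffusion, θ = 0.10 /min,
  σ = 4 mmHg/√min (stationary SD ≈ 8.9 mmHg); PP set-point N(48, 11)
  floored at 15, its own slower process (θ = 0.05, σ = 3.0). The channels
  satisfy DAP = MAP − PP/3, SAP = DAP + PP (the standard estimation
  identity), so SAP > MAP > DAP at every uncorrupted sample. Sampling at a
  jittered cuff cadence (180 s ± 25 %), rounded to integer seconds. A
  mean-reverting diffusion was chosen because nothing in the problem fixes
  a signal model; its parameters are exposed so tests can set variance
  regimes.
- **Corruption last**: Poisson(2) artifacts per trace, ±55 mmHg-scale
  offsets at logged positions; Poisson(0.3) gaps with lognormal length
  (median 4 min), so most gaps pass the 10-min rule and a minority
  exercises the exclusion path.
- **Outcome**: a latent prolonged-stay indicator is drawn from the logistic
  model p = expit(α + Σ β_j z_j), where z_j are the planted features
  computed on the patient's own clean samples and standardized across the
  cohort, β_j the `effect_coefs` (log-odds per SD), and α calibrated by
  root-finding so the marginal rate equals `base_plos_rate` (default 0.34).
  LOS is then drawn from negative-binomial count mixtures placed below or
  at (non-prolonged) versus strictly above (prolonged) a class-specific cut
  (2–5 days, marginal median 3): the non-prolonged component is clipped at
  the cut with enough mass *at* the cut that the realized subgroup median
  lands there with high probability. At n = 2000 the downstream
  subgroup-median labels agree with the latent indicator for ≈99.8 % of
  patients, which makes the planted logistic model an exact population
  oracle for effect-size checks (`population_asmd` integrates it over the
  realized draws). Deaths (1 %) are independent label overrides.
- **Truth ledger**: planted coefficients, standardized feature draws,
  event probabilities, latent labels, artifact and gap positions are all
  retained in `SimCohort.truth` so recovery tests never re-derive them.

### What the generator does and does not emulate

It reproduces the *structure* the pipeline must survive — collinear
variable blocks, cuff cadence, artifacts, gaps, subgroup-relative labels
with realistic ties — but the MAP and PP processes are mutually
independent, there is no drug-induced drift, no baseline dependence of
risk, no invasive-line segments and no between-center heterogeneity.
Passing recovery tests therefore shows the *machinery* is correct, not that
any particular clinical association is real.

### The recovery experiment

`RECOVERY_EFFECTS` plants MinDAP (−0.60), DropPP (+0.55) and MaxPP (+0.45)
log-odds per SD. These three were chosen because each is the strongest
single summary of its latent axis (diastolic floor, pulse-pressure spread,
pulse-pressure peak) *given the channel identities*: with SAP and DAP being
deterministic mixtures of the MAP and PP processes, effects planted on
"pure" features (e.g. MinMAP plus a PP-level feature) are aggregated by
composite channels (MinDAP inherits both), which would make exact
name-recovery ill-posed — the pipeline would correctly select the composite
apex instead of the planted name. Planting on the apexes makes "the final
set equals the planted names" a fair test. At n = 2000 the full pipeline
recovers exactly the three names in ≈90 % of replicates and the refit
standardized coefficients sit within 3 SE of the planted values (small
attenuation from cleaning and residual label noise is expected and
observed).

### The null experiment

With all effects zero, the final set should be noise. Because the
per-cluster ranking maximizes aSMD over hundreds of correlated candidates,
a selected variable's effect size must be compared with the permutation
null of the *maximum* aSMD across all candidates (labels reshuffled, 200
draws), not with a single-variable null — the latter is exceeded by the
winner of any selection almost by construction. A replicate passes when
its final set is empty or all members fall below the 97.5th percentile of
that maximum-null. Run at n = 400–500, where label noise from
finite-subgroup medians is visible, ≥ 90 % of replicates pass.

## Numerical choices and problem sizes

- Percentile rule everywhere: numpy linear interpolation between order
  statistics.
- Sample (n−1) SDs throughout.
- Logistic fits: statsmodels Newton MLE on standardized predictors;
  non-convergence and separation surface as explicit errors.
- Determinism: every stochastic step takes a seed or Generator; a pipeline
  run derives all stage seeds from the one root seed. Identical
  (config, seed) reproduce byte-identical cohorts and identical selections.
- Test and reproduction problem sizes: recovery runs 10 replicates at
  n = 2000, the null check 10–20 replicates at n = 400; these sizes give
  stable rates (binomial SE ≤ 0.13 on a 10-replicate proportion) while
  keeping a full run in minutes on one CPU.

## Known limitations

- The Hampel rule is global per series; slow physiological drift inflates
  the MAD and can hide small artifacts (windowed variants were deliberately
  not implemented — the global reading matches the cleaning contract this
  package implements).
- The 330-ish feature count depends on the cohort's pooled P5–P85 spread;
  narrower synthetic cohorts produce smaller grids. Nothing is hard-coded
  to a particular count.
- Below/above threshold features are exact complements; they always
  co-cluster and tie in aSMD. They are both kept for interface fidelity,
  with the deterministic name tie-break documented above.
- The benchmark module compares against published reference values only
  when the user supplies the original deposited data; no download is
  attempted.
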