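# File formats

All tabular artifacts are CSV; configs, manifests and trees are JSON.

## Inputs

- `traces.csv` — long format, one row per measurement:
  `patient_id` (int), `t_seconds` (int, seconds from intervention start),
  `signal` (`SAP` | `DAP` | `MAP`, case-insensitive), `value_mmHg` (float).
- `patients.csv` — one row per patient:
  `id`, `age`, `sex`, `surgery_class` (one of digestive, thoracic,
  gynecological, neurosurgical, ENT, urological, vascular),
  `duration_min`, `los_days` (int ≥ 0), `died` (bool). An optional
  `repeat_anesthesia` bool column triggers the repeat-anesthesia exclusion.

## Pipeline outputs (per run directory)

- `clean/<patient_id>.csv` — `t_seconds,sap,dap,map,pp` on the 30-s grid.
- `trace_exclusions.csv` / `exclusions.csv` — `patient_id,reason` with
  reason codes `GAP_GT_10MIN`, `TOO_FEW_POINTS`, `ALL_MISSING`,
  `OPERATING_TIME_LT_20`, `AGE_LT_18`, `LOS_LT_1`, `NO_USABLE_TRACE`,
  `EXCLUDED_PROCEDURE`, `REPEAT_ANESTHESIA`.
- `features.csv` — wide matrix, `patient_id` index column; columns named
  `MinMAP`, `DropPP`, `CumTimePP>61`, `CumTimeSAP<110`, ... ;
  `features_meta.json` — per column: signal, family, threshold, unit;
  `threshold_grid.json` — integer thresholds per signal.
- `outcomes.csv` — `patient_id,subgroup,plos50,plos75,plos90`;
  `subgroup_cuts.json` — per subgroup, the LOS cut per definition.
- `similarity.csv` — dense labelled |tau| matrix; `dendrogram.json` —
  `labels` (leaf order) + `merges` (scipy linkage rows: left, right,
  height, count); `clusters_k<k>.csv` — flat feature→cluster assignment.
- `effect_sizes.csv` — `feature,cluster,asmd,rank,representative,ci_lo,ci_hi`.
- `selection.json` — per-k trace (k, representatives, llf, bic, n_insig,
  mbic), chosen k, final variables; `odds_ratios.csv` —
  `feature,coef_per_sd,or_per_sd,or_lo,or_hi,p_value`.
- `table1.csv` / `table2.csv` — descriptive group comparisons.
- `manifest.json` — config + hash, per-stage counts and timings, the list
  of every file the run wrote.
- `truth.json` (simulated runs) — the planted log-odds per feature.
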