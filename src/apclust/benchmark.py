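"""Benchmark comparison against a user-supplied clinical deposit.

When the original study's deposited data (long-format trace CSV plus a
patient table) is available locally, this module runs the full pipeline on
it and compares the headline quantities — prolonged-stay fraction, median
LOS, top effect sizes, per-SD odds ratios and the Min MAP group medians —
against reference values supplied by the caller.  Nothing here downloads
anything.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import RunConfig, run_all
from .ranking import asmd

#: headline reference values printed by the original clinical analysis
#: (median-LOS definition); used only for side-by-side reporting.
REFERENCE_VALUES = {
    "plos_fraction": 0.34,
    "median_los_days": 3.0,
    "asmd_drop_pp": 0.39,
    "asmd_cumtime_pp_gt61": 0.21,
    "asmd_min_map": 0.20,
    "or_drop_pp_per_sd": 1.29,
    "min_map_median_non_plos": 64.0,
    "min_map_median_plos": 62.0,
}


def benchmark_report(deposit_dir: str | Path, out_dir: str | Path,
                     reference: dict | None = None) -> pd.DataFrame:
    """Run the pipeline on a deposited cohort and tabulate observed vs reference.

    ``deposit_dir`` must contain ``traces.csv`` (patient_id, t_seconds,
    signal, value_mmHg) and ``patients.csv`` (id, age, sex, surgery_class,
    duration_min, los_days, died).
    """
    deposit = Path(deposit_dir)
    ref = dict(REFERENCE_VALUES, **(reference or {}))
    cfg = RunConfig(out_dir=str(out_dir), simulate=False,
                    traces_csv=str(deposit / "traces.csv"),
                    patients_csv=str(deposit / "patients.csv"))
    manifest = run_all(cfg)

    out = Path(out_dir)
    outcomes = pd.read_csv(out / "outcomes.csv", index_col=0)
    feats = pd.read_csv(out / "features.csv", index_col=0)
    patients = pd.read_csv(out / "patients.csv")
    y = outcomes.loc[feats.index, "plos50"].to_numpy()
    los = patients.set_index("id").loc[feats.index, "los_days"]

    observed = {
        "plos_fraction": float(np.mean(y)),
        "median_los_days": float(np.median(los)),
    }
    if "DropPP" in feats:
        observed["asmd_drop_pp"] = asmd(feats["DropPP"].to_numpy(), y)
    if "MinMAP" in feats:
        observed["asmd_min_map"] = asmd(feats["MinMAP"].to_numpy(), y)
        observed["min_map_median_non_plos"] = float(np.median(feats.loc[y == 0, "MinMAP"]))
        observed["min_map_median_plos"] = float(np.median(feats.loc[y == 1, "MinMAP"]))
    if "CumTimePP>61" in feats:
        observed["asmd_cumtime_pp_gt61"] = asmd(feats["CumTimePP>61"].to_numpy(), y)
    try:
        ors = pd.read_csv(out / "odds_ratios.csv")
    except (FileNotFoundError, pd.errors.EmptyDataError):
        ors = pd.DataFrame()
    if len(ors) and "DropPP" in set(ors.get("feature", [])):
        observed["or_drop_pp_per_sd"] = float(
            ors.loc[ors["feature"] == "DropPP", "or_per_sd"].iloc[0])

    rows = [{"quantity": k, "observed": observed.get(k, np.nan), "reference": v}
            for k, v in ref.items()]
    report = pd.DataFrame(rows)
    report["abs_diff"] = (report["observed"] - report["reference"]).abs()
    report.to_csv(out / "benchmark.csv", index=False)
    with open(out / "benchmark_manifest.json", "w") as fh:
        json.dump({"chosen_k": manifest["selection"]["chosen_k"],
                   "final_variables": manifest["selection"]["final_variables"]}, fh)
    return report
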