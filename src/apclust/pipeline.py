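"""End-to-end orchestration: simulate/load -> clean -> features -> labels ->
cluster -> rank -> select -> report, with persisted artifacts and a manifest.

A run is driven by a single :class:`RunConfig`; every stage's parameters and
the root seed appear in the manifest so a rerun with the same config and
inputs reproduces all numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import kendall_matrix, ward_tree
from .features import assemble_matrix, build_threshold_grid
from .inference import descriptive_tables, select_k
from .outcomes import OutcomeConfig, eligibility_filter, plos_labels
from .preprocess import PreprocessConfig, clean_trace_to_frame, clean_traces
from .ranking import RankingConfig
from .simulate import SimConfig, generate_cohort


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # inputs: either simulate, or point at existing CSVs
    simulate: bool = True
    n_patients: int = 500
    effect_coefs: dict = field(default_factory=dict)
    traces_csv: str | None = None
    patients_csv: str | None = None
    # stage parameters
    gap_minutes: float = 10.0
    grid_seconds: float = 30.0
    loess_span: float = 0.40
    mad_constant: float = 1.0
    percentile_lo: float = 5.0
    percentile_hi: float = 85.0
    definition: str = "median"
    k_min: int = 1
    k_max: int = 10
    alpha: float = 0.05
    bootstrap: int = 1000
    with_ci: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def run_all(config: RunConfig) -> dict:
    """Execute all stages; write artifacts under ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) recording
    the config hash, per-stage record counts, the selection outcome and
    timings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "stages": {},
        "outputs": [],
    }

    def _stage(name):
        t0 = time.perf_counter()
        return lambda **info: manifest["stages"].update(
            {name: {"seconds": round(time.perf_counter() - t0, 3), **info}})

    def _write(df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(out / name, **kw)
        manifest["outputs"].append(name)

    # --- inputs -----------------------------------------------------------
    done = _stage("input")
    if config.simulate:
        sim = SimConfig(n_patients=config.n_patients, seed=config.seed,
                        effect_coefs=dict(config.effect_coefs))
        cohort = generate_cohort(sim)
        patients, traces = cohort.patients, cohort.traces
        with open(out / "truth.json", "w") as fh:
            json.dump({"effect_coefs": cohort.truth["effect_coefs"]}, fh, indent=2)
        manifest["outputs"].append("truth.json")
    else:
        traces = pd.read_csv(config.traces_csv)
        patients = pd.read_csv(config.patients_csv)
    _write(patients, "patients.csv", index=False)
    _write(traces, "traces.csv", index=False)
    done(patients=len(patients), trace_records=len(traces))

    # --- preprocessing ----------------------------------------------------
    done = _stage("preprocess")
    pcfg = PreprocessConfig(gap_minutes=config.gap_minutes,
                            grid_seconds=config.grid_seconds,
                            loess_span=config.loess_span,
                            mad_constant=config.mad_constant)
    clean, excl_log = clean_traces(traces, pcfg)
    clean_dir = out / "clean"
    clean_dir.mkdir(exist_ok=True)
    for pid, tr in clean.items():
        clean_trace_to_frame(tr).to_csv(clean_dir / f"{pid}.csv", index=False)
    _write(excl_log, "trace_exclusions.csv", index=False)
    done(kept=len(clean), excluded=len(excl_log))

    # --- eligibility + outcomes -------------------------------------------
    done = _stage("outcomes")
    ocfg = OutcomeConfig()
    eligible, elig_log = eligibility_filter(patients, set(clean.keys()), ocfg)
    labels = plos_labels(eligible, ocfg)
    _write(elig_log, "exclusions.csv", index=False)
    _write(labels.labels, "outcomes.csv")
    with open(out / "subgroup_cuts.json", "w") as fh:
        json.dump(labels.cuts, fh, indent=2, default=float)
    manifest["outputs"].append("subgroup_cuts.json")
    col = {"median": "plos50", "p75": "plos75", "p90": "plos90"}[config.definition]
    done(eligible=len(eligible), plos_fraction=float(labels.labels[col].mean()))

    # --- features ---------------------------------------------------------
    done = _stage("features")
    traces_elig = {pid: clean[pid] for pid in eligible["id"] if pid in clean}
    grid = build_threshold_grid(traces_elig, config.percentile_lo, config.percentile_hi)
    fmat, meta = assemble_matrix(traces_elig, grid)
    _write(fmat, "features.csv")
    with open(out / "features_meta.json", "w") as fh:
        json.dump(meta.to_dict(orient="index"), fh, default=str)
    manifest["outputs"].append("features_meta.json")
    with open(out / "threshold_grid.json", "w") as fh:
        json.dump({s: [int(t) for t in v] for s, v in grid.thresholds.items()}, fh)
    manifest["outputs"].append("threshold_grid.json")
    done(patients=fmat.shape[0], features=fmat.shape[1])

    # --- clustering + selection -------------------------------------------
    done = _stage("selection")
    y = labels.labels.loc[fmat.index, col].to_numpy()
    S, constant = kendall_matrix(fmat)
    usable = [c for c in fmat.columns if c not in constant]
    tree = ward_tree(S.loc[usable, usable])
    rank_cfg = RankingConfig(bootstrap=config.bootstrap, seed=config.seed)
    result = select_k(tree, usable, fmat, y,
                      k_range=range(config.k_min, config.k_max + 1),
                      alpha=config.alpha, ranking=rank_cfg, with_ci=config.with_ci)
    S.to_csv(out / "similarity.csv")
    manifest["outputs"].append("similarity.csv")
    with open(out / "dendrogram.json", "w") as fh:
        json.dump({"labels": usable, "merges": tree.tolist()}, fh)
    manifest["outputs"].append("dendrogram.json")
    _write(result.effect_sizes, "effect_sizes.csv", index=False)
    _write(result.odds_ratios, "odds_ratios.csv", index=False)
    sel = {
        "trace": result.trace.to_dict(orient="records"),
        "chosen_k": result.chosen_k,
        "representatives": result.representatives,
        "final_variables": result.final_variables,
    }
    with open(out / "selection.json", "w") as fh:
        json.dump(sel, fh, indent=2, default=str)
    manifest["outputs"].append("selection.json")
    done(chosen_k=result.chosen_k, final_variables=result.final_variables)

    # --- descriptive report -----------------------------------------------
    done = _stage("report")
    elig_idx = eligible.set_index("id").loc[fmat.index]
    table1 = descriptive_tables(elig_idx.reset_index(), y)
    _write(table1, "table1.csv", index=False)
    feat_tab = descriptive_tables(
        fmat.reset_index(), y,
        continuous=[c for c in fmat.columns if not c.startswith("CumTime")][:28],
        categorical=[])
    _write(feat_tab, "table2.csv", index=False)
    done()

    manifest["selection"] = sel
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
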