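"""Eligibility, surgery-class x duration-quartile subgroups and pLOS labels.

A patient's stay is *prolonged* (pLOS = 1) when their length of stay is
strictly greater than a percentile cut (median, 75th or 90th) of the LOS
within their subgroup — their surgery class crossed with the intra-class
quartile of intervention duration (7 x 4 = 28 subgroups).  Under the median
definition, when a subgroup's median equals its third quartile the cut is
raised to median + 1 day (tightly clustered distributions would otherwise
label large near-median fractions).  Patients who died in hospital are
labelled prolonged under every definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SURGERY_CLASSES

OPERATING_TIME_LT_20 = "OPERATING_TIME_LT_20"
AGE_LT_18 = "AGE_LT_18"
LOS_LT_1 = "LOS_LT_1"
NO_USABLE_TRACE = "NO_USABLE_TRACE"
EXCLUDED_PROCEDURE = "EXCLUDED_PROCEDURE"
REPEAT_ANESTHESIA = "REPEAT_ANESTHESIA"

DEFINITIONS = {"median": 50.0, "p75": 75.0, "p90": 90.0}


@dataclass
class OutcomeConfig:
    min_age: float = 18.0
    min_duration_min: float = 20.0
    min_los_days: int = 1
    procedure_blocklist: tuple = ()   # e.g. obstetric / transplant / endoscopy labels
    percentile_method: str = "linear"


@dataclass
class OutcomeLabels:
    labels: pd.DataFrame          # patient id index; subgroup, plos50, plos75, plos90
    cuts: dict = field(default_factory=dict)        # subgroup -> {definition: cut}
    quartile_bounds: dict = field(default_factory=dict)  # class -> (q25, q50, q75)


def eligibility_filter(patients: pd.DataFrame, usable_trace_ids: set[int] | None = None,
                       config: OutcomeConfig | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion rules; return eligible patients and an exclusion log.

    Rules: age >= 18, at least one night in hospital, operating time >= 20
    minutes, procedure class not blocklisted, one anesthesia per admission
    (flagged upstream via a ``repeat_anesthesia`` column when present) and a
    usable cleaned trace.
    """
    cfg = config or OutcomeConfig()
    excl = []
    keep_mask = pd.Series(True, index=patients.index)

    def _exclude(mask: pd.Series, reason: str) -> None:
        nonlocal keep_mask
        for pid in patients.loc[mask & keep_mask, "id"]:
            excl.append({"patient_id": int(pid), "reason": reason})
        keep_mask &= ~mask

    if "age" in patients:
        _exclude(patients["age"] < cfg.min_age, AGE_LT_18)
    _exclude(patients["los_days"] < cfg.min_los_days, LOS_LT_1)
    _exclude(patients["duration_min"] < cfg.min_duration_min, OPERATING_TIME_LT_20)
    if cfg.procedure_blocklist:
        _exclude(patients["surgery_class"].isin(cfg.procedure_blocklist), EXCLUDED_PROCEDURE)
    if "repeat_anesthesia" in patients:
        _exclude(patients["repeat_anesthesia"].astype(bool), REPEAT_ANESTHESIA)
    if usable_trace_ids is not None:
        _exclude(~patients["id"].isin(usable_trace_ids), NO_USABLE_TRACE)

    log = pd.DataFrame(excl, columns=["patient_id", "reason"])
    return patients.loc[keep_mask].reset_index(drop=True), log


def assign_subgroups(patients: pd.DataFrame, config: OutcomeConfig | None = None
                     ) -> tuple[pd.Series, dict]:
    """Map each patient to (surgery class, duration quartile 1..4).

    Quartile boundaries (25/50/75th percentiles of duration) are computed
    within each class; a duration d falls in quartile 1 + #(boundaries < d),
    so when all durations tie every patient lands in quartile 1.
    """
    cfg = config or OutcomeConfig()
    sub = pd.Series(index=patients.index, dtype=object)
    bounds = {}
    for cls, grp in patients.groupby("surgery_class"):
        if len(grp) == 0:
            continue
        q = np.percentile(grp["duration_min"], [25, 50, 75], method=cfg.percentile_method)
        bounds[cls] = tuple(float(x) for x in q)
        d = grp["duration_min"].to_numpy()
        quart = 1 + (d[:, None] > q[None, :]).sum(axis=1)
        sub.loc[grp.index] = [f"{cls}:Q{qi}" for qi in quart]
    return sub, bounds


def plos_labels(patients: pd.DataFrame, config: OutcomeConfig | None = None,
                definitions: tuple[str, ...] = ("median", "p75", "p90")) -> OutcomeLabels:
    """Binary prolonged-stay labels under each percentile definition.

    Per subgroup the cut is the chosen LOS percentile; the label is
    ``los_days > cut``; the median definition's cut becomes median + 1 when
    the subgroup median equals its third quartile; deaths override to 1.
    """
    cfg = config or OutcomeConfig()
    subgroups, bounds = assign_subgroups(patients, cfg)
    out = pd.DataFrame(index=patients["id"].to_numpy())
    out.index.name = "patient_id"
    out["subgroup"] = subgroups.to_numpy()
    died = patients["died"].astype(bool).to_numpy() if "died" in patients else np.zeros(len(patients), bool)
    los = patients["los_days"].to_numpy()

    cuts: dict[str, dict[str, float]] = {}
    colname = {"median": "plos50", "p75": "plos75", "p90": "plos90"}
    for definition in definitions:
        pct = DEFINITIONS[definition]
        labels = np.zeros(len(patients), dtype=int)
        for sg in pd.unique(out["subgroup"]):
            mask = (out["subgroup"] == sg).to_numpy()
            if mask.sum() == 0:
                continue
            cut = float(np.percentile(los[mask], pct, method=cfg.percentile_method))
            if definition == "median":
                q3 = float(np.percentile(los[mask], 75, method=cfg.percentile_method))
                if cut == q3:
                    cut = cut + 1.0
            cuts.setdefault(sg, {})[definition] = cut
            labels[mask] = (los[mask] > cut).astype(int)
        labels[died] = 1
        out[colname[definition]] = labels
    return OutcomeLabels(labels=out, cuts=cuts, quartile_bounds=bounds)
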