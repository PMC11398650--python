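"""Candidate arterial-pressure variable family.

For each of the four cleaned signals (MAP, SAP, DAP, PP) the family contains
seven whole-intervention summaries — Min, Max, Mean, Median, Std,
Var (= Std/Mean, the coefficient of variation) and Drop (= Max - Min) — plus
cumulative-time-below / cumulative-time-above features at every integer mmHg
threshold between the cohort-pooled 5th and 85th percentiles of that signal.
Cumulative times are stored both in minutes and as fractions of the
intervention time; area-below-threshold is computed on request but excluded
from the default matrix as redundant with the cumulative times.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CleanTrace

CHANNELS = ("MAP", "SAP", "DAP", "PP")
SUMMARY_STATS = ("Min", "Max", "Mean", "Median", "Std", "Var", "Drop")


@dataclass
class ThresholdGrid:
    """Integer mmHg thresholds per signal, spanning cohort P5..P85."""

    thresholds: dict[str, np.ndarray]
    percentiles: tuple[float, float] = (5.0, 85.0)

    def size(self) -> int:
        return sum(len(v) for v in self.thresholds.values())


def summary_features(values: np.ndarray) -> dict[str, float]:
    """Seven whole-intervention summaries of one channel."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("summary_features: empty channel")
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return {
        "Min": float(np.min(x)),
        "Max": float(np.max(x)),
        "Mean": mean,
        "Median": float(np.median(x)),
        "Std": std,
        "Var": std / mean if mean != 0 else np.nan,
        "Drop": float(np.max(x) - np.min(x)),
    }


def build_threshold_grid(traces: dict[int, CleanTrace], lo: float = 5.0,
                         hi: float = 85.0) -> ThresholdGrid:
    """Integer thresholds from ceil(P5) to floor(P85) of the pooled samples."""
    if not traces:
        raise ValueError("build_threshold_grid: no clean traces")
    grid = {}
    for sig in CHANNELS:
        pooled = np.concatenate([t.channel(sig) for t in traces.values()])
        p_lo, p_hi = np.percentile(pooled, [lo, hi])
        start, stop = math.ceil(p_lo), math.floor(p_hi)
        if p_lo == p_hi or start > stop:
            warnings.warn(f"degenerate {sig} distribution: empty threshold grid")
            grid[sig] = np.array([], dtype=int)
        else:
            grid[sig] = np.arange(start, stop + 1)
    return ThresholdGrid(thresholds=grid, percentiles=(lo, hi))


def cum_time_threshold(values: np.ndarray, theta: float, grid_seconds: float = 30.0
                       ) -> dict[str, float]:
    """Time below/above a threshold for a uniformly gridded channel.

    Each grid sample represents one ``grid_seconds`` slot.  "Below" counts
    samples strictly below theta; equality is assigned to "above" so that
    below + above equals the total intervention time exactly.
    ``area_below`` is the threshold-deficit integral sum(max(theta - v, 0))*dt.
    """
    x = np.asarray(values, dtype=float)
    total_min = len(x) * grid_seconds / 60.0
    below_min = float(np.sum(x < theta)) * grid_seconds / 60.0
    above_min = total_min - below_min
    return {
        "below_min": below_min,
        "above_min": above_min,
        "below_frac": below_min / total_min if total_min > 0 else np.nan,
        "above_frac": above_min / total_min if total_min > 0 else np.nan,
        "area_below": float(np.sum(np.maximum(theta - x, 0.0)) * grid_seconds / 60.0),
    }


def assemble_matrix(traces: dict[int, CleanTrace], grid: ThresholdGrid | None = None,
                    form: str = "fraction", with_area: bool = False,
                    equality_side: str = "above") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the patients x variables matrix and its column metadata.

    Parameters
    ----------
    traces
        Clean traces keyed by patient id (excluded patients already dropped).
    grid
        Threshold grid; built from the cohort when omitted.
    form
        ``"fraction"`` (default) stores cumulative times as fractions of the
        intervention time; ``"minutes"`` stores them in minutes.
    with_area
        Also emit ``AreaBelow`` columns (off by default).
    equality_side
        Which side samples exactly at the threshold count toward:
        ``"above"`` (default, below is strict ``<``) or ``"below"``
        (below is ``<=``).  Either way below + above is the full time.

    Returns
    -------
    (features, meta) where ``features`` is indexed by patient_id and ``meta``
    records signal/family/threshold/unit per column.
    """
    if len(traces) < 2:
        raise ValueError("assemble_matrix: need at least 2 patients")
    if form not in ("fraction", "minutes"):
        raise ValueError("form must be 'fraction' or 'minutes'")
    if equality_side not in ("above", "below"):
        raise ValueError("equality_side must be 'above' or 'below'")
    if grid is None:
        grid = build_threshold_grid(traces)

    rows = {}
    meta: dict[str, dict] = {}
    for pid, trace in sorted(traces.items()):
        row = {}
        for sig in CHANNELS:
            ch = trace.channel(sig)
            for stat, val in summary_features(ch).items():
                name = f"{stat}{sig}"
                row[name] = val
                meta.setdefault(name, {"signal": sig, "family": stat,
                                       "threshold": None, "unit": "" if stat == "Var" else "mmHg"})
            thetas = grid.thresholds[sig]
            if len(thetas):
                # one sort per channel; strict '<' matches side="left"
                srt = np.sort(ch)
                n_tot = len(ch)
                side = "left" if equality_side == "above" else "right"
                below_cnt = np.searchsorted(srt, thetas, side=side)
                below_min = below_cnt * 30.0 / 60.0
                total_min = n_tot * 30.0 / 60.0
                unit = "fraction" if form == "fraction" else "minutes"
                for theta, bmin in zip(thetas, below_min):
                    below_name = f"CumTime{sig}<{theta}"
                    above_name = f"CumTime{sig}>{theta}"
                    if form == "fraction":
                        row[below_name] = bmin / total_min
                        row[above_name] = 1.0 - bmin / total_min
                    else:
                        row[below_name] = bmin
                        row[above_name] = total_min - bmin
                    meta.setdefault(below_name, {"signal": sig, "family": "CumTimeBelow",
                                                 "threshold": int(theta), "unit": unit})
                    meta.setdefault(above_name, {"signal": sig, "family": "CumTimeAbove",
                                                 "threshold": int(theta), "unit": unit})
                    if with_area:
                        area_name = f"AreaBelow{sig}<{theta}"
                        row[area_name] = float(np.sum(np.maximum(theta - ch, 0.0)) * 0.5)
                        meta.setdefault(area_name, {"signal": sig, "family": "AreaBelow",
                                                    "threshold": int(theta), "unit": "mmHg.min"})
        rows[pid] = row

    features = pd.DataFrame.from_dict(rows, orient="index")
    features.index.name = "patient_id"
    meta_df = pd.DataFrame.from_dict(meta, orient="index")
    meta_df.index.name = "feature"
    return features, meta_df


def cum_time_minutes(traces: dict[int, CleanTrace], signal: str, theta: float,
                     side: str = "above") -> pd.Series:
    """Cumulative minutes above/below a threshold for every patient."""
    vals = {}
    for pid, trace in sorted(traces.items()):
        ct = cum_time_threshold(trace.channel(signal), theta)
        vals[pid] = ct["above_min"] if side == "above" else ct["below_min"]
    s = pd.Series(vals)
    s.index.name = "patient_id"
    return s
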