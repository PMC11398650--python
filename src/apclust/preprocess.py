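"""Cleaning of raw cuff-cadence arterial-pressure traces.

Raw input is a long table of timestamped SAP/DAP/MAP measurements (one row
per measurement).  The cleaning chain per patient is:

1. pair SAP and DAP records through a Cantor-pairing key on (time, patient)
   and derive the pulse-pressure series PP = SAP - DAP at paired times;
2. flag artifacts with a Hampel rule (|x - median| > 5 MAD, computed over
   the whole per-patient series, unscaled MAD) and treat them as missing;
3. reject the trace when any interior gap between surviving measurements
   exceeds 10 minutes (leading/trailing gaps are exempt);
4. impute the flagged points with a loess smoother (40 % span, tricube
   weights, local linear);
5. interpolate each channel onto a uniform 30-second grid with a
   shape-preserving piecewise cubic Hermite polynomial (pchip).

The grid PP channel is recomputed as SAP - DAP on the grid so the identity
pp = sap - dap holds exactly at every grid point; Hampel flags raised on the
native PP series are propagated to the SAP and DAP points they came from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from statsmodels.nonparametric.smoothers_lowess import lowess

SIGNALS = ("SAP", "DAP", "MAP")

#: exclusion reason codes
GAP_GT_10MIN = "GAP_GT_10MIN"
TOO_FEW_POINTS = "TOO_FEW_POINTS"
ALL_MISSING = "ALL_MISSING"


@dataclass
class PreprocessConfig:
    """Tunable parameters of the cleaning chain."""

    mad_threshold: float = 5.0          # Hampel fence, in MADs
    mad_constant: float = 1.0           # 1.4826 for the normal-consistent MAD
    gap_minutes: float = 10.0           # interior gap beyond which a trace is rejected
    grid_seconds: float = 30.0          # uniform resampling step
    loess_span: float = 0.40            # loess span (fraction of points)
    min_points: int = 5                 # minimum surviving points per channel


@dataclass
class CleanTrace:
    """One patient's cleaned, uniformly resampled signals (mmHg)."""

    patient_id: int
    grid_t: np.ndarray = field(default_factory=lambda: np.array([]))
    sap: np.ndarray = field(default_factory=lambda: np.array([]))
    dap: np.ndarray = field(default_factory=lambda: np.array([]))
    map_: np.ndarray = field(default_factory=lambda: np.array([]))
    pp: np.ndarray = field(default_factory=lambda: np.array([]))
    excluded: bool = False
    reason: str | None = None

    @property
    def duration_minutes(self) -> float:
        """Intervention time represented by the grid (one slot per sample)."""
        return len(self.grid_t) * 30.0 / 60.0

    def channel(self, name: str) -> np.ndarray:
        return {"SAP": self.sap, "DAP": self.dap, "MAP": self.map_, "PP": self.pp}[name.upper()]


def pair_key(t: int, patient_id: int) -> int:
    """Cantor pairing key pi(t, id) = (t+id)(t+id+1)/2 + id.

    Injective on pairs of non-negative integers; used to join SAP and DAP
    records recorded at the same instant for the same patient.
    """
    if isinstance(t, (bool, np.bool_)) or isinstance(patient_id, (bool, np.bool_)):
        raise TypeError("pair_key expects integers, got booleans")
    for v in (t, patient_id):
        if not (isinstance(v, (int, np.integer)) or (isinstance(v, float) and float(v).is_integer())):
            raise TypeError(f"pair_key expects non-negative integers, got {v!r}")
        if v < 0:
            raise ValueError(f"pair_key expects non-negative inputs, got {v!r}")
    a, b = int(t), int(patient_id)
    s = a + b
    return s * (s + 1) // 2 + b


def pair_sap_dap(raw: pd.DataFrame) -> pd.DataFrame:
    """Join SAP and DAP records sharing a Cantor key; derive PP where paired.

    Parameters
    ----------
    raw
        Long table with columns ``patient_id, t_seconds, signal, value_mmHg``.

    Returns
    -------
    DataFrame with columns ``patient_id, t_seconds, sap, dap, pp`` where
    ``sap``/``dap`` are NaN for unpaired records and ``pp = sap - dap`` only
    where both channels are present.
    """
    df = raw[raw["signal"].str.upper().isin(["SAP", "DAP"])].copy()
    if df.empty:
        return pd.DataFrame(columns=["patient_id", "t_seconds", "sap", "dap", "pp"])
    df["signal"] = df["signal"].str.upper()
    keys = [pair_key(int(t), int(p)) for t, p in zip(df["t_seconds"], df["patient_id"])]
    df["key"] = keys
    dup = df.duplicated(subset=["key", "signal"], keep=False)
    if dup.any():
        bad = df.loc[dup, ["patient_id", "t_seconds", "signal"]].drop_duplicates()
        raise ValueError(
            "duplicate (time, patient, signal) records cannot be paired:\n"
            + bad.to_string(index=False)
        )
    wide = df.pivot(index="key", columns="signal", values="value_mmHg")
    meta = df.drop_duplicates("key").set_index("key")[["patient_id", "t_seconds"]]
    out = meta.join(wide).reset_index(drop=True)
    for col in ("SAP", "DAP"):
        if col not in out:
            out[col] = np.nan
    out = out.rename(columns={"SAP": "sap", "DAP": "dap"})
    out["pp"] = out["sap"] - out["dap"]
    return out.sort_values(["patient_id", "t_seconds"]).reset_index(drop=True)


def hampel_clean(values: np.ndarray, n_mad: float = 5.0, mad_constant: float = 1.0) -> np.ndarray:
    """Set outliers to NaN using a global median/MAD fence.

    A value x is flagged iff |x - median| > n_mad * constant * MAD, with the
    median and MAD computed once over all non-missing values of the series
    (no sliding window).  The inequality is strict, so a value sitting
    exactly on the fence survives; with MAD = 0 every value differing from
    the median is flagged.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() == 0:
        raise ValueError("hampel_clean: all values missing")
    if finite.sum() < 3:
        raise ValueError("hampel_clean: need at least 3 non-missing values")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    fence = n_mad * mad_constant * mad
    out = x.copy()
    out[finite & (np.abs(x - med) > fence)] = np.nan
    return out


def gap_exclude(t_seconds: np.ndarray, values: np.ndarray, gap_minutes: float = 10.0) -> tuple[bool, str | None]:
    """Decide whether a series must be rejected for an interior gap.

    Returns ``(keep, reason)``.  A trace is rejected iff two consecutive
    *non-missing* measurements are more than ``gap_minutes`` apart; gaps
    before the first or after the last non-missing measurement never cause
    rejection.
    """
    t = np.asarray(t_seconds, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if ok.sum() == 0:
        return False, ALL_MISSING
    tt = t[ok]
    if np.any(np.diff(tt) > gap_minutes * 60.0):
        return False, GAP_GT_10MIN
    return True, None


def loess_impute(t_seconds: np.ndarray, values: np.ndarray, span: float = 0.40) -> np.ndarray:
    """Fill missing entries with a loess fit; observed entries untouched.

    Local linear regression with tricube weights over ``span`` of the points,
    evaluated at the missing timestamps.  Requires at least 5 observed
    points.  The smoothing window is floored at 4 points (on short series a
    40 % span can leave a single non-zero weight, which has no unique local
    line); in the rare degenerate windows that still produce no fit the
    point falls back to linear interpolation between its neighbours.
    """
    t = np.asarray(t_seconds, dtype=float)
    v = np.asarray(values, dtype=float)
    miss = ~np.isfinite(v)
    if not miss.any():
        return v.copy()
    n_obs = int((~miss).sum())
    if n_obs < 5:
        raise ValueError("loess_impute: need at least 5 observed points")
    frac = max(span, min(1.0, 4.0 / n_obs))
    fitted = lowess(v[~miss], t[~miss], frac=frac, it=0, xvals=t[miss])
    out = v.copy()
    out[miss] = fitted
    bad = ~np.isfinite(out)
    if bad.any():
        out[bad] = np.interp(t[bad], t[~miss], v[~miss])
    return out


def resample_30s(t_seconds: np.ndarray, values: np.ndarray, grid_seconds: float = 30.0,
                 grid_t: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """pchip interpolation of a complete series onto a uniform grid.

    The grid spans ``[t_first, t_last]`` with step ``grid_seconds`` (length
    floor((t_last - t_first)/step) + 1) unless an explicit ``grid_t`` is
    given.  pchip is shape-preserving: it passes through the knots and never
    overshoots local extrema.
    """
    t = np.asarray(t_seconds, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise ValueError("resample_30s: need at least 2 points")
    if not np.all(np.isfinite(v)):
        raise ValueError("resample_30s: series must be imputed first")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if grid_t is None:
        n = math.floor((t[-1] - t[0]) / grid_seconds) + 1
        grid_t = t[0] + grid_seconds * np.arange(n)
    interp = PchipInterpolator(t, v)
    return grid_t, interp(grid_t)


def _per_signal_arrays(records: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    sig_col = records["signal"].str.upper().to_numpy()
    t_all = records["t_seconds"].to_numpy(dtype=float)
    v_all = records["value_mmHg"].to_numpy(dtype=float)
    out = {}
    for sig in SIGNALS:
        m = sig_col == sig
        t, v = t_all[m], v_all[m]
        order = np.argsort(t, kind="stable")
        out[sig] = (t[order], v[order])
    return out


def clean_patient(records: pd.DataFrame, config: PreprocessConfig | None = None) -> CleanTrace:
    """Run the full cleaning chain for one patient's raw records."""
    cfg = config or PreprocessConfig()
    pid = int(records["patient_id"].iloc[0])
    arrays = _per_signal_arrays(records)

    for sig in SIGNALS:
        if len(arrays[sig][0]) < max(3, cfg.min_points):
            return CleanTrace(patient_id=pid, excluded=True, reason=TOO_FEW_POINTS)

    # Hampel on each recorded series
    times = {sig: arrays[sig][0] for sig in SIGNALS}
    vals = {sig: hampel_clean(arrays[sig][1], cfg.mad_threshold, cfg.mad_constant)
            for sig in SIGNALS}

    # Hampel on the paired PP series; flags propagate to SAP and DAP.
    # Pairing on shared (integer-second) timestamps is the array form of the
    # Cantor-key join: within one patient the key is injective in time.
    t_sap, v_sap = times["SAP"], arrays["SAP"][1]
    t_dap, v_dap = times["DAP"], arrays["DAP"][1]
    pp_t, i_sap, i_dap = np.intersect1d(t_sap, t_dap, return_indices=True)
    pp_v = v_sap[i_sap] - v_dap[i_dap]
    if len(pp_v) >= 3:
        pp_clean = hampel_clean(pp_v, cfg.mad_threshold, cfg.mad_constant)
        bad_t = pp_t[~np.isfinite(pp_clean)]
        for sig in ("SAP", "DAP"):
            vals[sig][np.isin(times[sig], bad_t)] = np.nan

    # gap rule (Hampel-flagged points count as missing)
    for sig in SIGNALS:
        keep, reason = gap_exclude(times[sig], vals[sig], cfg.gap_minutes)
        if not keep:
            return CleanTrace(patient_id=pid, excluded=True, reason=reason)
        if np.isfinite(vals[sig]).sum() < cfg.min_points:
            return CleanTrace(patient_id=pid, excluded=True, reason=TOO_FEW_POINTS)

    # loess imputation at native timestamps, then pchip to the common grid
    imputed = {}
    for sig in SIGNALS:
        # interior only: leading/trailing missing points have no support and are dropped
        v = vals[sig]
        ok = np.isfinite(v)
        first, last = np.argmax(ok), len(v) - 1 - np.argmax(ok[::-1])
        tt, vv = times[sig][first:last + 1], v[first:last + 1]
        imputed[sig] = (tt, loess_impute(tt, vv, cfg.loess_span))

    t0 = max(imputed[sig][0][0] for sig in SIGNALS)
    t1 = min(imputed[sig][0][-1] for sig in SIGNALS)
    if t1 - t0 < cfg.grid_seconds:
        return CleanTrace(patient_id=pid, excluded=True, reason=TOO_FEW_POINTS)
    n = math.floor((t1 - t0) / cfg.grid_seconds) + 1
    grid_t = t0 + cfg.grid_seconds * np.arange(n)

    chans = {}
    for sig in SIGNALS:
        tt, vv = imputed[sig]
        _, chans[sig] = resample_30s(tt, vv, cfg.grid_seconds, grid_t=grid_t)

    return CleanTrace(
        patient_id=pid,
        grid_t=grid_t,
        sap=chans["SAP"],
        dap=chans["DAP"],
        map_=chans["MAP"],
        pp=chans["SAP"] - chans["DAP"],
    )


def clean_traces(raw: pd.DataFrame, config: PreprocessConfig | None = None
                 ) -> tuple[dict[int, CleanTrace], pd.DataFrame]:
    """Clean every patient's trace; return kept traces and an exclusion log."""
    cfg = config or PreprocessConfig()
    kept: dict[int, CleanTrace] = {}
    excl = []
    for pid, grp in raw.groupby("patient_id", sort=True):
        trace = clean_patient(grp, cfg)
        if trace.excluded:
            excl.append({"patient_id": int(pid), "reason": trace.reason})
        else:
            kept[int(pid)] = trace
    log = pd.DataFrame(excl, columns=["patient_id", "reason"])
    return kept, log


def clean_trace_to_frame(trace: CleanTrace) -> pd.DataFrame:
    return pd.DataFrame({
        "t_seconds": trace.grid_t,
        "sap": trace.sap,
        "dap": trace.dap,
        "map": trace.map_,
        "pp": trace.pp,
    })
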