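"""Effect-size ranking and per-cluster representative selection.

Within each variable cluster, candidates are ranked by the absolute
standardized mean difference (aSMD) between prolonged-stay and
non-prolonged patients:

    aSMD = |mean(group1) - mean(group0)| / sd(group1)

where group1 is the *effect* (prolonged-stay) group and sd is the sample
standard deviation.  Confidence intervals come from a patient-level
percentile bootstrap (default 1000 resamples).  The top-ranked variable of
each cluster is its representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateEffectGroupError(ValueError):
    """The effect group has zero spread but a non-zero mean difference."""


@dataclass
class RankingConfig:
    sd_mode: str = "effect"        # "effect" (sd of group 1) or "pooled"
    bootstrap: int = 1000
    stratified: bool = False
    seed: int = 0


def asmd(values: np.ndarray, labels: np.ndarray, sd_mode: str = "effect") -> float:
    """Absolute standardized mean difference of a feature across outcomes."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    g1, g0 = x[y == 1], x[y == 0]
    if len(g1) < 2 or len(g0) < 1:
        raise ValueError("asmd: effect group needs >= 2 members, other group >= 1")
    diff = abs(float(np.mean(g1)) - float(np.mean(g0)))
    if sd_mode == "effect":
        sd = float(np.std(g1, ddof=1))
    elif sd_mode == "pooled":
        v1, v0 = np.var(g1, ddof=1), np.var(g0, ddof=1)
        sd = float(np.sqrt(((len(g1) - 1) * v1 + (len(g0) - 1) * v0) / (len(g1) + len(g0) - 2)))
    else:
        raise ValueError(f"unknown sd_mode: {sd_mode!r}")
    if sd == 0.0:
        if diff == 0.0:
            return 0.0
        raise DegenerateEffectGroupError("zero effect-group SD with non-zero mean difference")
    return diff / sd


def bootstrap_ci(values: np.ndarray, labels: np.ndarray, B: int = 1000,
                 seed: int | np.random.Generator = 0, sd_mode: str = "effect",
                 stratified: bool = False) -> tuple[float, float]:
    """Percentile-bootstrap 95% interval for the aSMD.

    Patients are resampled with replacement (optionally within outcome
    strata); replicates whose resample lacks a usable effect group are
    redrawn, and more than 10% failures aborts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(x)
    idx1, idx0 = np.where(y == 1)[0], np.where(y == 0)[0]
    reps = np.empty(B)
    failures = 0
    for b in range(B):
        for _attempt in range(10):
            if stratified:
                take = np.concatenate([rng.choice(idx1, len(idx1), replace=True),
                                       rng.choice(idx0, len(idx0), replace=True)])
            else:
                take = rng.integers(0, n, size=n)
            xb, yb = x[take], y[take]
            if (yb == 1).sum() >= 2 and (yb == 0).sum() >= 1:
                try:
                    reps[b] = asmd(xb, yb, sd_mode)
                    break
                except DegenerateEffectGroupError:
                    pass
            failures += 1
            if failures > 0.10 * B:
                raise RuntimeError("bootstrap_ci: more than 10% of replicates failed")
        else:
            raise RuntimeError("bootstrap_ci: could not draw a usable replicate")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def asmd_all(features: pd.DataFrame, labels: np.ndarray, sd_mode: str = "effect") -> pd.Series:
    """Vectorized aSMD for every feature column (NaN where degenerate)."""
    y = np.asarray(labels).astype(int)
    X = features.to_numpy(dtype=float)
    m1 = X[y == 1].mean(axis=0)
    m0 = X[y == 0].mean(axis=0)
    if sd_mode == "effect":
        sd = X[y == 1].std(axis=0, ddof=1)
    else:
        v1 = X[y == 1].var(axis=0, ddof=1)
        v0 = X[y == 0].var(axis=0, ddof=1)
        n1, n0 = (y == 1).sum(), (y == 0).sum()
        sd = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(m1 - m0) / sd
    out[(sd == 0) & (m1 == m0)] = 0.0
    return pd.Series(out, index=features.columns, name="asmd")


def select_representatives(features: pd.DataFrame, labels: np.ndarray,
                           assignment: pd.Series, config: RankingConfig | None = None,
                           with_ci: bool = False) -> pd.DataFrame:
    """Rank features within clusters by aSMD; flag each cluster's best.

    Returns an effect-size table (feature, cluster, asmd, ci_lo, ci_hi,
    rank, representative).  Ties in aSMD break deterministically by feature
    name.  Bootstrap CIs are computed only when ``with_ci`` (they are not
    needed for selection itself).
    """
    cfg = config or RankingConfig()
    cols = [c for c in features.columns if c in assignment.index]
    table = pd.DataFrame({
        "feature": cols,
        "cluster": [int(assignment[c]) for c in cols],
        "asmd": asmd_all(features[cols], labels, cfg.sd_mode).to_numpy(),
    })
    table = table.sort_values(["cluster", "asmd", "feature"],
                              ascending=[True, False, True], kind="stable")
    table["rank"] = table.groupby("cluster").cumcount() + 1
    table["representative"] = table["rank"] == 1
    if with_ci:
        rng = np.random.default_rng(cfg.seed)
        los, his = [], []
        for feat in table["feature"]:
            lo, hi = bootstrap_ci(features[feat].to_numpy(), labels, cfg.bootstrap,
                                  rng, cfg.sd_mode, cfg.stratified)
            los.append(lo)
            his.append(hi)
        table["ci_lo"], table["ci_hi"] = los, his
    else:
        table["ci_lo"] = table["ci_hi"] = np.nan
    return table.reset_index(drop=True)
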