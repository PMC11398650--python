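"""Penalized-BIC cluster-count selection and the final logistic model.

For each candidate number of clusters k (default 1..10), the dendrogram is
cut, each cluster's top-aSMD variable becomes a predictor, and a logistic
model of the prolonged-stay label is fitted on column-standardized
predictors.  Model quality is scored with a modified BIC

    mBIC = k ln(N) - 2 ln(L) + n_insignificant * ln(N)

where k is the number of clusters, L the maximized likelihood and
n_insignificant the count of predictors with Wald p >= 0.05; the k with the
smallest mBIC wins (ties go to the smaller k).  The winning model is then
reduced to its significant predictors (the independence filter), refitted
once, and reported as per-SD odds ratios with Wald 95% intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .clustering import cut_k
from .ranking import RankingConfig, select_representatives


@dataclass
class LogisticFit:
    predictors: list[str]
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    intercept: float
    llf: float
    n: int
    scale: pd.Series          # per-column SD used for standardization
    center: pd.Series


@dataclass
class SelectionResult:
    trace: pd.DataFrame                    # per-k: k, representatives, llf, bic, n_insig, mbic
    chosen_k: int
    representatives: list[str]             # representatives at the chosen k
    final_variables: list[str]             # after the p<0.05 independence filter
    final_fit: LogisticFit | None
    odds_ratios: pd.DataFrame
    effect_sizes: pd.DataFrame = field(default_factory=pd.DataFrame)


def fit_logistic(features: pd.DataFrame, labels: np.ndarray,
                 standardize: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic fit on (optionally standardized) columns."""
    y = np.asarray(labels).astype(int)
    X = features.to_numpy(dtype=float)
    center = features.mean()
    scale = features.std(ddof=1)
    if (scale == 0).any():
        bad = list(scale.index[scale == 0])
        raise ValueError(f"fit_logistic: constant predictor(s): {bad}")
    if standardize:
        X = (X - center.to_numpy()) / scale.to_numpy()
    else:
        center = pd.Series(0.0, index=features.columns)
        scale = pd.Series(1.0, index=features.columns)
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation, singular Hessian, ...
        raise RuntimeError(f"fit_logistic failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("fit_logistic: optimizer did not converge")
    names = list(features.columns)
    return LogisticFit(
        predictors=names,
        coef=pd.Series(res.params[1:], index=names),
        se=pd.Series(res.bse[1:], index=names),
        pvalues=pd.Series(res.pvalues[1:], index=names),
        intercept=float(res.params[0]),
        llf=float(res.llf),
        n=len(y),
        scale=scale,
        center=center,
    )


def mbic(llf: float, k: int, n: int, n_insig: int, complexity: str = "clusters") -> float:
    """Modified BIC: k ln(N) - 2 ln(L) + n_insig ln(N).

    ``complexity="clusters"`` (default) charges exactly the cluster count k;
    ``"parameters"`` charges the textbook k + 1 (the intercept counts too).
    """
    if n < 1 or k < 1 or not 0 <= n_insig <= k:
        raise ValueError("mbic: require N >= 1, k >= 1, 0 <= n_insig <= k")
    if complexity == "clusters":
        dof = k
    elif complexity == "parameters":
        dof = k + 1
    else:
        raise ValueError("complexity must be 'clusters' or 'parameters'")
    return dof * math.log(n) - 2.0 * llf + n_insig * math.log(n)


def odds_ratio_table(fit: LogisticFit) -> pd.DataFrame:
    """Per-SD odds ratios with Wald 95% intervals from a standardized fit."""
    z = stats.norm.ppf(0.975)
    return pd.DataFrame({
        "feature": fit.predictors,
        "coef_per_sd": fit.coef.to_numpy(),
        "or_per_sd": np.exp(fit.coef.to_numpy()),
        "or_lo": np.exp(fit.coef.to_numpy() - z * fit.se.to_numpy()),
        "or_hi": np.exp(fit.coef.to_numpy() + z * fit.se.to_numpy()),
        "p_value": fit.pvalues.to_numpy(),
    })


def apply_coding(features: pd.DataFrame, rules: dict[str, dict]) -> pd.DataFrame:
    """Recode predictors for odds-ratio reporting.

    Supported rules per feature:

    ``{"dichotomize_at": x}``
        1 when the value exceeds x, else 0 (e.g. cumulative time above a
        pressure threshold exceeding 50 minutes).
    ``{"floor_at": x, "per_sd": s}``
        values capped below at x, then divided by s so a unit change is one
        standard deviation (s defaults to the column's own SD after
        flooring).
    """
    out = features.copy()
    for feat, rule in rules.items():
        if feat not in out:
            continue
        if "dichotomize_at" in rule:
            out[feat] = (out[feat] > rule["dichotomize_at"]).astype(float)
        elif "floor_at" in rule:
            v = out[feat].clip(lower=rule["floor_at"])
            sd = rule.get("per_sd") or v.std(ddof=1)
            out[feat] = v / sd
        else:
            raise ValueError(f"unknown coding rule for {feat!r}: {rule}")
    return out


def report_odds_ratios(features: pd.DataFrame, labels: np.ndarray,
                       coding_rules: dict[str, dict] | None = None) -> pd.DataFrame:
    """Odds-ratio table, optionally after the covariate recoding rules.

    Recoded columns are fitted unstandardized (their scale is already
    meaningful); without rules this is the plain per-SD table.
    """
    if not coding_rules:
        return odds_ratio_table(fit_logistic(features, labels, standardize=True))
    coded = apply_coding(features, coding_rules)
    fit = fit_logistic(coded, labels, standardize=False)
    table = odds_ratio_table(fit)
    table["recoded"] = [f in coding_rules for f in table["feature"]]
    return table


def select_k(tree: np.ndarray, feature_names: list[str], features: pd.DataFrame,
             labels: np.ndarray, k_range: range = range(1, 11), alpha: float = 0.05,
             ranking: RankingConfig | None = None, with_ci: bool = False) -> SelectionResult:
    """Scan k, pick the mBIC-minimizing model, apply the independence filter.

    ``feature_names`` gives the leaf order of ``tree`` (constant columns
    already excluded).  Returns the per-k trace, the chosen k, the final
    significant variable set and its refit odds ratios.
    """
    cfg = ranking or RankingConfig()
    y = np.asarray(labels).astype(int)
    rows = []
    reps_by_k: dict[int, list[str]] = {}
    effect_by_k: dict[int, pd.DataFrame] = {}
    for k in k_range:
        if k > len(feature_names):
            break
        assignment = cut_k(tree, k, labels=feature_names)
        table = select_representatives(features[feature_names], y, assignment, cfg)
        reps = sorted(table.loc[table["representative"], "feature"].tolist())
        try:
            fit = fit_logistic(features[reps], y)
        except (RuntimeError, ValueError) as exc:
            rows.append({"k": k, "representatives": reps, "llf": np.nan, "bic": np.nan,
                         "n_insig": np.nan, "mbic": np.nan, "error": str(exc)})
            continue
        n_insig = int((fit.pvalues >= alpha).sum())
        bic = mbic(fit.llf, k, fit.n, 0)
        rows.append({"k": k, "representatives": reps, "llf": fit.llf, "bic": bic,
                     "n_insig": n_insig, "mbic": mbic(fit.llf, k, fit.n, n_insig),
                     "error": ""})
        reps_by_k[k] = reps
        effect_by_k[k] = table
    trace = pd.DataFrame(rows)
    valid = trace.dropna(subset=["mbic"])
    if valid.empty:
        raise RuntimeError("select_k: no k produced a valid fit")
    chosen_k = int(valid.loc[valid["mbic"].idxmin(), "k"])  # idxmin takes first = smallest k

    reps = reps_by_k[chosen_k]
    full_fit = fit_logistic(features[reps], y)
    final = [f for f in reps if full_fit.pvalues[f] < alpha]
    if final:
        final_fit = fit_logistic(features[final], y)
        ors = odds_ratio_table(final_fit)
    else:
        final_fit, ors = None, pd.DataFrame()

    effect_sizes = effect_by_k[chosen_k]
    if with_ci:
        effect_sizes = select_representatives(features[feature_names], y,
                                              cut_k(tree, chosen_k, labels=feature_names),
                                              cfg, with_ci=True)
    return SelectionResult(trace=trace, chosen_k=chosen_k, representatives=reps,
                           final_variables=final, final_fit=final_fit,
                           odds_ratios=ors, effect_sizes=effect_sizes)


def descriptive_tables(patients: pd.DataFrame, labels: np.ndarray,
                       continuous: list[str] | None = None,
                       categorical: list[str] | None = None) -> pd.DataFrame:
    """Group comparison table: median [IQR] + Mann-Whitney for continuous
    covariates, counts (%) + Fisher (2x2) or chi-square (RxC) for
    categorical ones."""
    y = np.asarray(labels).astype(int)
    continuous = continuous if continuous is not None else ["age", "duration_min", "los_days"]
    categorical = categorical if categorical is not None else ["sex", "surgery_class"]
    rows = []

    def _fmt(x: np.ndarray) -> str:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"

    for var in continuous:
        if var not in patients:
            continue
        x = patients[var].to_numpy(dtype=float)
        g1, g0 = x[y == 1], x[y == 0]
        if len(g1) and len(g0):
            p = stats.mannwhitneyu(g1, g0, alternative="two-sided").pvalue
        else:
            p = np.nan
        rows.append({"variable": var, "level": "", "non_plos": _fmt(g0),
                     "plos": _fmt(g1), "test": "mann-whitney", "p_value": p})

    for var in categorical:
        if var not in patients:
            continue
        levels = sorted(patients[var].astype(str).unique())
        counts = pd.crosstab(patients[var].astype(str), y)
        for col in (0, 1):
            if col not in counts:
                counts[col] = 0
        tab = counts[[0, 1]].to_numpy()
        if tab.shape == (2, 2):
            p = stats.fisher_exact(tab)[1]
            test = "fisher"
        else:
            p = stats.chi2_contingency(tab)[1] if tab.min() >= 0 and tab.shape[0] > 1 else np.nan
            test = "chi2"
        for lev in levels:
            n0, n1 = counts.loc[lev, 0], counts.loc[lev, 1]
            t0, t1 = max((y == 0).sum(), 1), max((y == 1).sum(), 1)
            rows.append({"variable": var, "level": lev,
                         "non_plos": f"{n0} ({100 * n0 / t0:.1f})",
                         "plos": f"{n1} ({100 * n1 / t1:.1f})",
                         "test": test, "p_value": p})
    return pd.DataFrame(rows)
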