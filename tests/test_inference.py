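"""Logistic fits, modified BIC, k selection, odds ratios, group tables."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import hypergeom

from apclust.clustering import ward_tree
from apclust.inference import (apply_coding, descriptive_tables, fit_logistic,
                               mbic, odds_ratio_table, report_odds_ratios,
                               select_k)


class TestMbic:
    def test_plain_bic_when_all_significant(self):
        assert mbic(-50, 2, 100, 0) == pytest.approx(2 * math.log(100) + 100)
        assert mbic(-50, 2, 100, 0) == pytest.approx(109.2103403719762, abs=1e-9)

    def test_penalty_adds_log_n(self):
        assert mbic(-50, 2, 100, 1) - mbic(-50, 2, 100, 0) == pytest.approx(math.log(100))
        assert mbic(-50, 2, 100, 1) == pytest.approx(113.8155105579643, abs=1e-9)

    def test_strictly_increasing_in_insignificance(self):
        vals = [mbic(-120, 4, 500, i) for i in range(5)]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            mbic(-10, 0, 100, 0)
        with pytest.raises(ValueError):
            mbic(-10, 2, 100, 3)


class TestLogistic:
    def test_two_by_two_equals_log_odds_ratio(self):
        # cells: x=0 -> 30 events / 70 non; x=1 -> 60 / 40
        x = np.r_[np.zeros(100), np.ones(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(60), np.zeros(40)].astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y, standardize=False)
        table_or = (60 / 40) / (30 / 70)
        assert fit.coef["x"] == pytest.approx(math.log(table_or), abs=1e-6)

    def test_null_coefficients_small(self, rng):
        n = 2000
        f = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = (rng.random(n) < 0.4).astype(int)
        fit = fit_logistic(f, y)
        assert (fit.coef.abs() < 0.15).all()

    def test_parameter_recovery(self, rng):
        n = 5000
        X = rng.normal(size=(n, 3))
        beta = np.array([0.5, -0.3, 0.2])
        y = (rng.random(n) < expit(-0.5 + X @ beta)).astype(int)
        fit = fit_logistic(pd.DataFrame(X, columns=list("abc")), y)
        # standardized X has SD ~1 so per-SD coefs match beta
        for j, name in enumerate("abc"):
            assert abs(fit.coef[name] - beta[j]) < 3 * fit.se[name]

    def test_permutation_invariance(self, rng):
        n = 500
        f = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = (rng.random(n) < 0.35).astype(int)
        fit1 = fit_logistic(f, y)
        perm = rng.permutation(n)
        fit2 = fit_logistic(f.iloc[perm].reset_index(drop=True), y[perm])
        assert np.allclose(fit1.coef, fit2.coef, atol=1e-8)

    def test_constant_predictor_rejected(self):
        f = pd.DataFrame({"c": np.ones(50)})
        with pytest.raises(ValueError):
            fit_logistic(f, np.r_[np.zeros(25), np.ones(25)].astype(int))


class TestOddsRatios:
    def test_zero_coefficient_gives_or_one(self):
        from apclust.inference import LogisticFit
        fit = LogisticFit(predictors=["x"], coef=pd.Series({"x": 0.0}),
                          se=pd.Series({"x": 0.0}), pvalues=pd.Series({"x": 1.0}),
                          intercept=0.0, llf=-10.0, n=100,
                          scale=pd.Series({"x": 1.0}), center=pd.Series({"x": 0.0}))
        t = odds_ratio_table(fit)
        assert t["or_per_sd"].iloc[0] == 1.0
        assert t["or_lo"].iloc[0] == t["or_hi"].iloc[0] == 1.0

    def test_log2_coefficient(self):
        from apclust.inference import LogisticFit
        fit = LogisticFit(predictors=["x"], coef=pd.Series({"x": math.log(2)}),
                          se=pd.Series({"x": 0.0}), pvalues=pd.Series({"x": 0.0}),
                          intercept=0.0, llf=-10.0, n=100,
                          scale=pd.Series({"x": 1.0}), center=pd.Series({"x": 0.0}))
        t = odds_ratio_table(fit)
        assert t["or_per_sd"].iloc[0] == pytest.approx(2.0)
        assert (t["or_lo"].iloc[0], t["or_hi"].iloc[0]) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_coding_rules(self):
        f = pd.DataFrame({"ct": [10.0, 55.0, 80.0], "drop": [20.0, 25.0, 40.0]})
        coded = apply_coding(f, {"ct": {"dichotomize_at": 50},
                                 "drop": {"floor_at": 25, "per_sd": 14.9}})
        assert coded["ct"].tolist() == [0.0, 1.0, 1.0]
        assert coded["drop"].tolist() == pytest.approx([25 / 14.9, 25 / 14.9, 40 / 14.9])

    def test_report_with_coding(self, rng):
        n = 800
        ct = rng.uniform(0, 120, n)
        y = (rng.random(n) < expit(-1 + 0.8 * (ct > 50))).astype(int)
        t = report_odds_ratios(pd.DataFrame({"ct": ct}), y,
                               {"ct": {"dichotomize_at": 50}})
        assert t["recoded"].iloc[0]
        assert 1.2 < t["or_per_sd"].iloc[0] < 4.0


class TestSelectK:
    def _toy_tree(self, p, rng):
        A = rng.uniform(0.0, 0.4, size=(p, p))
        S = (A + A.T) / 2
        np.fill_diagonal(S, 1.0)
        return ward_tree(pd.DataFrame(S))

    def test_k_range_single(self, rng):
        n, p = 400, 4
        f = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
        y = (rng.random(n) < expit(-0.5 + f["f0"])).astype(int)
        tree = self._toy_tree(p, rng)
        res = select_k(tree, list(f.columns), f, y.to_numpy(), k_range=range(1, 2))
        assert res.chosen_k == 1

    def test_single_planted_predictor_chooses_k1(self, rng):
        # one signal feature, others pure noise weakly correlated
        hits = 0
        for rep in range(10):
            n = 2000
            sig = rng.normal(size=n)
            y = (rng.random(n) < expit(-0.8 + 0.45 * sig)).astype(int)
            f = pd.DataFrame({
                "signal": sig,
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            })
            from apclust.clustering import kendall_matrix
            S, _ = kendall_matrix(f)
            tree = ward_tree(S)
            res = select_k(tree, list(f.columns), f, y)
            if res.chosen_k == 1 and res.final_variables == ["signal"]:
                hits += 1
        assert hits >= 8

    def test_column_order_invariance(self, rng):
        n, p = 600, 5
        X = rng.normal(size=(n, p))
        y = (rng.random(n) < expit(-0.5 + 0.6 * X[:, 0] - 0.4 * X[:, 3])).astype(int)
        f = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
        from apclust.clustering import kendall_matrix
        S, _ = kendall_matrix(f)
        res1 = select_k(ward_tree(S), list(f.columns), f, y)
        cols = list(f.columns)[::-1]
        S2, _ = kendall_matrix(f[cols])
        res2 = select_k(ward_tree(S2), cols, f, y)
        assert sorted(res1.final_variables) == sorted(res2.final_variables)


class TestDescriptives:
    def test_identical_groups_p_near_one(self):
        # blocks of 4: two patients per outcome group with identical covariates
        p = pd.DataFrame({
            "id": range(40),
            "age": np.tile([40.0, 50, 40, 50], 10),
            "sex": np.tile(["male", "female", "male", "female"], 10),
            "duration_min": np.tile([60.0, 90, 60, 90], 10),
            "los_days": np.tile([2, 3, 2, 3], 10),
            "surgery_class": ["digestive"] * 40,
        })
        y = np.tile([0, 0, 1, 1], 10)
        t = descriptive_tables(p, y)
        assert (t["p_value"].dropna() > 0.5).all()

    def test_fisher_matches_hypergeometric_enumeration(self):
        # 2x2 table {{8,2},{1,5}}: two-sided Fisher by enumerating the
        # hypergeometric probabilities of all tables with the same margins
        from scipy.stats import fisher_exact
        table = np.array([[8, 2], [1, 5]])
        _, p_obs = fisher_exact(table)
        M, n1, N = table.sum(), table[0].sum(), table[:, 0].sum()
        rv = hypergeom(M, n1, N)
        p0 = rv.pmf(table[0, 0])
        p_enum = sum(rv.pmf(k) for k in range(max(0, N - (M - n1)), min(n1, N) + 1)
                     if rv.pmf(k) <= p0 + 1e-12)
        assert p_obs == pytest.approx(p_enum, abs=1e-10)


class TestMbicComplexity:
    def test_parameter_variant_adds_one_log_n(self):
        assert (mbic(-50, 2, 100, 0, complexity="parameters")
                - mbic(-50, 2, 100, 0)) == pytest.approx(math.log(100))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            mbic(-50, 2, 100, 0, complexity="aic")
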