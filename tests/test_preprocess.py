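"""Trace-cleaning chain: pairing, Hampel, gap rule, loess, pchip."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apclust.preprocess import (GAP_GT_10MIN, CleanTrace, PreprocessConfig,
                                clean_patient, clean_traces, gap_exclude,
                                hampel_clean, loess_impute, pair_key,
                                pair_sap_dap, resample_30s)
from .conftest import make_raw


class TestPairKey:
    @pytest.mark.parametrize("t,pid,expected", [(0, 0, 0), (2, 3, 18), (1, 0, 1), (0, 1, 2)])
    def test_closed_form(self, t, pid, expected):
        assert pair_key(t, pid) == expected

    def test_injective_on_small_domain(self):
        keys = {pair_key(a, b) for a in range(200) for b in range(200)}
        assert len(keys) == 40_000

    @pytest.mark.parametrize("bad", [(-1, 0), (0, -2), (1.5, 0), ("3", 1)])
    def test_rejects_invalid(self, bad):
        with pytest.raises((ValueError, TypeError)):
            pair_key(*bad)


class TestPairing:
    def test_fully_paired(self):
        raw = make_raw([(1, t, s, v) for t, v in [(0, 120), (30, 118), (60, 122)]
                        for s, v in [("SAP", v), ("DAP", v - 50)]])
        out = pair_sap_dap(raw)
        assert len(out) == 3
        assert np.allclose(out["pp"], 50)

    def test_partial_pairing_leaves_missing(self):
        raw = make_raw([(1, 0, "SAP", 120), (1, 30, "SAP", 118), (1, 60, "SAP", 122),
                        (1, 0, "DAP", 70), (1, 60, "DAP", 72)])
        out = pair_sap_dap(raw)
        assert np.isfinite(out["pp"]).sum() == 2
        missing = out.loc[out["pp"].isna(), "t_seconds"].tolist()
        assert missing == [30]

    def test_empty_input(self):
        assert pair_sap_dap(make_raw([])).empty

    def test_duplicates_rejected(self):
        raw = make_raw([(1, 0, "SAP", 120), (1, 0, "SAP", 121), (1, 0, "DAP", 70)])
        with pytest.raises(ValueError, match="duplicate"):
            pair_sap_dap(raw)


class TestHampel:
    def test_constant_series_unchanged(self):
        x = np.full(10, 90.0)
        assert np.array_equal(hampel_clean(x), x)

    def test_gross_outlier_flagged(self):
        x = np.array([80, 82, 81, 83, 200, 79], dtype=float)
        out = hampel_clean(x)
        # median 81.5, MAD 1.5 -> fence 7.5; only 200 exceeds it
        assert np.isnan(out[4])
        assert np.isfinite(out[[0, 1, 2, 3, 5]]).all()

    def test_boundary_value_survives(self):
        # value exactly at median + 5*MAD is retained (strict inequality)
        x = np.array([10.0, 10, 11, 9, 12, 8, 10 + 5 * 1.0])
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        assert x[-1] == med + 5 * mad
        assert np.isfinite(hampel_clean(x)).all()

    def test_survivors_unchanged(self, rng):
        x = rng.normal(85, 8, size=200)
        out = hampel_clean(x)
        ok = np.isfinite(out)
        assert np.array_equal(out[ok], x[ok])

    def test_spike_on_flat_trace_flagged(self):
        x = np.full(40, 90.0)
        x[17] += 80.0
        out = hampel_clean(x)
        assert np.isnan(out[17]) and np.isfinite(np.delete(out, 17)).all()

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            hampel_clean(np.array([np.nan, np.nan, np.nan]))


class TestGapRule:
    def test_small_gaps_kept(self):
        t = np.arange(0, 3600, 180)
        keep, _ = gap_exclude(t, np.full(len(t), 80.0))
        assert keep

    def test_interior_gap_rejects(self):
        t = np.array([0, 180, 360, 360 + 720, 360 + 900])  # 12-min interior gap
        keep, reason = gap_exclude(t, np.full(5, 80.0))
        assert not keep and reason == GAP_GT_10MIN

    def test_leading_gap_exempt(self):
        # the 12-min gap is before the first non-missing value only
        t = np.array([0, 720, 900, 1080, 1260])
        v = np.array([np.nan, 80.0, 81, 82, 83])
        keep, _ = gap_exclude(t, v)
        assert keep

    def test_trailing_gap_exempt(self):
        t = np.array([0, 180, 360, 540, 1500])
        v = np.array([80.0, 81, 82, 83, np.nan])
        keep, _ = gap_exclude(t, v)
        assert keep

    def test_flagged_points_count_as_missing(self):
        # removing the middle point opens a 12-min hole
        t = np.array([0, 360, 720])
        v = np.array([80.0, np.nan, 82])
        keep, reason = gap_exclude(t, v)
        assert not keep and reason == GAP_GT_10MIN


class TestLoess:
    def test_identity_without_missing(self):
        t = np.arange(0, 1800, 180, dtype=float)
        v = np.sin(t / 400) * 5 + 80
        assert np.array_equal(loess_impute(t, v), v)

    def test_linear_ramp_recovered_exactly(self):
        t = np.arange(0, 3600, 180, dtype=float)
        v = 60 + 0.01 * t
        v2 = v.copy()
        v2[7] = np.nan
        out = loess_impute(t, v2)
        assert abs(out[7] - v[7]) < 1e-6

    def test_sinusoid_against_dense_reference(self, rng):
        # imputation error bounded by the error of a reference loess fitted
        # on the complete series and evaluated at the same points
        from statsmodels.nonparametric.smoothers_lowess import lowess
        t = np.arange(0, 7200, 120, dtype=float)
        v = 80 + 8 * np.sin(t / 900)
        miss = rng.choice(len(t), size=len(t) // 10, replace=False)
        v2 = v.copy()
        v2[miss] = np.nan
        out = loess_impute(t, v2)
        ref = lowess(v, t, frac=0.4, it=0, xvals=t[miss])
        err = np.abs(out[miss] - v[miss]).max()
        ref_err = np.abs(ref - v[miss]).max()
        assert err <= ref_err * 1.5 + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_impute(np.arange(4.0), np.array([1.0, np.nan, 3, 4]))


class TestResample:
    def test_knots_reproduced(self):
        t = np.arange(0, 600, 30, dtype=float)
        v = np.cos(t / 100) * 10 + 80
        gt, gv = resample_30s(t, v)
        assert np.allclose(gt, t)
        assert np.allclose(gv, v)

    def test_monotone_preserved(self):
        t = np.array([0, 200, 350, 700, 1000], dtype=float)
        v = np.array([60, 62, 70, 71, 90], dtype=float)
        _, gv = resample_30s(t, v)
        assert np.all(np.diff(gv) >= -1e-12)
        assert gv.min() >= 60 - 1e-12 and gv.max() <= 90 + 1e-12

    def test_three_point_hermite_closed_form(self):
        # symmetric data -> pchip slope at the middle knot is the harmonic
        # mean construction; evaluate the cubic Hermite basis by hand
        t = np.array([0.0, 60.0, 120.0])
        v = np.array([0.0, 30.0, 40.0])
        # endpoint-interior slopes
        d0 = (30 - 0) / 60      # 0.5
        d1 = (40 - 30) / 60     # 1/6
        # pchip interior slope: weighted harmonic mean (equal spacing -> w1=w2)
        m1 = 2 / (1 / d0 + 1 / d1)
        gt, gv = resample_30s(t, v)
        # evaluate at t=30 via Hermite basis on [0, 60]
        # endpoint slope (scipy one-sided three-point rule)
        m0 = ((2 * 60 + 60) * d0 - 60 * d1) / (60 + 60)
        if np.sign(m0) != np.sign(d0):
            m0 = 0.0
        s = 0.5  # normalized position of t=30
        h00, h10, h01, h11 = (2 * s**3 - 3 * s**2 + 1, s**3 - 2 * s**2 + s,
                              -2 * s**3 + 3 * s**2, s**3 - s**2)
        expected = h00 * 0 + h10 * 60 * m0 + h01 * 30 + h11 * 60 * m1
        assert abs(gv[1] - expected) < 1e-9

    def test_grid_length(self):
        t = np.array([0.0, 95.0, 200.0, 310.0])
        v = np.array([80.0, 81, 82, 83])
        gt, _ = resample_30s(t, v)
        assert len(gt) == int((310 - 0) // 30) + 1

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            resample_30s(np.array([0.0]), np.array([80.0]))


class TestEndToEnd:
    def _flat_patient(self, pid=1, n=40, dt=180):
        recs = []
        for i in range(n):
            t = i * dt
            recs += [(pid, t, "SAP", 120.0), (pid, t, "DAP", 70.0), (pid, t, "MAP", 86.0)]
        return make_raw(recs)

    def test_pp_identity_on_grid(self, clean_small_cohort):
        kept, _ = clean_small_cohort
        assert kept
        for trace in kept.values():
            assert np.array_equal(trace.pp, trace.sap - trace.dap)
            assert np.all(np.diff(trace.grid_t) == 30.0)

    def test_idempotence_on_clean_trace(self):
        raw = self._flat_patient()
        t1 = clean_patient(raw)
        # feed the cleaned grid back through the chain
        recs = []
        for t, s, d, m in zip(t1.grid_t, t1.sap, t1.dap, t1.map_):
            recs += [(1, int(t), "SAP", s), (1, int(t), "DAP", d), (1, int(t), "MAP", m)]
        t2 = clean_patient(make_raw(recs))
        assert np.allclose(t1.sap[: len(t2.sap)], t2.sap)
        assert np.allclose(t1.map_[: len(t2.map_)], t2.map_)

    def test_planted_spike_removed(self):
        raw = self._flat_patient()
        idx = (raw["signal"] == "MAP") & (raw["t_seconds"] == 180 * 20)
        raw.loc[idx, "value_mmHg"] += 80.0
        trace = clean_patient(raw)
        assert not trace.excluded
        assert trace.map_.max() < 100.0  # spike imputed away

    def test_false_positive_rate_below_one_percent(self, small_cohort):
        # artifact-free simulation: Hampel should flag almost nothing
        from apclust import SimConfig, generate_cohort
        c = generate_cohort(SimConfig(n_patients=40, seed=9, artifact_rate=0.0, gap_rate=0.0))
        total = flagged = 0
        for pid, grp in c.traces.groupby("patient_id"):
            for sig in ("SAP", "DAP", "MAP"):
                v = grp.loc[grp["signal"] == sig, "value_mmHg"].to_numpy()
                out = hampel_clean(v)
                total += len(v)
                flagged += int(np.isnan(out).sum())
        assert flagged / total < 0.01

    def test_exclusion_log_reasons(self, clean_small_cohort):
        _, log = clean_small_cohort
        assert set(log["reason"]) <= {"GAP_GT_10MIN", "TOO_FEW_POINTS", "ALL_MISSING"}
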