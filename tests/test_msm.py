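"""Weighted Cox engine, MSM model objects, multiplicity correction."""

import os
import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rxmsm._coxengine import fit_cox, schoenfeld_test
from rxmsm.msm import MarginalStructuralCox, bh_adjust, refit_reference

from oracles import bh_stepup


def _sim_counting_data(seed=1, n=400, tie_grid=5):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        t0 = 0.0
        x = rng.normal(size=2)
        for _ in range(rng.integers(1, 4)):
            t1 = t0 + rng.integers(1, 20)
            ev = rng.random() < 0.15
            rows.append((i, t0, t1, int(ev), x[0] + rng.normal() * 0.3, x[1],
                         round(rng.uniform(0.5, 2.0), 2)))
            t0 = t1
            if ev:
                break
    df = pd.DataFrame(rows, columns=["id", "start", "stop", "event",
                                     "x1", "x2", "w"])
    if tie_grid:
        df["stop"] = np.ceil(df["stop"] / tie_grid) * tie_grid
    return df[df.stop > df.start].reset_index(drop=True)


class TestCoxEngine:
    def test_matches_r_survival_with_ties_weights_clusters(self):
        """Coefficients and both variance estimators agree with coxph."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = _sim_counting_data()
        fit = fit_cox(df[["x1", "x2"]].to_numpy(), df.start, df.stop,
                      df.event.astype(bool), df.w,
                      cluster=df["id"].to_numpy())
        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "d.csv")
            df.to_csv(path, index=False)
            out = subprocess.run(
                ["Rscript", "-e", f'''
                 d <- read.csv("{path}"); library(survival)
                 f <- coxph(Surv(start,stop,event)~x1+x2+cluster(id), data=d,
                            weights=w, ties="efron")
                 cat(coef(f), sqrt(diag(f$naive.var)), sqrt(diag(f$var)))'''],
                capture_output=True, text=True, check=True)
            vals = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(fit.params, vals[:2], atol=1e-6)
        assert np.allclose(np.sqrt(np.diag(fit.cov)), vals[2:4], atol=1e-6)
        assert np.allclose(np.sqrt(np.diag(fit.cov_robust)), vals[4:6],
                           atol=1e-6)

    def test_matches_lifelines_time_varying_point_estimates(self):
        lifelines = pytest.importorskip("lifelines")
        df = _sim_counting_data(seed=2, tie_grid=None)
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(df.rename(columns={"w": "weights"}),
                id_col="id", event_col="event", start_col="start",
                stop_col="stop", weights_col="weights")
        fit = fit_cox(df[["x1", "x2"]].to_numpy(), df.start, df.stop,
                      df.event.astype(bool), df.w, robust=False)
        assert np.allclose(fit.params, ctv.params_.to_numpy(), atol=1e-5)

    def test_invalid_inputs_rejected(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError, match="start < stop"):
            fit_cox(X, [0, 0, 0, 0, 5], [1, 1, 1, 1, 5],
                    [1, 0, 0, 0, 1], None)
        with pytest.raises(ValueError, match="no events"):
            fit_cox(X, np.zeros(5), np.ones(5), np.zeros(5, bool), None)
        with pytest.raises(ValueError, match="weights"):
            fit_cox(X, np.zeros(5), np.ones(5), np.ones(5, bool),
                    np.array([1, 1, 0, 1, 1.0]))


class TestProportionalHazards:
    def test_calibrated_under_proportional_hazards(self):
        # under a proportional effect the identity-transform test should not
        # reject at a high rate
        rejections = 0
        for seed in range(25):
            df = _sim_counting_data(seed=100 + seed, n=250, tie_grid=None)
            fit = fit_cox(df[["x1", "x2"]].to_numpy(), df.start, df.stop,
                          df.event.astype(bool), robust=False)
            res = schoenfeld_test(fit)
            rejections += res["global_p"] < 0.05
        assert rejections <= 5

    def test_detects_time_varying_effect(self):
        # effect that reverses sign over time yields a strong rejection
        rng = np.random.default_rng(7)
        n = 3000
        x = rng.normal(size=n)
        rows = []
        for i in range(n):
            t, dead = 0.0, False
            while t < 40 and not dead:
                beta = 0.8 if t < 20 else -0.8
                lam = 0.02 * np.exp(beta * x[i])
                gap = rng.exponential(1 / lam)
                if t + gap < min(t + 10, 40):
                    rows.append((i, t, t + gap, 1, x[i]))
                    dead = True
                else:
                    rows.append((i, t, min(t + 10, 40), 0, x[i]))
                    t += 10
        df = pd.DataFrame(rows, columns=["id", "start", "stop", "event", "x"])
        fit = fit_cox(df[["x"]].to_numpy(), df.start, df.stop,
                      df.event.astype(bool), robust=False)
        res = schoenfeld_test(fit)
        assert res["global_p"] < 0.01


class TestMsmModel:
    def test_unit_weights_equal_unweighted_fit(self, small_result):
        ap = small_result.analysis_periods["death"].copy()
        ap["ones"] = 1.0
        unit = MarginalStructuralCox(ap, weight_col="ones").fit()
        unweighted = MarginalStructuralCox(ap, weight_col=None).fit()
        assert np.allclose(unit.fit.params, unweighted.fit.params)
        assert np.allclose(unit.fit.cov_robust, unweighted.fit.cov_robust)

    def test_reference_recoding_identity(self, small_result):
        ap = small_result.analysis_periods["death"]
        base = MarginalStructuralCox(ap, weight_col="w_total")
        never_fit = base.fit()
        recoded = refit_reference(base, "recent_inconsistent")
        hr_cons = never_fit.estimates.loc["llt:consistent", "log_hr"]
        hr_rec = never_fit.estimates.loc["llt:recent_inconsistent", "log_hr"]
        got = recoded.estimates.loc["llt:consistent", "log_hr"]
        assert got == pytest.approx(hr_cons - hr_rec, abs=1e-6)

    def test_reference_never_reproduces_original(self, small_result):
        ap = small_result.analysis_periods["death"]
        base = MarginalStructuralCox(ap, weight_col="w_total")
        a = base.fit()
        b = refit_reference(base, "never")
        assert np.allclose(a.fit.params, b.fit.params, atol=1e-10)

    def test_single_level_data_rejected(self):
        df = pd.DataFrame({
            "pid": np.arange(20), "start": 0.0, "stop": 1.0,
            "event": [True] * 5 + [False] * 15,
            "llt_level": 0, "aht_level": 0, "asa_level": 0,
        })
        with pytest.raises(ValueError, match="single exposure level"):
            MarginalStructuralCox(df, weight_col=None)

    def test_unknown_reference_rejected(self, small_result):
        ap = small_result.analysis_periods["death"]
        with pytest.raises(ValueError, match="unknown reference"):
            MarginalStructuralCox(ap, reference="sometimes")

    def test_zero_event_level_reported_undefined(self):
        rng = np.random.default_rng(8)
        n = 300
        df = pd.DataFrame({
            "pid": np.arange(n), "start": 0.0,
            "stop": rng.uniform(1, 10, n),
            "event": rng.random(n) < 0.3,
            "llt_level": rng.choice([0, 2], n),
            "aht_level": 0, "asa_level": 0,
        })
        # add a remote stratum that never has events
        df.loc[df.index[:20], "llt_level"] = 1
        df.loc[df.index[:20], "event"] = False
        res = MarginalStructuralCox(df, weight_col=None).fit()
        row = res.estimates.loc["llt:remote"]
        assert np.isnan(row["hr"]) and row["n_events"] == 0

    def test_summary_mentions_reference(self, small_result):
        s = small_result.results["death"].summary()
        assert "reference level: never" in s

    def test_event_counts_match_data(self, small_result):
        ap = small_result.analysis_periods["death"]
        res = small_result.results["death"]
        for term in res.terms:
            grp, level = term.split(":")[:2]
            from rxmsm.config import LEVEL_CODES
            mask = ap[f"{grp}_level"].to_numpy() == LEVEL_CODES[level]
            n_ev = int((ap["event"].to_numpy() & mask).sum())
            assert res.estimates.loc[term, "n_events"] == n_ev


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("raw,expected", [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.001, 0.5, 0.9), (0.003, 0.75, 0.9)),
    ])
    def test_hand_computed_stepup_values(self, raw, expected):
        assert np.allclose(bh_adjust(list(raw)), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_independent_stepup_and_dominates_raw(self, ps):
        adj = bh_adjust(ps)
        want = bh_stepup(ps)
        assert np.allclose(adj, want)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
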