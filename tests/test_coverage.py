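"""Pill-stock coverage reconstruction and trailing-year PDC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rxmsm.config import CoverageRules, GridSpec
from rxmsm.coverage import (
    build_coverage,
    compute_haart_adherence,
    compute_pdc,
    coverage_matrix,
    cumulative_coverage,
    pdc_at,
)
from rxmsm import io as rio

from conftest import make_fills, make_stays
from oracles import brute_force_coverage, brute_force_pdc


def _single(fills, stays=(), horizon=200, **kw):
    return build_coverage(make_fills(fills), make_stays(stays), "statin",
                          horizon=horizon, **kw)


class TestBuildCoverage:
    def test_no_fills_all_uncovered(self):
        cov = _single([], horizon=50)
        assert not cov.any()

    def test_early_refill_stacks_to_sixty_days(self):
        # two 30-day fills of the same drug on days 0 and 25: the 5 unused
        # days carry over, so days 0-59 are covered
        cov = _single([(0, 30, "simvastatin", "statin"),
                       (25, 30, "simvastatin", "statin")])
        assert cov[:60].all() and not cov[60:].any()

    def test_hospital_stay_pauses_stock(self):
        # a 30-day fill with a 10-day admission inside it covers 40 days
        cov = _single([(0, 30, "simvastatin", "statin")],
                      stays=[(10, 19)])
        assert cov[:40].all() and not cov[40:].any()

    def test_switch_resets_stock(self):
        # switching drugs inside the class does not stack remaining supply
        cov = _single([(0, 30, "simvastatin", "statin"),
                       (10, 30, "atorvastatin", "statin")])
        assert cov[:40].all() and not cov[40:].any()

    def test_stockpile_cap_limits_carryover(self):
        rules = CoverageRules(stock_cap_days=5)
        cov = _single([(0, 30, "s", "statin"), (10, 30, "s", "statin")],
                      rules=rules)
        # carry-over is capped at 5 of the 20 remaining days
        assert cov[:45].all() and not cov[45:].any()

    def test_incompatible_class_truncates(self):
        rules = CoverageRules(incompatible={"fibrate": frozenset({"statin"})})
        cov = _single([(0, 60, "s", "statin"), (20, 30, "f", "fibrate")],
                      rules=rules)
        assert cov[:20].all() and not cov[20:].any()

    def test_fill_after_exit_rejected(self):
        with pytest.raises(ValueError, match="after patient exit"):
            _single([(100, 30, "s", "statin")], exit_day=50)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown drug class"):
            _single([(0, 30, "x", "mystery")], known_classes={"statin"})

    def test_zero_supply_rejected(self):
        with pytest.raises(ValueError, match="days_supply"):
            _single([(0, 0, "s", "statin")])


@st.composite
def fill_schedules(draw):
    n_fills = draw(st.integers(1, 8))
    fills = [(draw(st.integers(0, 250)), draw(st.integers(1, 60)),
              draw(st.sampled_from(["a", "b"])), "statin")
             for _ in range(n_fills)]
    n_stays = draw(st.integers(0, 3))
    stays = []
    for _ in range(n_stays):
        a = draw(st.integers(0, 280))
        stays.append((a, a + draw(st.integers(0, 20))))
    cap = draw(st.sampled_from([5, 30, 90]))
    return fills, stays, cap


class TestOracleEquivalence:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(fill_schedules())
    def test_matches_day_by_day_stock_simulation(self, sched):
        fills, stays, cap = sched
        horizon = 400
        rules = CoverageRules(stock_cap_days=cap)
        # distinct fill days keep the processing order unambiguous
        seen, uniq = set(), []
        for d, s, g, c in fills:
            if d not in seen:
                seen.add(d)
                uniq.append((d, s, g, c))
        got = build_coverage(make_fills(uniq), make_stays(stays), "statin",
                             rules=rules, horizon=horizon)
        want = brute_force_coverage([(d, s, g) for d, s, g, _ in uniq],
                                    stays, horizon, cap=cap)
        assert np.array_equal(got, want)

    def test_batch_matrix_equals_single_patient(self):
        rng = np.random.default_rng(3)
        frames = []
        horizon = 300
        for pid in range(20):
            days = np.sort(rng.choice(250, size=rng.integers(1, 6),
                                      replace=False))
            for d in days:
                frames.append({"patient_id": pid + 1, "pid": pid,
                               "fill_day": int(d),
                               "days_supply": int(rng.integers(1, 60)),
                               "drug_code": rng.choice(["a", "b"]),
                               "drug_class": "statin"})
        fills = pd.DataFrame(frames)
        mat = coverage_matrix(fills, None, 20, horizon)
        for pid in range(20):
            single = build_coverage(fills[fills.pid == pid],
                                    make_stays([]), "statin", horizon=horizon)
            assert np.array_equal(mat[pid], single)


class TestPdc:
    def test_fully_covered_year_is_one(self):
        cov = np.ones(800, dtype=bool)
        df = compute_pdc(cov, entry=400, exit_day=500)
        assert np.allclose(df["pdc"], 1.0)

    def test_330_of_365_days(self):
        cov = np.zeros(800, dtype=bool)
        cov[500 - 330 + 1:501] = True
        df = compute_pdc(cov, entry=500, exit_day=500)
        assert df["pdc"].iloc[0] == pytest.approx(330 / 365)

    def test_elapsed_denominator_before_full_year(self):
        # anchor 100 days after the start of observation, 50 covered days
        cov = np.zeros(200, dtype=bool)
        cov[1:51] = True
        df = compute_pdc(cov, entry=100, exit_day=100, obs_start=0)
        assert df["pdc"].iloc[0] == pytest.approx(0.5)

    def test_anchor_before_observation_rejected(self):
        with pytest.raises(ValueError, match="anchor before"):
            pdc_at(cumulative_coverage(np.ones(10, bool)), [0], [-5],
                   obs_start=0)

    def test_event_days_join_the_grid(self):
        cov = np.ones(400, dtype=bool)
        df = compute_pdc(cov, entry=0, exit_day=100, event_days=[33])
        assert 33 in set(df["anchor_day"])

    def test_matches_direct_count_on_random_calendars(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            cov = rng.random(900) < 0.4
            anchor = int(rng.integers(10, 900))
            got = pdc_at(cumulative_coverage(cov), [0], [anchor])[0]
            assert got == pytest.approx(brute_force_pdc(cov, anchor))

    def test_weekly_change_bounded(self):
        # trailing-year PDC moves by at most 1/365 per day
        rng = np.random.default_rng(4)
        cov = rng.random(900) < 0.5
        C = cumulative_coverage(cov)
        days = np.arange(366, 900)
        pdc = pdc_at(C, np.zeros(len(days), np.int64), days)
        assert np.all(np.abs(np.diff(pdc)) <= 1 / 365 + 1e-12)

    def test_hospitalization_never_decreases_pdc(self, small_cohort):
        fills = make_fills([(0, 30, "s", "statin"), (40, 30, "s", "statin")])
        base = build_coverage(fills, make_stays([]), "statin", horizon=500)
        with_stay = build_coverage(fills, make_stays([(50, 70)]), "statin",
                                   horizon=500)
        Cb, Cs = cumulative_coverage(base), cumulative_coverage(with_stay)
        days = np.arange(500)
        rows = np.zeros(500, np.int64)
        assert np.all(pdc_at(Cs, rows, days) >= pdc_at(Cb, rows, days) - 1e-12)


class TestHaart:
    def _agents(self, cov_by_agent, horizon=800):
        return {a: np.asarray(c, dtype=bool) for a, c in cov_by_agent.items()}

    def test_full_combo_all_year(self):
        cov = np.ones(800, dtype=bool)
        agents = {"tdf": cov, "ftc": cov, "efv": cov}
        df = compute_haart_adherence(agents, [frozenset({"tdf", "ftc", "efv"})],
                                     entry=400, exit_day=500)
        assert np.allclose(df["haart_pdc"], 1.0)

    def test_two_of_three_agents_is_zero(self):
        cov = np.ones(800, dtype=bool)
        agents = {"tdf": cov, "ftc": cov, "efv": np.zeros(800, bool)}
        df = compute_haart_adherence(agents, [frozenset({"tdf", "ftc", "efv"})],
                                     entry=400, exit_day=500)
        assert np.allclose(df["haart_pdc"], 0.0)

    def test_partial_combo_coverage(self):
        cov = np.zeros(800, dtype=bool)
        cov[500 - 200 + 1:501] = True
        agents = {"tdf": cov, "ftc": cov, "efv": cov}
        df = compute_haart_adherence(agents, [frozenset({"tdf", "ftc", "efv"})],
                                     entry=500, exit_day=500)
        assert df["haart_pdc"].iloc[0] == pytest.approx(200 / 365)

    def test_empty_combos_rejected(self):
        with pytest.raises(ValueError, match="accepted_combos"):
            compute_haart_adherence({"tdf": np.ones(10, bool)}, [], 0, 5)


class TestTableRoundTrip:
    def test_cohort_tables_round_trip(self, small_cohort, tmp_path):
        rio.write_tables(small_cohort.tables, str(tmp_path))
        back = rio.read_tables(str(tmp_path))
        for name, cols in rio.TABLES.items():
            a = small_cohort.tables[name][cols].reset_index(drop=True)
            b = back[name][cols].reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_empty_cohort_writes_headers(self, tmp_path):
        rio.write_tables({}, str(tmp_path))
        back = rio.read_tables(str(tmp_path))
        assert all(len(df) == 0 for df in back.values())
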