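"""Day-level drug coverage from refill records, and trailing one-year PDC.

The day-to-day exposure model is a pill-stock simulation: each pharmacy fill
adds its days supply to a per-class stock, every outpatient day consumes one
day of stock, hospital days are covered without consuming stock, a fill of a
different drug within the same class resets the stock (switching does not
stack across drugs), and same-drug early refills stack up to a carry-over cap.

Two implementations are provided: :func:`build_coverage` for a single
patient/class (the reference implementation, supporting the full rule set
including incompatible-class truncation) and :func:`coverage_matrix`, a
vectorized builder producing an ``(n_patients, horizon)`` boolean matrix for
a whole cohort at once.  Both share the same interval arithmetic; a
day-by-day brute-force simulator in the test suite serves as their oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CoverageRules, GridSpec, YEAR_DAYS

__all__ = [
    "hospital_cumsum",
    "coverage_matrix",
    "build_coverage",
    "cumulative_coverage",
    "window_count",
    "pdc_at",
    "compute_pdc",
    "combo_coverage",
    "compute_haart_adherence",
]


def hospital_cumsum(stays: pd.DataFrame, n_patients: int, horizon: int,
                    pid_col: str = "pid") -> np.ndarray:
    """(n, horizon+1) prefix sums of the inpatient-day indicator.

    ``stays`` must carry integer columns ``pid`` (0..n-1), ``admit_day`` and
    ``discharge_day``; a stay occupies days admit..discharge inclusive.
    """
    acc = np.zeros((n_patients, horizon + 1), dtype=np.int32)
    if len(stays):
        pid = stays[pid_col].to_numpy()
        a = np.clip(stays["admit_day"].to_numpy(), 0, horizon)
        d = np.clip(stays["discharge_day"].to_numpy() + 1, 0, horizon)
        np.add.at(acc, (pid, a), 1)
        np.add.at(acc, (pid, d), -1)
    inpatient = np.cumsum(acc[:, :-1], axis=1) > 0
    out = np.zeros((n_patients, horizon + 1), dtype=np.int32)
    np.cumsum(inpatient, axis=1, out=out[:, 1:])
    return out


def _stock_intervals(pid, day, supply, drug, hosp_cum, horizon, cap):
    """Vectorized pill-stock scan over fills sorted by (pid, day).

    Returns per-fill half-open coverage intervals [day, exhaust) already
    extended for hospital pauses.  One chain per patient (fills must belong
    to one drug class).
    """
    order = np.lexsort((day, pid))
    pid, day, supply, drug = pid[order], day[order], supply[order], drug[order]
    n_fills = len(pid)
    starts = np.empty(n_fills, dtype=np.int64)
    ends = np.empty(n_fills, dtype=np.int64)

    # position of each fill within its patient's chain
    first_of_chain = np.ones(n_fills, dtype=bool)
    first_of_chain[1:] = pid[1:] != pid[:-1]

    H = horizon
    hc = hosp_cum

    def hosp_between(p, a, b):
        a = np.clip(a, 0, H)
        b = np.clip(b, 0, H)
        return hc[p, b] - hc[p, a]

    # sequential scan over chain position, vectorized across patients
    chain_pos = np.zeros(n_fills, dtype=np.int64)
    idx = np.arange(n_fills)
    chain_start_idx = idx[first_of_chain]
    # compute position within chain
    chain_id = np.cumsum(first_of_chain) - 1
    chain_pos = idx - chain_start_idx[chain_id]
    max_len = int(chain_pos.max()) + 1 if n_fills else 0

    n_chains = len(chain_start_idx)
    prev_d0 = np.zeros(n_chains, dtype=np.int64)
    prev_s0 = np.zeros(n_chains, dtype=np.int64)
    prev_drug = np.full(n_chains, -1, dtype=np.int64)
    has_prev = np.zeros(n_chains, dtype=bool)

    for k in range(max_len):
        sel = idx[chain_pos == k]
        ch = chain_id[sel]
        d, s, g, p = day[sel], supply[sel], drug[sel], pid[sel]
        # remaining same-drug supply at the fill date (hospital days do not consume)
        elapsed_outpatient = (d - prev_d0[ch]) - hosp_between(p, prev_d0[ch], d)
        rem = np.maximum(prev_s0[ch] - elapsed_outpatient, 0)
        same = has_prev[ch] & (g == prev_drug[ch])
        carry = np.where(same, np.minimum(rem, cap), 0)
        s0 = s + carry
        # exhaust day: d + s0 outpatient days, extended by overlapped
        # hospital days; the fixed point grows monotonically and is bounded
        # by the patient's total inpatient time
        e = d + s0
        while True:
            e_new = d + s0 + hosp_between(p, d, e)
            if np.array_equal(e_new, e):
                break
            e = e_new
        starts[sel] = d
        ends[sel] = e
        prev_d0[ch] = d
        prev_s0[ch] = s0
        prev_drug[ch] = g
        has_prev[ch] = True

    # every fill restates the stock, so the predecessor's interval cannot
    # run past the fill date (switches reset it; the cap binds at refills)
    if n_fills > 1:
        same_chain = pid[1:] == pid[:-1]
        trunc = np.minimum(ends[:-1][same_chain], day[1:][same_chain])
        ends[:-1][same_chain] = trunc
    return pid, starts, ends


def coverage_matrix(fills: pd.DataFrame, stays: pd.DataFrame | None,
                    n_patients: int, horizon: int,
                    rules: CoverageRules = CoverageRules(),
                    hosp_cum: np.ndarray | None = None,
                    inpatient: np.ndarray | None = None) -> np.ndarray:
    """Boolean (n_patients, horizon) coverage matrix for one drug class.

    ``fills`` must be restricted to a single drug class and carry integer
    columns ``pid``, ``fill_day``, ``days_supply`` and ``drug_code``.
    """
    if rules.incompatible:
        raise NotImplementedError(
            "incompatible-class truncation is supported only in build_coverage"
        )
    cov = np.zeros((n_patients, horizon), dtype=bool)
    if not len(fills):
        return cov
    if (fills["days_supply"] < 1).any():
        raise ValueError("days_supply must be >= 1")
    if hosp_cum is None:
        hosp_cum = hospital_cumsum(
            stays if stays is not None else pd.DataFrame(), n_patients, horizon
        )
    drug_codes = pd.factorize(fills["drug_code"])[0].astype(np.int64)
    pid, starts, ends = _stock_intervals(
        fills["pid"].to_numpy(np.int64),
        fills["fill_day"].to_numpy(np.int64),
        fills["days_supply"].to_numpy(np.int64),
        drug_codes, hosp_cum, horizon, rules.stock_cap_days,
    )
    # work on the subset of patients with any fill of this class
    upids = np.unique(pid)
    row = np.searchsorted(upids, pid)
    acc = np.zeros((len(upids), horizon + 1), dtype=np.int16)
    s = np.clip(starts, 0, horizon)
    e = np.clip(ends, 0, horizon)
    np.add.at(acc, (row, s), 1)
    np.add.at(acc, (row, e), -1)
    sub = np.cumsum(acc[:, :-1], axis=1, dtype=np.int16) > 0
    if rules.inpatient_covered:
        inp = inpatient[upids] if inpatient is not None \
            else np.diff(hosp_cum[upids], axis=1) > 0
        # inpatient days count as covered from the first class fill onward
        first_fill = np.full(len(upids), horizon, dtype=np.int64)
        np.minimum.at(first_fill, row, starts)
        after_first = np.arange(horizon)[None, :] >= first_fill[:, None]
        sub |= inp & after_first
    cov[upids] = sub
    return cov


def build_coverage(fills: pd.DataFrame, stays: pd.DataFrame,
                   drug_class: str, rules: CoverageRules = CoverageRules(),
                   horizon: int | None = None,
                   known_classes: set | None = None,
                   exit_day: int | None = None) -> np.ndarray:
    """Coverage calendar (boolean day vector) for one patient and drug class.

    ``fills`` may contain fills of other classes; only rows of ``drug_class``
    contribute stock, but classes configured as incompatible with
    ``drug_class`` truncate its stock at their fill dates.
    """
    if known_classes is not None:
        unknown = set(fills["drug_class"]) - set(known_classes)
        if unknown:
            raise ValueError(f"unknown drug class(es): {sorted(unknown)}")
    if exit_day is not None and len(fills) and (fills["fill_day"] > exit_day).any():
        raise ValueError("fill after patient exit")
    cls_fills = fills[fills["drug_class"] == drug_class]
    if horizon is None:
        last = 0
        if len(cls_fills):
            last = int((cls_fills["fill_day"] + cls_fills["days_supply"]).max()) + 90
        horizon = max(last, int(exit_day) + 1 if exit_day is not None else 1)
    f = cls_fills.copy()
    f["pid"] = 0
    st = stays.copy()
    if len(st):
        st["pid"] = 0
    base = CoverageRules(
        stock_cap_days=rules.stock_cap_days,
        switch_resets=rules.switch_resets,
        inpatient_covered=rules.inpatient_covered,
    )
    cov = coverage_matrix(f, st, 1, horizon, base)[0]
    # incompatible-class truncation: a fill of a trigger class clears this
    # class's stock until its own next fill
    triggers = [c for c, targets in rules.incompatible.items()
                if drug_class in targets]
    if triggers and len(cls_fills):
        own_days = np.sort(cls_fills["fill_day"].to_numpy(np.int64))
        trig_days = fills.loc[fills["drug_class"].isin(triggers), "fill_day"]
        for t in np.sort(trig_days.to_numpy(np.int64)):
            nxt = own_days[own_days > t]
            stop = int(nxt[0]) if len(nxt) else horizon
            cov[t:stop] = False
    return cov


def cohort_coverage(fills: pd.DataFrame, stays: pd.DataFrame,
                    n_patients: int, horizon: int,
                    rules: CoverageRules = CoverageRules()) -> dict:
    """Per-class and per-group coverage matrices for a whole cohort.

    ``fills`` needs integer columns ``pid``, ``fill_day``, ``days_supply``
    plus ``drug_code`` and ``drug_class``.  Antiretroviral agents (class
    ``arv``) keep stock per agent (keyed by drug code); all other classes
    keep stock per class.  Returns a dict with one boolean matrix per class
    (or ARV agent, prefixed ``arv:``) and the three class-group unions
    ``llt``, ``aht``, ``asa`` plus ``statin`` and ``nonstatin_llt``.
    """
    from .config import AHT_CLASSES, ASA_CLASSES, LLT_CLASSES, NS_LLT_CLASSES

    hosp = hospital_cumsum(stays, n_patients, horizon)
    inpatient = np.diff(hosp, axis=1) > 0
    out = {}
    non_arv = fills[fills["drug_class"] != "arv"]
    for cls, sub in non_arv.groupby("drug_class", sort=True):
        out[cls] = coverage_matrix(sub, None, n_patients, horizon, rules, hosp,
                                   inpatient)
    arv = fills[fills["drug_class"] == "arv"]
    for code, sub in arv.groupby("drug_code", sort=True):
        out[f"arv:{code}"] = coverage_matrix(sub, None, n_patients, horizon,
                                             rules, hosp, inpatient)

    def union(classes):
        mats = [out[c] for c in classes if c in out]
        if not mats:
            return np.zeros((n_patients, horizon), dtype=bool)
        return np.logical_or.reduce(mats)

    out["statin"] = out.get("statin", np.zeros((n_patients, horizon), dtype=bool))
    out["nonstatin_llt"] = union(NS_LLT_CLASSES)
    out["llt"] = out["statin"] | out["nonstatin_llt"]
    out["aht"] = union(AHT_CLASSES)
    out["asa"] = union(ASA_CLASSES)
    return out


# ---------------------------------------------------------------------------
# Trailing-window adherence (PDC)
# ---------------------------------------------------------------------------

def cumulative_coverage(cov: np.ndarray) -> np.ndarray:
    """Prefix sums: out[..., k] = number of covered days with index < k."""
    cov = np.atleast_2d(cov)
    out = np.zeros((cov.shape[0], cov.shape[1] + 1), dtype=np.int32)
    np.cumsum(cov, axis=1, out=out[:, 1:])
    return out


def window_count(C: np.ndarray, rows, a, b) -> np.ndarray:
    """Covered days in the half-open day window (a, b] per (row, a, b) triple."""
    H = C.shape[1] - 1
    lo = np.clip(np.asarray(a) + 1, 0, H)
    hi = np.clip(np.asarray(b) + 1, 0, H)
    return C[rows, hi] - C[rows, lo]


def pdc_at(C: np.ndarray, rows, anchors, obs_start=0) -> np.ndarray:
    """Trailing one-year percent of days covered at each anchor day.

    The window is ``(anchor - 365, anchor]``; before one full year of
    observation the denominator is the number of observed days.
    """
    anchors = np.asarray(anchors, dtype=np.int64)
    start = np.asarray(obs_start, dtype=np.int64)
    if np.any(anchors < start):
        raise ValueError("anchor before start of observation")
    covered = window_count(C, rows, np.maximum(anchors - YEAR_DAYS, start - 1), anchors)
    denom = np.minimum(YEAR_DAYS, anchors - start)
    denom = np.maximum(denom, 1)
    return covered / denom


def anchor_grid(entry: int, exit_day: int, grid: GridSpec = GridSpec(),
                event_days=()) -> np.ndarray:
    """Weekly anchors from entry plus recorded event days, strictly increasing."""
    anchors = np.arange(entry, exit_day + 1, grid.interval_days, dtype=np.int64)
    extra = np.asarray([d for d in event_days if entry <= d <= exit_day],
                       dtype=np.int64)
    return np.unique(np.concatenate([anchors, extra]))


def compute_pdc(cov: np.ndarray, entry: int, exit_day: int,
                grid: GridSpec = GridSpec(), event_days=(),
                obs_start: int = 0) -> pd.DataFrame:
    """PDC series of one calendar on the weekly/event anchor grid.

    Returns a DataFrame with columns ``anchor_day``, ``pdc`` and
    ``last_covered_day`` (-1 if never covered up to the anchor).
    """
    if cov.ndim != 1 or cov.size < 1:
        raise ValueError("calendar must span at least one day")
    C = cumulative_coverage(cov)
    anchors = anchor_grid(entry, exit_day, grid, event_days)
    rows = np.zeros(len(anchors), dtype=np.int64)
    pdc = pdc_at(C, rows, anchors, obs_start)
    # last covered day <= anchor: searchsorted on covered-day positions
    covered_days = np.flatnonzero(cov)
    if len(covered_days):
        pos = np.searchsorted(covered_days, anchors, side="right") - 1
        last = np.where(pos >= 0, covered_days[np.maximum(pos, 0)], -1)
    else:
        last = np.full(len(anchors), -1, dtype=np.int64)
    return pd.DataFrame({"anchor_day": anchors, "pdc": pdc, "last_covered_day": last})


# ---------------------------------------------------------------------------
# HAART (combination ARV) adherence
# ---------------------------------------------------------------------------

def combo_coverage(agent_cov: dict, accepted_combos) -> np.ndarray:
    """Day is HAART-covered iff some accepted combination is fully covered."""
    combos = list(accepted_combos)
    if not combos:
        raise ValueError("accepted_combos must not be empty")
    out = None
    for combo in combos:
        missing = [a for a in combo if a not in agent_cov]
        if missing:
            continue
        mat = np.logical_and.reduce([agent_cov[a] for a in combo])
        out = mat if out is None else (out | mat)
    if out is None:
        any_cov = next(iter(agent_cov.values()))
        out = np.zeros_like(any_cov, dtype=bool)
    return out


def compute_haart_adherence(agent_cov: dict, accepted_combos,
                            entry: int, exit_day: int,
                            grid: GridSpec = GridSpec(), event_days=(),
                            obs_start: int = 0) -> pd.DataFrame:
    """Trailing one-year PDC of accepted ARV combinations (single patient)."""
    cov = combo_coverage(agent_cov, accepted_combos)
    cov = np.atleast_2d(cov)[0]
    df = compute_pdc(cov, entry, exit_day, grid, event_days, obs_start)
    return df.rename(columns={"pdc": "haart_pdc"})
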