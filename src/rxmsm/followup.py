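"""Follow-up definition, endpoint adjudication and person-period tables.

Follow-up begins at the first undetectable viral load and ends at the
earliest of death, loss of clinical follow-up (a care gap longer than 13
months, operationalized as 396 days), or the administrative end of data.
Death takes precedence over gap censoring whenever it occurs before the gap
completes (death records are registry-reconciled and observed even between
visits).

ASCVD diagnosis codes count as events only when corroborated by a procedure
code, a qualifying biomarker value, or a neuroimaging record within a
configurable window; uncorroborated codes are discarded to avoid events
without a well-defined day of onset.  Infection and cancer endpoints are the
first qualifying diagnosis code after enrolment, with configured exclusion
sets (e.g. cellulitis, simple urinary and upper-respiratory infections,
squamous and basal cell skin cancers) removed.

The counting-process realization splits each patient's follow-up at weekly
anchors (plus the event day); periods are half-open ``(start, stop]`` and an
event on a boundary belongs to the period ending there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AdjudicationConfig, EndpointCodes, FollowUpRules, GridSpec

__all__ = [
    "derive_followup",
    "adjudicate_ascvd",
    "first_endpoint",
    "collect_events",
    "build_person_periods",
]

ENDPOINTS = ("death", "ascvd_coronary", "ascvd_cerebrovascular", "ascvd_any",
             "infection", "cancer")


def derive_followup(viral_loads: pd.DataFrame, contacts: pd.DataFrame,
                    deaths: pd.DataFrame, admin_end: int,
                    rules: FollowUpRules = FollowUpRules()) -> pd.DataFrame:
    """Entry/exit/reason per patient; patients who never suppress are excluded.

    All frames carry integer ``pid`` and ``*_day`` columns.  ``contacts``
    should hold every dated care contact (fills, labs, viral loads, hospital
    admissions).  Returns one row per *included* patient with columns
    ``pid``, ``entry``, ``exit``, ``exit_reason``.
    """
    vl = viral_loads
    undet = vl[vl["copies_per_ml"] < rules.undetectable_copies]
    if not len(undet):
        return pd.DataFrame(columns=["pid", "entry", "exit", "exit_reason"])
    entry = undet.groupby("pid")["vl_day"].min()

    death = deaths.set_index("pid")["death_day"] if len(deaths) else pd.Series(
        dtype="int64")
    death = death.reindex(entry.index)

    c = contacts[["pid", "day"]].copy()
    c = c[c["pid"].isin(entry.index)]
    c["entry"] = entry.reindex(c["pid"]).to_numpy()
    c = c[(c["day"] >= c["entry"]) & (c["day"] <= admin_end)]
    c = pd.concat([c[["pid", "day"]],
                   pd.DataFrame({"pid": entry.index, "day": entry.to_numpy()})])
    c = c.drop_duplicates().sort_values(["pid", "day"])
    day = c["day"].to_numpy()
    pidc = c["pid"].to_numpy()
    new_grp = np.ones(len(c), dtype=bool)
    new_grp[1:] = pidc[1:] != pidc[:-1]
    gap_prev = np.empty(len(c), dtype=np.int64)
    gap_prev[new_grp] = 0
    gap_prev[~new_grp] = day[~new_grp] - day[np.flatnonzero(~new_grp) - 1]
    # first internal completed gap: censor candidate at the left contact
    exceed = gap_prev > rules.gap_days
    cand = pd.Series(np.where(exceed, day - gap_prev, np.iinfo(np.int64).max),
                     index=pidc)
    internal = cand[exceed[np.arange(len(c))]] if exceed.any() else pd.Series(
        dtype="int64")
    internal = internal.groupby(level=0).min() if len(internal) else internal
    last_contact = pd.Series(day, index=pidc).groupby(level=0).max()
    tail = last_contact[admin_end - last_contact > rules.gap_days]
    gap_cand = pd.concat([internal, tail]).groupby(level=0).min() \
        if (len(internal) or len(tail)) else pd.Series(dtype="int64")
    gap_cand = gap_cand.reindex(entry.index)

    big = np.int64(np.iinfo(np.int64).max // 4)
    g = gap_cand.fillna(big).astype(np.int64).to_numpy()
    d = death.fillna(big).astype(np.int64).to_numpy()
    e = entry.to_numpy()

    death_wins = d <= np.minimum(g + rules.gap_days, admin_end)
    gap_wins = ~death_wins & (g + rules.gap_days <= admin_end)
    exit_day = np.where(
        death_wins, d,
        np.where(gap_wins,
                 g + (rules.gap_days if rules.gap_censor_at == "gap_end" else 0),
                 admin_end),
    )
    reason = np.where(death_wins, "death",
                      np.where(gap_wins, "gap_censor", "admin_censor"))
    out = pd.DataFrame({"pid": entry.index.to_numpy(), "entry": e,
                        "exit": exit_day, "exit_reason": reason})
    out = out[out["exit"] > out["entry"]].reset_index(drop=True)
    return out


def adjudicate_ascvd(conditions: pd.DataFrame, labs: pd.DataFrame,
                     cfg: AdjudicationConfig = AdjudicationConfig()
                     ) -> pd.DataFrame:
    """Corroborated first ASCVD events per patient and subtype.

    Returns columns ``pid``, ``endpoint`` (ascvd_coronary /
    ascvd_cerebrovascular), ``event_day``; the earliest corroborated
    diagnosis date per patient defines the event.
    """
    if cfg is None:
        raise ValueError("adjudication requires a code-set configuration")
    dx = conditions[conditions["kind"] == "diagnosis"]
    out = []
    specs = [
        ("ascvd_coronary", cfg.coronary_dx, cfg.coronary_procedures, "procedure",
         cfg.lab_criteria),
        ("ascvd_cerebrovascular", cfg.cerebrovascular_dx,
         cfg.cerebrovascular_imaging, "imaging", {}),
    ]
    for endpoint, dx_codes, evid_codes, evid_kind, lab_criteria in specs:
        cand = dx[dx["code"].isin(dx_codes)][["pid", "record_day"]]
        if not len(cand):
            continue
        evid = conditions[
            (conditions["kind"] == evid_kind)
            & conditions["code"].isin(evid_codes)
        ][["pid", "record_day"]].rename(columns={"record_day": "evid_day"})
        frames = [evid]
        for analyte, thr in lab_criteria.items():
            ql = labs[(labs["analyte"] == analyte) & (labs["value"] >= thr)]
            frames.append(ql[["pid", "lab_day"]].rename(
                columns={"lab_day": "evid_day"}))
        evidence = pd.concat(frames, ignore_index=True)
        merged = cand.merge(evidence, on="pid", how="inner")
        ok = merged[
            (merged["evid_day"] - merged["record_day"]).abs() <= cfg.window_days
        ]
        if len(ok):
            first = ok.groupby("pid")["record_day"].min().rename("event_day")
            out.append(first.reset_index().assign(endpoint=endpoint))
    if not out:
        return pd.DataFrame(columns=["pid", "endpoint", "event_day"])
    return pd.concat(out, ignore_index=True)[["pid", "endpoint", "event_day"]]


def first_endpoint(conditions: pd.DataFrame, codes: EndpointCodes,
                   entry: pd.Series) -> pd.Series:
    """Earliest qualifying diagnosis day strictly after enrolment, per pid."""
    dx = conditions[(conditions["kind"] == "diagnosis")
                    & conditions["code"].isin(codes.include)
                    & ~conditions["code"].isin(codes.exclude)]
    dx = dx[dx["pid"].isin(entry.index)]
    if not len(dx):
        return pd.Series(dtype="int64")
    dx = dx[dx["record_day"].to_numpy()
            > entry.reindex(dx["pid"]).to_numpy()]
    return dx.groupby("pid")["record_day"].min()


def collect_events(tables: dict, followup: pd.DataFrame, config) -> pd.DataFrame:
    """First event per patient and endpoint, restricted to follow-up.

    ``config`` is a :class:`rxmsm.config.PipelineConfig`.  The combined
    ``ascvd_any`` endpoint is the earlier of the two subtype events.
    """
    entry = followup.set_index("pid")["entry"]
    exit_ = followup.set_index("pid")["exit"]
    parts = []

    asc = adjudicate_ascvd(tables["conditions"], tables["labs"],
                           config.adjudication)
    parts.append(asc)
    if len(asc):
        any_ = asc.groupby("pid")["event_day"].min().reset_index()
        any_["endpoint"] = "ascvd_any"
        parts.append(any_[["pid", "endpoint", "event_day"]])
    for ep, codes in config.endpoint_codes.items():
        s = first_endpoint(tables["conditions"], codes, entry)
        parts.append(pd.DataFrame({"pid": s.index, "endpoint": ep,
                                   "event_day": s.to_numpy()}))
    ev = pd.concat(parts, ignore_index=True)
    ev = ev[ev["pid"].isin(entry.index)]
    ev = ev[(ev["event_day"].to_numpy() > entry.reindex(ev["pid"]).to_numpy())
            & (ev["event_day"].to_numpy() <= exit_.reindex(ev["pid"]).to_numpy())]
    return ev.reset_index(drop=True)


def build_person_periods(followup: pd.DataFrame, events: pd.DataFrame,
                         endpoint: str, grid: GridSpec = GridSpec()
                         ) -> pd.DataFrame:
    """Counting-process rows (start, stop] per patient for one endpoint.

    Follow-up for an explanatory endpoint is truncated at its first event.
    Returned columns: ``pid``, ``start``, ``stop`` (days since entry),
    ``anchor_day`` (calendar day of the period start, where time-updated
    covariates are evaluated), ``event`` and ``censored`` (gap censoring
    indicator of the period, for the censoring-weight model).
    """
    fu = followup
    entry = fu["entry"].to_numpy()
    exit_ = fu["exit"].to_numpy()
    if endpoint == "death":
        event_day = np.where(fu["exit_reason"].to_numpy() == "death", exit_, -1)
        stop_day = exit_
    else:
        ev = events[events["endpoint"] == endpoint].set_index("pid")["event_day"]
        ev = ev.reindex(fu["pid"]).to_numpy()
        has = ~np.isnan(ev)
        event_day = np.where(has, np.nan_to_num(ev, nan=-1), -1).astype(np.int64)
        stop_day = np.where(has, event_day, exit_).astype(np.int64)
    has_event = event_day > 0
    gap_censored = (fu["exit_reason"].to_numpy() == "gap_censor") & ~has_event

    span = stop_day - entry
    if np.any(span <= 0):
        raise AssertionError("non-positive follow-up span")
    k = -(-span // grid.interval_days)  # ceil: number of periods
    pid_rows = np.repeat(fu["pid"].to_numpy(), k)
    entry_rows = np.repeat(entry, k)
    stop_rows = np.repeat(stop_day, k)
    ends = np.cumsum(k)
    offs = np.arange(int(ends[-1])) - np.repeat(ends - k, k)
    start = offs * grid.interval_days
    stop = np.minimum(start + grid.interval_days, stop_rows - entry_rows)
    last = offs == np.repeat(k, k) - 1
    out = pd.DataFrame({
        "pid": pid_rows,
        "start": start,
        "stop": stop,
        "anchor_day": entry_rows + start,
        "event": last & np.repeat(has_event, k),
        "censored": last & np.repeat(gap_censored, k),
    })
    if np.any(out["stop"].to_numpy() <= out["start"].to_numpy()):
        raise AssertionError("empty person-period produced")
    return out
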