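"""End-to-end analysis: tables -> follow-up -> exposure -> weights -> MSM.

The pipeline consumes only the written file set (or equivalent in-memory
tables): it derives follow-up from viral loads and care contacts,
reconstructs day-level coverage and weekly exposure levels, attaches
time-updated covariates at the anchor grid, estimates stabilized truncated
treatment and censoring weights, and fits the weighted multi-level Cox
model per endpoint.

For model estimation, consecutive weekly person-periods with identical
exposure levels and categorical covariates are collapsed into runs of at
most ``collapse_days`` (default 56); continuously drifting covariates
(HAART adherence, age, lab running averages) are evaluated at the run-start
anchor.  The weekly table remains available for the structural invariants;
collapsing conserves person-time and event placement exactly and only
coarsens how often smooth covariates refresh inside an unchanged exposure
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CLASS_GROUPS,
    LEVEL_CONSISTENT,
    LEVEL_RECENT,
    PipelineConfig,
    YEAR_DAYS,
)
from .coverage import cohort_coverage, combo_coverage, cumulative_coverage, \
    pdc_at, window_count
from .diagnostics import assemble_report, balance_table, weight_diagnostics
from .followup import build_person_periods, collect_events, derive_followup
from .levels import classify_levels, sensitivity_consistent_matrix
from .msm import MarginalStructuralCox
from .weights import compute_weights, screen_predictors

__all__ = ["PipelineContext", "PipelineResult", "prepare_context",
           "attach_covariates", "collapse_periods", "run_pipeline",
           "run_subgroup", "run_immortal_time_sensitivity"]

_KEY = np.int64(1) << 22  # segment key stride: pid * _KEY + day


def _segmented(sorted_pid, sorted_day):
    return sorted_pid.astype(np.int64) * _KEY + sorted_day.astype(np.int64)


def _last_value(lab_pid, lab_day, lab_val, q_pid, q_day, default=0.0):
    """Most recent value at or before each query day, per patient."""
    order = np.lexsort((lab_day, lab_pid))
    key = _segmented(lab_pid[order], lab_day[order])
    vals = lab_val[order]
    q = _segmented(q_pid, q_day)
    idx = np.searchsorted(key, q, side="right") - 1
    ok = idx >= 0
    ok &= np.where(ok, (key[np.maximum(idx, 0)] // _KEY) == q_pid, False)
    out = np.full(len(q_pid), default, dtype=float)
    out[ok] = vals[idx[ok]]
    return out


def _window_mean(lab_pid, lab_day, lab_val, q_pid, q_day, window=YEAR_DAYS,
                 default=0.0):
    """Mean of values in (day-window, day] per patient (running average)."""
    order = np.lexsort((lab_day, lab_pid))
    key = _segmented(lab_pid[order], lab_day[order])
    cs = np.concatenate([[0.0], np.cumsum(lab_val[order])])
    hi = np.searchsorted(key, _segmented(q_pid, q_day), side="right")
    lo = np.searchsorted(key, _segmented(q_pid, q_day - window), side="right")
    cnt = hi - lo
    out = np.full(len(q_pid), default, dtype=float)
    nz = cnt > 0
    out[nz] = (cs[hi[nz]] - cs[lo[nz]]) / cnt[nz]
    return out


@dataclass
class PipelineContext:
    """Shared intermediates: coverage matrices, follow-up, events, contacts."""

    tables: dict
    config: PipelineConfig
    admin_end: int
    n_patients: int
    coverage: dict
    cum: dict = field(repr=False)
    followup: pd.DataFrame = None
    events: pd.DataFrame = None
    contacts: pd.DataFrame = None
    clinic_contacts: pd.DataFrame = None
    first_llt_fill: np.ndarray = None


def _with_pid(df, n=None):
    out = df.copy()
    out["pid"] = out["patient_id"].to_numpy(np.int64) - 1
    return out


def prepare_context(tables: dict, admin_end: int,
                    config: PipelineConfig = PipelineConfig()) -> PipelineContext:
    from . import io as rio

    tables = rio.day_tables(tables)
    t = {k: _with_pid(v) for k, v in tables.items()}
    n = 0
    for df in t.values():
        if len(df):
            n = max(n, int(df["pid"].max()) + 1)
    H = admin_end

    fills = t["fills"].rename(columns={})
    cov = cohort_coverage(fills, t["stays"], n, H, config.rules)
    # HAART combination coverage
    agents = {k.split(":", 1)[1]: v for k, v in cov.items()
              if k.startswith("arv:")}
    cov["haart"] = combo_coverage(agents, config.accepted_combos) if agents \
        else np.zeros((n, H), dtype=bool)

    cum = {k: cumulative_coverage(v) for k, v in cov.items()
           if k in ("llt", "aht", "asa", "statin", "nonstatin_llt", "haart")
           or k in tuple(CLASS_GROUPS["aht"])}

    # clinic visits (lab draws, viral loads, admissions) measure outpatient
    # follow-up frequency; pharmacy fills additionally count as care contacts
    # for the gap-censoring rule but not as visits (they would proxy adherence)
    clinic = pd.DataFrame({
        "pid": np.concatenate([
            t["labs"]["pid"], t["viral_loads"]["pid"], t["stays"]["pid"]]),
        "day": np.concatenate([
            t["labs"]["lab_day"], t["viral_loads"]["vl_day"],
            t["stays"]["admit_day"]]),
    }).drop_duplicates()
    contacts = pd.concat([
        clinic,
        pd.DataFrame({"pid": t["fills"]["pid"], "day": t["fills"]["fill_day"]}),
    ]).drop_duplicates()
    fu = derive_followup(t["viral_loads"], contacts, t["deaths"], admin_end,
                         config.followup)
    events = collect_events(t, fu, config)

    first_llt = np.full(n, np.iinfo(np.int64).max // 4, dtype=np.int64)
    llt_fills = fills[fills["drug_class"].isin(CLASS_GROUPS["llt"])]
    if len(llt_fills):
        np.minimum.at(first_llt, llt_fills["pid"].to_numpy(),
                      llt_fills["fill_day"].to_numpy())

    return PipelineContext(tables=t, config=config, admin_end=admin_end,
                           n_patients=n, coverage=cov, cum=cum, followup=fu,
                           events=events, contacts=contacts,
                           clinic_contacts=clinic, first_llt_fill=first_llt)


def attach_covariates(ctx: PipelineContext, periods: pd.DataFrame,
                      sensitivity_consistent: bool = False) -> pd.DataFrame:
    """Exposure levels, sublevels and time-updated covariates at each anchor."""
    cfg = ctx.config
    p = periods.copy()
    pid = p["pid"].to_numpy()
    anchor = p["anchor_day"].to_numpy()

    for grp in CLASS_GROUPS:
        p[f"{grp}_level"] = classify_levels(ctx.cum[grp], pid, anchor,
                                            rules=cfg.levels)
    if sensitivity_consistent:
        sens = sensitivity_consistent_matrix(ctx.cum["llt"], pid, anchor,
                                             ctx.first_llt_fill, cfg.levels)
        lev = p["llt_level"].to_numpy().copy()
        lev[(lev == LEVEL_CONSISTENT) & ~sens] = LEVEL_RECENT
        lev[(lev == LEVEL_RECENT) & sens] = LEVEL_CONSISTENT
        p["llt_level"] = lev

    # LLT sublevels over the trailing year / the remote window
    s_year = window_count(ctx.cum["statin"], pid, anchor - YEAR_DAYS, anchor) > 0
    n_year = window_count(ctx.cum["nonstatin_llt"], pid, anchor - YEAR_DAYS,
                          anchor) > 0
    s_ever = window_count(ctx.cum["statin"], pid, -1, anchor - YEAR_DAYS) > 0
    lev = p["llt_level"].to_numpy()
    sub = np.zeros(len(p), dtype=np.int8)
    cons = lev == LEVEL_CONSISTENT
    sub[cons & s_year & ~n_year] = 1          # statin_only
    sub[cons & s_year & n_year] = 2           # combination
    sub[cons & ~s_year & n_year] = 3          # statin_free
    p["llt_sub"] = sub
    p["llt_statin_containing"] = np.where(lev == LEVEL_RECENT, s_year, s_ever)

    # AHT single vs combination over the trailing year
    active = np.zeros(len(p), dtype=np.int8)
    for cls in CLASS_GROUPS["aht"]:
        if cls in ctx.cum:
            active += (window_count(ctx.cum[cls], pid, anchor - YEAR_DAYS,
                                    anchor) > 0).astype(np.int8)
    p["aht_combination"] = active >= 2

    # HAART adherence (trailing-year PDC of accepted combinations)
    p["haart_pdc"] = pdc_at(ctx.cum["haart"], pid, anchor, obs_start=0)

    labs = ctx.tables["labs"]
    for analyte, col, how in [("comorbidity_index", "comorbidity_index", "last"),
                              ("age", "age", "last"),
                              ("ldl", "ldl_avg", "mean")]:
        sel = labs[labs["analyte"] == analyte]
        fn = _last_value if how == "last" else _window_mean
        p[col] = fn(sel["pid"].to_numpy(), sel["lab_day"].to_numpy(),
                    sel["value"].to_numpy(float), pid, anchor)

    # categorized frequency of outpatient follow-up: clinic visits in the
    # trailing year, annualized over the in-care part of the window so that
    # anchors shortly after the first contact are not artificially low
    c = ctx.clinic_contacts
    order = np.lexsort((c["day"].to_numpy(), c["pid"].to_numpy()))
    cpid = c["pid"].to_numpy()[order]
    cday = c["day"].to_numpy()[order]
    key = _segmented(cpid, cday)
    first_contact = np.full(ctx.n_patients, 0, dtype=np.int64)
    firsts = np.ones(len(cpid), dtype=bool)
    firsts[1:] = cpid[1:] != cpid[:-1]
    first_contact[cpid[firsts]] = cday[firsts]
    wstart = np.maximum(anchor - YEAR_DAYS, first_contact[pid])
    hi = np.searchsorted(key, _segmented(pid, anchor), side="right")
    lo = np.searchsorted(key, _segmented(pid, wstart), side="right")
    span = np.maximum(anchor - wstart, 30)
    visits_per_year = (hi - lo) * (YEAR_DAYS / span)
    p["fu_freq_mid"] = ((visits_per_year >= 4) & (visits_per_year < 12)
                        ).astype(float)
    p["fu_freq_high"] = (visits_per_year >= 12).astype(float)

    p["ptime"] = (p["stop"] - p["start"]).astype(float)
    return p


_RUN_KEYS = ["llt_level", "aht_level", "asa_level", "llt_sub",
             "llt_statin_containing", "aht_combination",
             "fu_freq_mid", "fu_freq_high"]


def collapse_periods(p: pd.DataFrame, max_days: int | None = 56) -> pd.DataFrame:
    """Merge consecutive weekly rows with identical exposure state.

    Runs never span an exposure-level, sublevel or follow-up-frequency
    change, never exceed ``max_days``, and event/censoring rows terminate
    runs by construction (they are each patient's final rows).  Person-time
    and event placement are conserved exactly.
    """
    if max_days is None:
        return p
    p = p.sort_values(["pid", "start"], kind="stable").reset_index(drop=True)
    pid = p["pid"].to_numpy()
    new = np.ones(len(p), dtype=bool)
    new[1:] = pid[1:] != pid[:-1]
    change = new.copy()
    for k in _RUN_KEYS:
        v = p[k].to_numpy()
        change[1:] |= v[1:] != v[:-1]
    run0 = np.cumsum(change) - 1
    # enforce the maximum run length
    first_idx = np.zeros(len(p), dtype=np.int64)
    firsts = np.flatnonzero(change)
    first_idx = firsts[np.searchsorted(firsts, np.arange(len(p)), side="right") - 1]
    within = np.arange(len(p)) - first_idx
    per_run = max(max_days // 7, 1)
    run = run0 * 10000 + within // per_run
    grp = pd.Series(np.arange(len(p))).groupby(run, sort=False)
    keep_first = grp.head(1).to_numpy()
    keep_last = grp.tail(1).to_numpy()
    out = p.iloc[keep_first].copy().reset_index(drop=True)
    last = p.iloc[keep_last].reset_index(drop=True)
    out["stop"] = last["stop"].to_numpy()
    out["event"] = last["event"].to_numpy()
    out["censored"] = last["censored"].to_numpy()
    out["ptime"] = (out["stop"] - out["start"]).astype(float)
    return out


@dataclass
class PipelineResult:
    context: PipelineContext
    periods: dict          # endpoint -> weekly person-period table
    analysis_periods: dict  # endpoint -> collapsed table with weights merged
    weights: dict           # endpoint -> WeightSet
    covariates: dict        # endpoint -> screened covariate list
    results: dict           # endpoint -> MSMResults (weighted)
    results_unweighted: dict
    balance: pd.DataFrame = None
    weight_summary: pd.DataFrame = None
    report: dict = None


def run_pipeline(tables: dict, admin_end: int,
                 config: PipelineConfig = PipelineConfig(),
                 endpoints=None, fit_unweighted: bool = False,
                 collapse_days: int | None = 56,
                 build_report: bool = False,
                 screen: bool = True) -> PipelineResult:
    ctx = prepare_context(tables, admin_end, config)
    endpoints = list(endpoints if endpoints is not None else config.endpoints)
    periods, analysis, wsets, covs, fits, fits_uw = {}, {}, {}, {}, {}, {}
    for ep in endpoints:
        weekly = build_person_periods(ctx.followup, ctx.events, ep, config.grid)
        weekly = attach_covariates(ctx, weekly)
        periods[ep] = weekly
        ap = collapse_periods(weekly, collapse_days)
        if screen:
            kept = screen_predictors(ap, config.candidate_covariates,
                                     alpha=config.screen_alpha)
        else:
            kept = [c for c in config.candidate_covariates
                    if c in ("comorbidity_index", "age")] + \
                   ["fu_freq_mid", "fu_freq_high"]
        covs[ep] = kept
        ws = compute_weights(ap, kept, truncation_pct=config.truncation_pct)
        wsets[ep] = ws
        ap = pd.concat([ap.reset_index(drop=True), ws.table.reset_index(drop=True)],
                       axis=1)
        analysis[ep] = ap
        model = MarginalStructuralCox(ap, weight_col="w_total",
                                      llt_sublevels=config.llt_sublevels)
        fits[ep] = model.fit()
        if fit_unweighted:
            fits_uw[ep] = MarginalStructuralCox(
                ap, weight_col=None, llt_sublevels=config.llt_sublevels).fit()

    res = PipelineResult(context=ctx, periods=periods, analysis_periods=analysis,
                         weights=wsets, covariates=covs, results=fits,
                         results_unweighted=fits_uw)
    ep0 = endpoints[0]
    try:
        res.balance = balance_table(analysis[ep0],
                                    covs[ep0] or ["comorbidity_index"],
                                    group="llt")
    except ValueError:
        res.balance = pd.DataFrame(columns=["asd_unweighted", "asd_weighted"])
    res.weight_summary = weight_diagnostics(
        wsets[ep0].table, analysis[ep0], wsets[ep0].truncation_bounds)
    if build_report:
        res.report = assemble_report(fits, res.balance, res.weight_summary,
                                     {"endpoints": endpoints,
                                      "admin_end": admin_end})
    return res


def run_subgroup(ctx: PipelineContext, endpoint: str, predicate,
                 collapse_days: int | None = 56, screen: bool = False):
    """Refit the full weighting + MSM pipeline on a person-period subset.

    ``predicate`` maps the attached weekly person-period table to a boolean
    row mask (criteria referring to the preceding year are expressible
    through the attached trailing-window covariates).
    """
    weekly = build_person_periods(ctx.followup, ctx.events, endpoint,
                                  ctx.config.grid)
    weekly = attach_covariates(ctx, weekly)
    mask = np.asarray(predicate(weekly), dtype=bool)
    if not mask.any():
        raise ValueError("empty subgroup")
    sub = weekly[mask].reset_index(drop=True)
    ap = collapse_periods(sub, collapse_days)
    if screen:
        kept = screen_predictors(ap, ctx.config.candidate_covariates,
                                 alpha=ctx.config.screen_alpha)
    else:
        kept = ["comorbidity_index", "age", "fu_freq_mid", "fu_freq_high"]
        kept = [k for k in kept if k in ap.columns]
    ws = compute_weights(ap, kept, truncation_pct=ctx.config.truncation_pct)
    ap = pd.concat([ap.reset_index(drop=True), ws.table.reset_index(drop=True)],
                   axis=1)
    model = MarginalStructuralCox(ap, weight_col="w_total",
                                  llt_sublevels=ctx.config.llt_sublevels)
    return model.fit(), ap


def fit_naive_ever_user(ctx: PipelineContext, endpoint: str = "death"):
    """Deliberately naive ever-user-from-baseline Cox model.

    Each patient contributes a single interval from entry to exit with a
    fixed 'ever used LLT' indicator (any fill at any time, including after
    baseline) — the textbook immortal-time construction.
    """
    from ._coxengine import fit_cox

    fu = ctx.followup
    pid = fu["pid"].to_numpy()
    ever = (ctx.first_llt_fill[pid] < ctx.admin_end).astype(float)
    dur = (fu["exit"] - fu["entry"]).to_numpy(float)
    event = fu["exit_reason"].to_numpy() == "death"
    fit = fit_cox(ever[:, None], np.zeros(len(fu)), dur, event,
                  cluster=pid)
    return fit


def run_immortal_time_sensitivity(ctx: PipelineContext, endpoint: str = "death",
                                  collapse_days: int | None = 56) -> dict:
    """Sensitivity battery for immortal-time / new-user concerns.

    Returns fits of (a) the since-initiation redefinition of consistent use,
    (b) the new-LLT-user-restricted cohort, and (c) the naive ever-user
    model alongside the primary time-updated weighted fit.
    """
    out = {}
    weekly = build_person_periods(ctx.followup, ctx.events, endpoint,
                                  ctx.config.grid)

    def _fit(wk):
        ap = collapse_periods(wk, collapse_days)
        kept = [k for k in ("comorbidity_index", "age", "fu_freq_mid",
                            "fu_freq_high") if k in ap.columns]
        ws = compute_weights(ap, kept, truncation_pct=ctx.config.truncation_pct)
        ap = pd.concat([ap.reset_index(drop=True),
                        ws.table.reset_index(drop=True)], axis=1)
        return MarginalStructuralCox(ap, weight_col="w_total").fit()

    out["primary"] = _fit(attach_covariates(ctx, weekly))
    out["sensitivity_definition"] = _fit(
        attach_covariates(ctx, weekly, sensitivity_consistent=True))

    entry = ctx.followup.set_index("pid")["entry"]
    new_user = ctx.first_llt_fill[ctx.followup["pid"].to_numpy()] >= \
        entry.to_numpy()
    keep_pids = set(ctx.followup["pid"].to_numpy()[new_user])
    wk = weekly[weekly["pid"].isin(keep_pids)].reset_index(drop=True)
    out["new_user"] = _fit(attach_covariates(ctx, wk))
    out["naive_ever_user"] = fit_naive_ever_user(ctx, endpoint)
    return out
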