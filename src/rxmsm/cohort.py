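"""Synthetic veteran-like cohort generator with known ground-truth effects.

The generator produces the full longitudinal file set the analysis pipeline
consumes (fills, stays, labs, viral loads, conditions, deaths) from a
discrete-time simulation on a daily grid:

* every patient enters care at a staggered date, starts a three-agent ARV
  regimen, and achieves an undetectable viral load with configurable
  probability — the first undetectable measurement defines cohort entry;
* a latent log-normal frailty score raises both the probability of starting
  cardiovascular drugs (indication confounding) and the death hazard; the
  score is also emitted as a measured laboratory covariate
  (``comorbidity_index``) so that a correctly specified weighting model can
  remove the confounding it induces;
* refill persistence follows a three-class adherence mixture
  (high / intermittent / poor) that can optionally be correlated with
  frailty (healthy-adherer confounding);
* the death hazard at day *t* multiplies the baseline by
  ``exp(true_log_hr[class_group, level(t)])`` where ``level(t)`` is computed
  from the simulated fills with the exact classifier the pipeline uses
  (weekly updated), so the configured hazard ratios are the estimand of the
  downstream models by construction;
* explanatory endpoints (coronary and cerebrovascular ASCVD, serious
  infection, new cancer) run as independent competing processes; ASCVD
  diagnosis codes carry corroborating procedure / biomarker / imaging
  records most of the time, and uncorroborated administrative diagnosis
  noise is sprinkled in for the adjudicator to discard.

Per-patient ground truth (frailty, adherence class, true event days) is kept
on the returned :class:`SyntheticCohort` for validation only and is never
written to the file set the pipeline reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as rio
from .config import (
    CLASS_GROUPS,
    LEVEL_NAMES,
    NS_LLT_CLASSES,
    AHT_CLASSES,
    CoverageRules,
    SimulationConfig,
)
from .coverage import cohort_coverage, cumulative_coverage
from .levels import classify_levels

__all__ = ["SyntheticCohort", "simulate_cohort", "write_cohort", "read_cohort"]

_ADHER_P_REFILL = np.array([0.97, 0.75, 0.45])
_ADHER_MEAN_GAP = np.array([10.0, 45.0, 90.0])
_ADHER_P_STOP = np.array([0.010, 0.040, 0.120])

_STATIN_CODES = ["simvastatin", "atorvastatin", "pravastatin"]
_AHT_CODES = {"ace_arb": "lisinopril", "beta_blocker": "metoprolol",
              "ccb": "amlodipine", "diuretic": "hctz"}
_ARV_CODES = ["tdf", "ftc", "efv"]

_SUPPLY = 30


@dataclass
class SyntheticCohort:
    """Generated tables plus hidden ground truth."""

    tables: dict
    latent_truth: pd.DataFrame
    config: SimulationConfig
    #: weekly ground-truth level codes per class group, (n, n_weeks) int8
    true_levels: dict = field(default_factory=dict, repr=False)

    @property
    def n_patients(self) -> int:
        return self.config.n_patients


def _chain_fills(rng, start, stop, adher, codes, class_name, p_switch=0.03,
                 p_stop_scale=1.0):
    """Vectorized refill chains: one row per chain, loop over refill cycles.

    ``start``/``stop`` are per-chain day bounds; ``codes`` is the list of
    interchangeable drug codes of the class (switching exercises the
    stock-reset rule).  Returns (chain_idx, day, code_idx) arrays.
    """
    m = len(start)
    day = np.asarray(start, dtype=np.int64).copy()
    stop = np.asarray(stop, dtype=np.int64)
    active = day < stop
    code_idx = rng.integers(0, len(codes), size=m)
    out_chain, out_day, out_code = [], [], []
    max_cycles = int(np.max(stop - np.minimum(day, stop), initial=0) // 12) + 2
    for _ in range(max_cycles):
        if not active.any():
            break
        sel = np.flatnonzero(active)
        out_chain.append(sel)
        out_day.append(day[sel])
        out_code.append(code_idx[sel])
        a = adher[sel]
        # permanent discontinuation
        stopping = rng.random(sel.size) < p_stop_scale * _ADHER_P_STOP[a]
        # refill timing: on-time (slightly early or late) vs a refill gap
        on_time = rng.random(sel.size) < _ADHER_P_REFILL[a]
        jitter = rng.integers(-7, 8, size=sel.size)
        gap = 8 + rng.geometric(1.0 / _ADHER_MEAN_GAP[a])
        delay = np.where(on_time, jitter, gap)
        nxt = day[sel] + _SUPPLY + np.maximum(delay, -15)
        switching = rng.random(sel.size) < (p_switch if len(codes) > 1 else 0.0)
        code_idx[sel] = np.where(
            switching, (code_idx[sel] + 1) % len(codes), code_idx[sel]
        )
        day[sel] = nxt
        active[sel] = (~stopping) & (nxt < stop[sel])
    if not out_chain:
        return (np.empty(0, np.int64),) * 3
    return (np.concatenate(out_chain), np.concatenate(out_day),
            np.concatenate(out_code))


def _weekly_event_sampler(rng, log_h, active_from, horizon):
    """First-event day under a weekly piecewise-constant daily log hazard.

    ``log_h`` is (n, n_weeks); returns per-patient event day (horizon if no
    event).  Within the event week the day is drawn from the conditional
    geometric distribution of the daily Bernoulli process.
    """
    n, W = log_h.shape
    week_start = np.arange(W, dtype=np.int64) * 7
    days_active = np.clip(
        np.minimum(week_start[None, :] + 7, horizon)
        - np.maximum(week_start[None, :], active_from[:, None]),
        0, 7,
    )
    h = np.exp(log_h)
    p_week = -np.expm1(-h * days_active)
    u = rng.random((n, W))
    hit = u < p_week
    first = np.where(hit.any(axis=1), hit.argmax(axis=1), -1)
    event_day = np.full(n, horizon, dtype=np.int64)
    idx = np.flatnonzero(first >= 0)
    if idx.size:
        w = first[idx]
        m = days_active[idx, w]
        p_day = -np.expm1(-h[idx, w])
        v = rng.random(idx.size)
        # j ~ truncated geometric on {0, ..., m-1}
        j = np.floor(
            np.log1p(-v * (1.0 - (1.0 - p_day) ** m)) / np.log1p(-p_day)
        ).astype(np.int64)
        j = np.minimum(j, m - 1)
        start_in_week = np.maximum(week_start[w], active_from[idx])
        event_day[idx] = start_in_week + j
    return event_day


def _log_hr_lookup(log_hr_map: dict, group: str) -> np.ndarray:
    return np.array([float(log_hr_map.get((group, name), 0.0))
                     for name in LEVEL_NAMES])


def simulate_cohort(config: SimulationConfig,
                    rules: CoverageRules = CoverageRules()) -> SyntheticCohort:
    """Run the generator; deterministic given the config (including seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, H = config.n_patients, config.horizon_days
    pid = np.arange(n)

    # ---- latent patient characteristics -----------------------------------
    z = rng.standard_normal(n)                      # frailty (log-normal scalar)
    age = rng.normal(53.0, 8.0, size=n)
    care_start = rng.integers(0, config.entry_spread_days, size=n)

    # adherence class, optionally correlated with frailty: high frailty ->
    # poorer refill persistence when the healthy-adherer knob is on
    rho = float(config.adherence_frailty_corr)
    u_adh = rng.standard_normal(n)
    score = rho * z + np.sqrt(max(1.0 - rho * rho, 0.0)) * u_adh
    cuts = np.quantile(score, np.cumsum(config.adherence_mixture)[:-1]) \
        if rho != 0.0 else None
    if cuts is None:
        from scipy.stats import norm
        cuts = norm.ppf(np.cumsum(config.adherence_mixture)[:-1])
    adher = np.digitize(score, cuts)                # 0 high, 1 intermittent, 2 poor

    # loss to follow-up (permanent care gap) and suppression
    ltfu_rate = config.ltfu_rate * np.exp(config.ltfu_frailty_coef * z)
    dropout = np.where(
        ltfu_rate > 0,
        care_start + np.floor(rng.exponential(1.0 / np.maximum(ltfu_rate, 1e-300))),
        H,
    ).astype(np.int64)
    dropout = np.minimum(dropout, H)
    suppresses = rng.random(n) < config.suppression_prob
    supp_delay = rng.exponential(config.suppression_mean_days, size=n)
    supp_day = np.where(suppresses, care_start + supp_delay.astype(np.int64),
                        np.iinfo(np.int64).max)

    # ---- prescription fills -------------------------------------------------
    fill_pid, fill_day, fill_code, fill_class = [], [], [], []

    def add_fills(mask, start, class_name, codes, p_switch=0.03):
        sel = np.flatnonzero(mask)
        if not sel.size:
            return
        ch, day, code = _chain_fills(
            rng, start[sel], np.minimum(dropout[sel], H), adher[sel],
            codes, class_name, p_switch,
        )
        fill_pid.append(sel[ch])
        fill_day.append(day)
        fill_code.append(np.asarray(codes, dtype=object)[code])
        fill_class.append(np.full(len(ch), class_name, dtype=object))

    # ARV regimen for everyone in care; the agents of the regimen are
    # dispensed together (one refill event covers all three), which models
    # single-regimen refills and clusters adherence across agents
    arv_start = care_start + rng.integers(0, 15, size=n)
    ch, day, _ = _chain_fills(rng, arv_start, np.minimum(dropout, H), adher,
                              ["regimen"], "arv", 0.0, p_stop_scale=0.15)
    for agent in _ARV_CODES:
        fill_pid.append(ch.copy())
        fill_day.append(day.copy())
        fill_code.append(np.full(len(ch), agent, dtype=object))
        fill_class.append(np.full(len(ch), "arv", dtype=object))

    # CV drug classes: start hazard raised by frailty and age (indication bias)
    lin = config.confounding_strength * z + 0.02 * (age - 53.0)
    for group, base_rate in config.start_rates.items():
        rate = base_rate * np.exp(lin)
        delay = rng.exponential(1.0 / np.maximum(rate, 1e-300))
        start = care_start + np.minimum(delay, 10 * H).astype(np.int64)
        started = start < np.minimum(dropout, H)
        if group == "llt":
            pattern = rng.choice(3, size=n, p=[0.55, 0.25, 0.20])
            ns_class = np.asarray(NS_LLT_CLASSES)[
                rng.integers(0, len(NS_LLT_CLASSES), size=n)
            ]
            statin_mask = started & np.isin(pattern, [0, 2])
            add_fills(statin_mask, start, "statin", _STATIN_CODES)
            ns_start = start + rng.integers(0, 180, size=n)
            for cls in NS_LLT_CLASSES:
                mask = started & np.isin(pattern, [1, 2]) & (ns_class == cls)
                add_fills(mask, np.where(pattern == 1, start, ns_start),
                          cls, [f"{cls}_agent"], 0.0)
        elif group == "aht":
            n_sub = 1 + (rng.random(n) < 0.4)
            first_sub = rng.integers(0, len(AHT_CLASSES), size=n)
            second_sub = (first_sub + 1 + rng.integers(0, len(AHT_CLASSES) - 1,
                                                       size=n)) % len(AHT_CLASSES)
            for j, cls in enumerate(AHT_CLASSES):
                mask = started & ((first_sub == j) | ((n_sub == 2) & (second_sub == j)))
                add_fills(mask, start + rng.integers(0, 90, size=n) * (first_sub != j),
                          cls, [_AHT_CODES[cls]], 0.0)
        else:  # asa
            add_fills(started, start, "asa", ["aspirin_81"], 0.0)

    fills = pd.DataFrame({
        "pid": np.concatenate(fill_pid) if fill_pid else np.empty(0, np.int64),
        "fill_day": np.concatenate(fill_day) if fill_day else np.empty(0, np.int64),
        "drug_code": np.concatenate(fill_code) if fill_code else np.empty(0, object),
        "drug_class": np.concatenate(fill_class) if fill_class else np.empty(0, object),
    })
    fills["days_supply"] = _SUPPLY
    fills = fills[fills["fill_day"] < H].reset_index(drop=True)

    # ---- hospital stays ------------------------------------------------------
    in_care_years = np.maximum(np.minimum(dropout, H) - care_start, 0) / 365.25
    n_stays = rng.poisson(0.15 * in_care_years * np.exp(0.4 * z))
    stay_pid = np.repeat(pid, n_stays)
    admit = (care_start[stay_pid]
             + (rng.random(len(stay_pid))
                * np.maximum(np.minimum(dropout, H) - care_start, 1)[stay_pid])
             .astype(np.int64))
    dur = np.minimum(1 + rng.geometric(1.0 / 5.0, size=len(stay_pid)), 60)
    stays = pd.DataFrame({
        "pid": stay_pid, "admit_day": admit,
        "discharge_day": np.minimum(admit + dur, H - 1),
    })

    # ---- coverage and ground-truth weekly exposure levels -------------------
    cov = cohort_coverage(fills, stays, n, H, rules)
    W = (H + 6) // 7
    week_anchor = np.minimum(np.arange(W, dtype=np.int64) * 7, H - 1)
    group_levels = {}
    for group in CLASS_GROUPS:
        C = cumulative_coverage(cov[group])
        rows = np.repeat(pid, W)
        anchors = np.tile(week_anchor, n)
        group_levels[group] = classify_levels(C, rows, anchors).reshape(n, W)

    # ---- death ---------------------------------------------------------------
    log_h = (np.log(config.baseline_hazard)
             + config.frailty_death_coef * z[:, None]
             + 0.03 * (age - 53.0)[:, None]) * np.ones((1, W))
    for group in CLASS_GROUPS:
        lut = _log_hr_lookup(config.true_log_hr, group)
        log_h = log_h + lut[group_levels[group]]
    death_day = _weekly_event_sampler(rng, log_h, care_start, H)

    # ---- explanatory endpoints ------------------------------------------------
    true_events = {}
    for ep, base in config.event_rates.items():
        ep_log_h = (np.log(base) + 0.5 * z[:, None]) * np.ones((1, W))
        for group in CLASS_GROUPS:
            lut = _log_hr_lookup(config.endpoint_log_hr.get(ep, {}), group)
            ep_log_h = ep_log_h + lut[group_levels[group]]
        true_events[ep] = _weekly_event_sampler(rng, ep_log_h, care_start, H)

    # ---- observation cut-offs --------------------------------------------------
    last_obs = np.minimum(np.minimum(dropout, death_day), H - 1)

    def trunc(df, day_col):
        return df[df[day_col].to_numpy() <= last_obs[df["pid"].to_numpy()]]

    fills = trunc(fills, "fill_day").reset_index(drop=True)
    stays = trunc(stays, "admit_day").reset_index(drop=True)
    stays["discharge_day"] = np.minimum(
        stays["discharge_day"], last_obs[stays["pid"].to_numpy()]
    )

    def _ragged_arange(counts):
        ends = np.cumsum(counts)
        if not len(ends) or ends[-1] == 0:
            return np.empty(0, np.int64)
        return np.arange(int(ends[-1])) - np.repeat(ends - counts, counts)

    # ---- viral loads -------------------------------------------------------------
    # visit intensity is heterogeneous and higher in frail patients, so the
    # categorized follow-up frequency is an informative, balanceable covariate
    visit_scale = np.exp(-0.35 * z - 0.45 * rng.standard_normal(n))
    vl_interval = np.clip((90 * visit_scale).astype(np.int64), 30, 365)
    vl_count = np.maximum((last_obs - care_start) // vl_interval + 1, 0)
    vl_pid = np.repeat(pid, vl_count)
    offs = _ragged_arange(vl_count)
    vl_day = care_start[vl_pid] + vl_interval[vl_pid] * offs
    detect = vl_day < supp_day[vl_pid]
    copies = np.where(detect, 10 ** rng.normal(4.3, 0.6, size=len(vl_pid)), 20.0)
    vls = pd.DataFrame({"pid": vl_pid, "vl_day": vl_day,
                        "copies_per_ml": np.round(copies, 1)})

    # ---- labs ------------------------------------------------------------------
    lab_interval = np.clip((270 * visit_scale).astype(np.int64), 60, 540)
    lab_count = np.maximum((last_obs - care_start) // lab_interval + 1, 0)
    lab_pid = np.repeat(pid, lab_count)
    offs = _ragged_arange(lab_count)
    lab_day = care_start[lab_pid] + lab_interval[lab_pid] * offs
    labs = pd.concat([
        pd.DataFrame({"pid": lab_pid, "analyte": "comorbidity_index",
                      "lab_day": lab_day,
                      "value": np.round(z[lab_pid], 4)}),
        pd.DataFrame({"pid": lab_pid, "analyte": "age",
                      "lab_day": lab_day,
                      "value": np.round(age[lab_pid] + lab_day / 365.25, 2)}),
        pd.DataFrame({"pid": lab_pid, "analyte": "ldl",
                      "lab_day": lab_day,
                      "value": np.round(rng.normal(3.1, 0.8, len(lab_pid)), 2)}),
    ], ignore_index=True)

    # ---- conditions: endpoint codes, corroboration, administrative noise --------
    cond_parts = []
    extra_labs = []

    def observed(ep_day):
        return ep_day <= last_obs

    cor_day = true_events["ascvd_coronary"]
    sel = np.flatnonzero(observed(cor_day))
    corro = rng.random(sel.size) < 0.9
    via_lab = rng.random(sel.size) < 0.5
    cond_parts.append(pd.DataFrame({
        "pid": sel, "code": "icd_mi", "kind": "diagnosis",
        "record_day": cor_day[sel]}))
    proc_sel = sel[corro & ~via_lab]
    cond_parts.append(pd.DataFrame({
        "pid": proc_sel, "code": "ptca", "kind": "procedure",
        "record_day": cor_day[proc_sel] + rng.integers(-2, 3, proc_sel.size)}))
    lab_sel = sel[corro & via_lab]
    extra_labs.append(pd.DataFrame({
        "pid": lab_sel, "analyte": "troponin",
        "lab_day": cor_day[lab_sel] + rng.integers(-1, 2, lab_sel.size),
        "value": np.round(rng.uniform(0.2, 5.0, lab_sel.size), 2)}))

    cer_day = true_events["ascvd_cerebrovascular"]
    sel = np.flatnonzero(observed(cer_day))
    corro = rng.random(sel.size) < 0.9
    cond_parts.append(pd.DataFrame({
        "pid": sel, "code": "icd_stroke", "kind": "diagnosis",
        "record_day": cer_day[sel]}))
    img_sel = sel[corro]
    cond_parts.append(pd.DataFrame({
        "pid": img_sel, "code": "ct_head", "kind": "imaging",
        "record_day": cer_day[img_sel] + rng.integers(0, 4, img_sel.size)}))

    # uncorroborated administrative ASCVD codes (should be discarded)
    noise = rng.random(n) < 0.03
    sel = np.flatnonzero(noise)
    noise_day = care_start[sel] + (
        rng.random(sel.size) * np.maximum(last_obs[sel] - care_start[sel], 1)
    ).astype(np.int64)
    cond_parts.append(pd.DataFrame({
        "pid": sel, "code": rng.choice(["icd_mi", "icd_stroke"], sel.size),
        "kind": "diagnosis", "record_day": noise_day}))

    inf_day = true_events["infection"]
    sel = np.flatnonzero(observed(inf_day))
    cond_parts.append(pd.DataFrame({
        "pid": sel,
        "code": rng.choice(["icd_pneumonia", "icd_sepsis", "icd_pyelonephritis"],
                           sel.size),
        "kind": "diagnosis", "record_day": inf_day[sel]}))
    can_day = true_events["cancer"]
    sel = np.flatnonzero(observed(can_day))
    cond_parts.append(pd.DataFrame({
        "pid": sel,
        "code": rng.choice(["icd_lung_ca", "icd_lymphoma", "icd_colon_ca"], sel.size),
        "kind": "diagnosis", "record_day": can_day[sel]}))
    # excluded-code nuisance records (cellulitis etc., skin cancers)
    sel = np.flatnonzero(rng.random(n) < 0.25)
    nz_day = care_start[sel] + (
        rng.random(sel.size) * np.maximum(last_obs[sel] - care_start[sel], 1)
    ).astype(np.int64)
    cond_parts.append(pd.DataFrame({
        "pid": sel,
        "code": rng.choice(["icd_cellulitis", "icd_uri", "icd_cystitis",
                            "icd_squamous_skin_ca", "icd_basal_skin_ca"], sel.size),
        "kind": "diagnosis", "record_day": nz_day}))

    conditions = pd.concat(cond_parts, ignore_index=True)
    conditions["record_day"] = np.clip(conditions["record_day"], 0, H - 1)
    conditions = trunc(conditions, "record_day").reset_index(drop=True)
    if extra_labs:
        labs = pd.concat([labs, *extra_labs], ignore_index=True)
    labs["lab_day"] = np.clip(labs["lab_day"], 0, H - 1)
    labs = trunc(labs, "lab_day").reset_index(drop=True)

    deaths = pd.DataFrame({
        "pid": np.flatnonzero(death_day < H),
        "death_day": death_day[death_day < H],
    })

    # ---- assemble ------------------------------------------------------------
    def finish(df, day_cols):
        out = df.copy()
        out.insert(0, "patient_id", out.pop("pid") + 1)
        for c in day_cols:
            dates = np.datetime64("1996-01-01") + out[c].to_numpy(np.int64)
            out[c.replace("_day", "_date")] = np.datetime_as_string(
                dates.astype("datetime64[D]"), unit="D")
        return out

    tables = {
        "fills": finish(fills.sort_values(["pid", "fill_day"]).reset_index(drop=True),
                        ["fill_day"]),
        "stays": finish(stays.sort_values(["pid", "admit_day"]).reset_index(drop=True),
                        ["admit_day", "discharge_day"]),
        "labs": finish(labs.sort_values(["pid", "lab_day"]).reset_index(drop=True),
                       ["lab_day"]),
        "viral_loads": finish(vls.sort_values(["pid", "vl_day"]).reset_index(drop=True),
                              ["vl_day"]),
        "conditions": finish(
            conditions.sort_values(["pid", "record_day"]).reset_index(drop=True),
            ["record_day"]),
        "deaths": finish(deaths.sort_values("pid").reset_index(drop=True),
                         ["death_day"]),
    }
    latent = pd.DataFrame({
        "patient_id": pid + 1,
        "frailty": z,
        "age": age,
        "adherence_class": adher,
        "care_start_day": care_start,
        "suppression_day": np.where(suppresses, supp_day, -1),
        "dropout_day": dropout,
        "death_day": np.where(death_day < H, death_day, -1),
        **{f"true_{ep}_day": np.where(d < H, d, -1)
           for ep, d in true_events.items()},
    })
    return SyntheticCohort(tables=tables, latent_truth=latent, config=config,
                           true_levels=group_levels)


def write_cohort(cohort: SyntheticCohort, directory: str) -> dict:
    """Write the patient-visible file set (ground truth is not written)."""
    return rio.write_tables(cohort.tables, directory)


def read_cohort(directory: str) -> dict:
    return rio.read_tables(directory)
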