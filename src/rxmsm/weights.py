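"""Stabilized, asymmetrically truncated inverse-probability weights.

For each cardiovascular class group a multinomial logistic propensity model
predicts the probability of the person-period's observed exposure level
given the screened covariates.  The stabilized weight is the marginal
(person-time) level frequency divided by that probability, clipped at the
5th and 95th percentiles of its own distribution (asymmetric truncation).
A pooled logistic censoring model yields inverse-probability-of-censoring
weights for the gap-censoring process, and the total weight is the product
of the three class-group weights and the censoring weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._coxengine import fit_cox
from .config import CLASS_GROUPS

__all__ = [
    "screen_predictors",
    "fit_propensity",
    "stabilize_truncate",
    "fit_censoring_weight",
    "compute_weights",
    "WeightSet",
]


def screen_predictors(periods: pd.DataFrame, candidates, endpoint_col="event",
                      alpha: float = 0.05, always=("fu_freq_mid", "fu_freq_high"),
                      weight_col=None) -> list:
    """Retain candidate covariates with p < alpha in an unweighted survival
    predictor model; the categorized outpatient follow-up frequency terms are
    always appended."""
    kept = []
    cands = [c for c in candidates if periods[c].std() > 0]
    if cands:
        X = periods[cands].to_numpy(dtype=float)
        try:
            fit = fit_cox(X, periods["start"], periods["stop"],
                          periods[endpoint_col].to_numpy(bool),
                          cluster=periods["pid"].to_numpy(), robust=False)
            from scipy import stats
            se = np.sqrt(np.diag(fit.cov))
            pvals = 2 * stats.norm.sf(np.abs(fit.params / se))
            kept = [c for c, pv in zip(cands, pvals) if pv < alpha]
        except (ValueError, np.linalg.LinAlgError):
            kept = []
    for col in always:
        if col in periods.columns and col not in kept:
            kept.append(col)
    return kept


def fit_propensity(periods: pd.DataFrame, level_col: str, covariates,
                   sample_weight_col: str | None = "ptime",
                   return_full: bool = False):
    """Per-row predicted probability of the observed exposure level.

    Multinomial logit over the observed levels (unpenalized MLE); with an
    empty covariate list the prediction is the marginal level frequency.
    Raises if fewer than two levels are observed.  With ``return_full`` the
    full per-level probability matrix and the level codes are also returned.
    """
    y = periods[level_col].to_numpy()
    levels, y_idx = np.unique(y, return_inverse=True)
    if len(levels) < 2:
        raise ValueError(f"fewer than two observed levels in {level_col}")
    sw = periods[sample_weight_col].to_numpy(float) \
        if sample_weight_col and sample_weight_col in periods else None
    if not covariates:
        freq = np.bincount(y_idx, weights=sw, minlength=len(levels))
        freq = freq / freq.sum()
        proba = np.tile(freq, (len(y_idx), 1))
    else:
        X = periods[list(covariates)].to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500,
                                 tol=1e-8)
        clf.fit(Xs, y_idx, sample_weight=sw)
        proba = clf.predict_proba(Xs)
    p_obs = proba[np.arange(len(y_idx)), y_idx]
    if np.any(p_obs <= 0):
        raise ValueError("positivity violation: zero predicted probability")
    if return_full:
        return p_obs, proba, levels
    return p_obs


def _weighted_percentile(values, weights, pct):
    order = np.argsort(values)
    v, cw = values[order], np.cumsum(weights[order])
    cw = cw / cw[-1]
    return np.interp(np.asarray(pct) / 100.0, cw, v)


def stabilize_truncate(p_obs: np.ndarray, level_codes: np.ndarray,
                       ptime: np.ndarray | None = None,
                       lower_pct: float = 5.0, upper_pct: float = 95.0,
                       p_num: np.ndarray | None = None):
    """Stabilized weight = marginal level frequency / p(observed level),
    clipped at the empirical [lower, upper] percentiles of its distribution.

    ``p_num`` replaces the overall marginal frequency with a row-specific
    stabilization numerator (e.g. a time-stratified level frequency).
    Percentiles are person-time weighted when ``ptime`` is given.  Returns
    ``(sw, bounds)`` with the per-level truncation bounds used.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    if np.any(p_obs <= 0) or np.any(p_obs >= 1 + 1e-12):
        raise ValueError("propensities must lie in (0, 1)")
    codes, inv = np.unique(level_codes, return_inverse=True)
    w = ptime if ptime is not None else np.ones(len(p_obs))
    if p_num is None:
        freq = np.bincount(inv, weights=w, minlength=len(codes))
        freq = freq / freq.sum()
        numerator = freq[inv]
    else:
        numerator = np.asarray(p_num, dtype=float)
    sw = numerator / p_obs
    if np.allclose(sw, 1.0):
        return sw, {int(c): (float(sw.min()), float(sw.max())) for c in codes}
    # each level's weight distribution is truncated at its own percentiles
    out = sw.copy()
    bounds = {}
    for k, code in enumerate(codes):
        m = inv == k
        if ptime is not None:
            lo, hi = _weighted_percentile(sw[m], np.asarray(ptime, float)[m],
                                          [lower_pct, upper_pct])
        else:
            lo, hi = np.percentile(sw[m], [lower_pct, upper_pct])
        out[m] = np.clip(sw[m], lo, hi)
        bounds[int(code)] = (float(lo), float(hi))
    return out, bounds


def fit_censoring_weight(periods: pd.DataFrame, covariates,
                         censor_col: str = "censored") -> np.ndarray:
    """Stabilized inverse-probability-of-censoring weights.

    Pooled logistic model of remaining uncensored over person-period rows;
    the weight of a row is the cumulative marginal probability of remaining
    uncensored through the preceding rows divided by the cumulative
    conditional probability, per patient.  With no censoring the weights are
    identically 1.
    """
    cens = periods[censor_col].to_numpy(bool)
    n = len(periods)
    if not cens.any():
        return np.ones(n)
    y = (~cens).astype(int)
    p_marg = np.full(n, y.mean())
    if covariates:
        X = periods[list(covariates)].to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500, tol=1e-8)
        clf.fit((X - mu) / sd, y)
        p_cond = clf.predict_proba((X - mu) / sd)[:, 1]
    else:
        p_cond = p_marg.copy()
    # cumulative products over each patient's preceding rows
    df = pd.DataFrame({
        "pid": periods["pid"].to_numpy(),
        "lm": np.log(p_marg), "lc": np.log(np.clip(p_cond, 1e-12, 1)),
    })
    g = df.groupby("pid", sort=False)
    cum_lm = g["lm"].cumsum() - df["lm"]
    cum_lc = g["lc"].cumsum() - df["lc"]
    return np.exp((cum_lm - cum_lc).to_numpy())


@dataclass
class WeightSet:
    """Per-period weights and their bookkeeping."""

    table: pd.DataFrame                       # sw_<group>, sw_censor, w_total
    truncation_bounds: dict = field(default_factory=dict)
    marginal_freqs: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in self.table.columns:
            if col.startswith("sw_") or col == "w_total":
                v = self.table[col].to_numpy()
                rows.append({"weight": col, "mean": v.mean(), "max": v.max(),
                             "min": v.min()})
        return pd.DataFrame(rows)


def compute_weights(periods: pd.DataFrame, covariates,
                    groups=tuple(CLASS_GROUPS),
                    truncation_pct=(5.0, 95.0),
                    time_cols=()) -> WeightSet:
    """Treatment weights per class group plus the censoring weight.

    ``periods`` must carry ``<group>_level`` codes, the covariate columns, a
    ``ptime`` column (person-time per row) and the ``censored`` indicator.
    With ``time_cols`` the treatment model is time-indexed: the denominator
    conditions on the time terms plus the covariates and the stabilization
    numerator on the time terms alone (time-stratified relative frequency).
    """
    out = pd.DataFrame(index=periods.index)
    bounds, freqs = {}, {}
    ptime = periods["ptime"].to_numpy(float)
    total = np.ones(len(periods))
    time_cols = list(time_cols)
    for grp in groups:
        col = f"{grp}_level"
        levels = periods[col].to_numpy()
        if len(np.unique(levels)) < 2:
            sw = np.ones(len(periods))
            bounds[grp] = {}
        else:
            p_obs = fit_propensity(periods, col, time_cols + list(covariates))
            p_num = fit_propensity(periods, col, time_cols) if time_cols \
                else None
            sw, b = stabilize_truncate(p_obs, levels, ptime,
                                       *truncation_pct, p_num=p_num)
            bounds[grp] = b
        codes, inv = np.unique(levels, return_inverse=True)
        f = np.bincount(inv, weights=ptime)
        freqs[grp] = dict(zip(codes.tolist(), (f / f.sum()).tolist()))
        out[f"sw_{grp}"] = sw
        total = total * sw
    sw_c = fit_censoring_weight(periods, covariates)
    out["sw_censor"] = sw_c
    out["w_total"] = total * sw_c
    return WeightSet(table=out, truncation_bounds=bounds, marginal_freqs=freqs)
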