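"""Covariate balance and weight diagnostics, and assembled run reports.

The balance metric is the absolute standardized difference (pooled-variance
form): ``|m_a - m_b| / sqrt((v_a + v_b) / 2)`` with weighted means and
variances; binary covariates use the proportion variance p(1-p).  The
default contrast compares consistent users against never-exposed patients,
before and after weighting.  Weight diagnostics flag stabilized-weight
means outside [0.9, 1.1] per level.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .config import LEVEL_CODES, LEVEL_NAMES

__all__ = [
    "absolute_standardized_difference",
    "balance_table",
    "weight_diagnostics",
    "assemble_report",
]


def _wmean_var(x, w, binary):
    w = w / w.sum()
    m = float(np.sum(w * x))
    if binary:
        v = m * (1.0 - m)
    else:
        v = float(np.sum(w * (x - m) ** 2))
    return m, v


def absolute_standardized_difference(values_a, values_b,
                                     weights_a=None, weights_b=None) -> float:
    """Weighted ASD between two groups; infinite if the pooled variance is
    zero while the means differ, 0.0 if both are degenerate and equal."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    wa = np.ones(a.size) if weights_a is None else np.asarray(weights_a, float)
    wb = np.ones(b.size) if weights_b is None else np.asarray(weights_b, float)
    binary = set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}
    ma, va = _wmean_var(a, wa, binary)
    mb, vb = _wmean_var(b, wb, binary)
    pooled = (va + vb) / 2.0
    diff = abs(ma - mb)
    if pooled <= 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / np.sqrt(pooled)


def balance_table(periods: pd.DataFrame, covariates, weight_col: str = "w_total",
                  group: str = "llt",
                  contrast=("consistent", "never")) -> pd.DataFrame:
    """Unweighted vs weighted ASD for every covariate, one row each.

    The comparison groups are person-periods at the two contrast levels of
    ``group`` (consistent users vs never exposed by default); weighting uses
    ``weight_col`` times person-time.
    """
    lev = periods[f"{group}_level"].to_numpy()
    mask_a = lev == LEVEL_CODES[contrast[0]]
    mask_b = lev == LEVEL_CODES[contrast[1]]
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("empty contrast group")
    ptime = periods["ptime"].to_numpy(float) if "ptime" in periods else \
        np.ones(len(periods))
    w = periods[weight_col].to_numpy(float) * ptime
    rows = []
    for cov in covariates:
        x = periods[cov].to_numpy(float)
        rows.append({
            "covariate": cov,
            "asd_unweighted": absolute_standardized_difference(
                x[mask_a], x[mask_b], ptime[mask_a], ptime[mask_b]),
            "asd_weighted": absolute_standardized_difference(
                x[mask_a], x[mask_b], w[mask_a], w[mask_b]),
        })
    return pd.DataFrame(rows).set_index("covariate")


def weight_diagnostics(weight_table: pd.DataFrame, level_codes: pd.DataFrame,
                       bounds: dict | None = None,
                       flag_range=(0.9, 1.1)) -> pd.DataFrame:
    """Mean / max / truncated share of each class-group weight per level.

    ``level_codes`` carries one ``<group>_level`` column per class group
    aligned with ``weight_table``; rows are flagged when a level's mean
    weight leaves ``flag_range``.
    """
    rows = []
    for col in weight_table.columns:
        if not col.startswith("sw_") or col == "sw_censor":
            continue
        grp = col[3:]
        sw = weight_table[col].to_numpy(float)
        lev = level_codes[f"{grp}_level"].to_numpy()
        grp_bounds = (bounds or {}).get(grp, {}) or {}
        for code in np.unique(lev):
            m = lev == code
            mean = float(sw[m].mean())
            lo, hi = grp_bounds.get(int(code), (-np.inf, np.inf))
            rows.append({
                "group": grp, "level": LEVEL_NAMES[code],
                "mean": mean, "max": float(sw[m].max()),
                "share_truncated": float(
                    ((sw[m] <= lo) | (sw[m] >= hi)).mean())
                if np.isfinite(lo) else 0.0,
                "flagged": not (flag_range[0] <= mean <= flag_range[1]),
            })
    return pd.DataFrame(rows)


def assemble_report(fits: dict, balance: pd.DataFrame,
                    weight_summary: pd.DataFrame, config_echo: dict) -> dict:
    """Machine-readable run report: hazard-ratio grid, balance, weights.

    ``fits`` maps endpoint name to an :class:`~rxmsm.msm.MSMResults`; raw
    p-values are Benjamini–Hochberg adjusted across the full endpoint x
    class x level grid of the overall analysis.
    """
    if not fits:
        raise ValueError("no fitted models to report")
    if balance is None or weight_summary is None:
        raise ValueError("missing report section")
    from .msm import bh_adjust

    grid = []
    for ep, res in fits.items():
        est = res.estimates.reset_index()
        est.insert(0, "endpoint", ep)
        grid.append(est)
    grid = pd.concat(grid, ignore_index=True)
    grid["p_bh"] = bh_adjust(grid["p_raw"].to_numpy())
    grid["significant"] = grid["p_bh"] < 0.05
    report = {
        "hazard_ratios": grid.to_dict(orient="records"),
        "balance": balance.reset_index().to_dict(orient="records"),
        "weight_summary": weight_summary.to_dict(orient="records"),
        "config": config_echo,
        "n_cells": int(len(grid)),
    }
    return report


def write_report(report: dict, path: str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
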