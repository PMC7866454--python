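"""Marginal structural Cox models for multi-level drug exposure.

:class:`MarginalStructuralCox` is built from a person-period table carrying
time-updated exposure-level codes for the three cardiovascular drug-class
groups and (optionally) per-period inverse-probability weights; ``fit()``
returns an :class:`MSMResults` with hazard ratios, robust confidence
intervals, raw and Benjamini–Hochberg-adjusted p-values, per-level event
counts, a ``summary()`` table and a proportional-hazards test.

The reference level defaults to never-exposed; refitting against a
different reference (:func:`refit_reference`) is an exact reparametrization,
so the consistent-vs-recent hazard ratio equals the ratio of the two
never-referenced hazard ratios up to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._coxengine import CoxFit, fit_cox, schoenfeld_test
from .config import CLASS_GROUPS, LEVEL_CODES, LEVEL_NAMES

__all__ = [
    "MarginalStructuralCox",
    "MSMResults",
    "refit_reference",
    "bh_adjust",
]

#: sublevel codes used in the ``llt_sub`` person-period column
LLT_SUB_NAMES = {1: "statin_only", 2: "combination", 3: "statin_free"}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def _exposure_design(periods: pd.DataFrame, reference: str,
                     groups, llt_sublevels: bool):
    """Indicator columns for every non-reference exposure level."""
    ref_code = LEVEL_CODES[reference]
    cols, names = [], []
    for grp in groups:
        level = periods[f"{grp}_level"].to_numpy()
        for code, name in enumerate(LEVEL_NAMES):
            if code == ref_code:
                continue
            mask = level == code
            if llt_sublevels and grp == "llt" and name == "consistent":
                sub = periods["llt_sub"].to_numpy()
                for sc, sname in LLT_SUB_NAMES.items():
                    cols.append((mask & (sub == sc)).astype(float))
                    names.append(f"llt:consistent:{sname}")
            elif llt_sublevels and grp == "llt" and name in ("remote",
                                                             "recent_inconsistent"):
                statin = periods["llt_statin_containing"].to_numpy(bool)
                for flag, sname in ((True, "statin_containing"),
                                    (False, "statin_free")):
                    cols.append((mask & (statin == flag)).astype(float))
                    names.append(f"llt:{name}:{sname}")
            else:
                cols.append(mask.astype(float))
                names.append(f"{grp}:{name}")
    X = np.column_stack(cols) if cols else np.empty((len(periods), 0))
    return X, names


@dataclass
class MSMResults:
    """Estimates from a fitted multi-level weighted Cox model."""

    model: "MarginalStructuralCox"
    fit: CoxFit
    terms: list
    dropped: list                       # terms with zero events
    estimates: pd.DataFrame = field(init=False)

    def __post_init__(self):
        se = self.fit.se
        beta = self.fit.params
        z = beta / se
        p = 2 * stats.norm.sf(np.abs(z))
        rows = []
        j = 0
        counts = self._event_counts()
        for term in self.terms + self.dropped:
            if term in self.dropped:
                rows.append({"term": term, "log_hr": np.nan, "hr": np.nan,
                             "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "p_raw": np.nan, "n_events": counts.get(term, 0)})
                continue
            rows.append({
                "term": term, "log_hr": beta[j], "hr": np.exp(beta[j]),
                "se": se[j],
                "ci_low": np.exp(beta[j] - 1.959963984540054 * se[j]),
                "ci_high": np.exp(beta[j] + 1.959963984540054 * se[j]),
                "p_raw": p[j], "n_events": counts.get(term, 0),
            })
            j += 1
        df = pd.DataFrame(rows).set_index("term")
        df["p_bh"] = bh_adjust(df["p_raw"].to_numpy())
        self.estimates = df

    def _event_counts(self):
        per = self.model.periods
        ev = per["event"].to_numpy(bool)
        X, names = self.model._design
        return {name: int(ev[X[:, k] > 0].sum()) for k, name in enumerate(names)}

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit.params, index=self.terms)

    def conf_int(self) -> pd.DataFrame:
        return self.estimates[["ci_low", "ci_high"]]

    def ph_test(self) -> pd.DataFrame:
        """Scaled Schoenfeld residual test against time, per term and global."""
        res = schoenfeld_test(self.fit)
        df = pd.DataFrame({"chi2": res["chi2"], "p": res["p"]},
                          index=self.terms)
        df.loc["GLOBAL"] = [res["global_chi2"], res["global_p"]]
        return df

    def summary(self) -> str:
        lines = [
            "Marginal structural Cox model "
            f"(reference level: {self.model.reference})",
            f"periods: {len(self.model.periods)}   "
            f"events: {self.fit.n_events}   "
            f"weighted: {self.model.weight_col is not None}",
            "",
            self.estimates.round(4).to_string(),
        ]
        return "\n".join(lines)


class MarginalStructuralCox:
    """Weighted multi-level-exposure Cox model on counting-process data.

    Parameters
    ----------
    periods
        Person-period table with ``pid``, ``start``, ``stop``, ``event`` and
        one ``<group>_level`` code column per class group (plus sublevel
        columns when ``llt_sublevels`` is used).
    weight_col
        Column of per-period total weights; None fits the unweighted model.
    reference
        Reference exposure level, default ``"never"``.
    """

    def __init__(self, periods: pd.DataFrame, weight_col: str | None = "w_total",
                 reference: str = "never", groups=tuple(CLASS_GROUPS),
                 llt_sublevels: bool = False):
        if reference not in LEVEL_CODES:
            raise ValueError(f"unknown reference level {reference!r}")
        ref_code = LEVEL_CODES[reference]
        observed = np.unique(
            np.concatenate([periods[f"{g}_level"].to_numpy() for g in groups])
        )
        if ref_code not in observed:
            raise ValueError(f"reference level {reference!r} not observed")
        if len(observed) < 2:
            raise ValueError("only a single exposure level observed")
        self.periods = periods
        self.weight_col = weight_col
        self.reference = reference
        self.groups = tuple(groups)
        self.llt_sublevels = llt_sublevels
        self._design = _exposure_design(periods, reference, self.groups,
                                        llt_sublevels)

    def fit(self, robust: bool = True, ties: str = "efron") -> MSMResults:
        X, names = self._design
        ev = self.periods["event"].to_numpy(bool)
        keep, dropped = [], []
        for k, name in enumerate(names):
            if ev[X[:, k] > 0].sum() == 0 or X[:, k].std() == 0:
                dropped.append(name)
            else:
                keep.append(k)
        Xk = X[:, keep]
        w = None if self.weight_col is None else \
            self.periods[self.weight_col].to_numpy(float)
        fit = fit_cox(Xk, self.periods["start"].to_numpy(float),
                      self.periods["stop"].to_numpy(float), ev, w,
                      cluster=self.periods["pid"].to_numpy(),
                      ties=ties, robust=robust)
        return MSMResults(model=self, fit=fit,
                          terms=[names[k] for k in keep], dropped=dropped)


def refit_reference(model: MarginalStructuralCox, reference: str,
                    **fit_kwargs) -> MSMResults:
    """Refit the identical model with a different reference level."""
    m = MarginalStructuralCox(
        model.periods, weight_col=model.weight_col, reference=reference,
        groups=model.groups, llt_sublevels=model.llt_sublevels,
    )
    return m.fit(**fit_kwargs)
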