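"""Four-level time-updated exposure classification, sublevels and variants.

At every anchor a drug-class group is in exactly one of four mutually
exclusive levels:

``consistent``
    use in >= 11 of the 12 trailing month blocks *and* trailing one-year
    PDC > 0.91 (strict), optionally gated on a covered day within the last
    30 days;
``recent_inconsistent``
    any covered day in the trailing year, but not consistent;
``remote``
    prior use, none of it in the trailing year;
``never``
    no covered day up to the anchor (reference category).

Sublevels differentiate statin-only / combination / statin-free use within
consistent LLT (statin-containing vs statin-free for recent/remote) and
single vs combination antihypertensive use.  The ongoing-current-use variant
(>= 3 of the past 4 weeks with use) and the since-initiation sensitivity
redefinition of consistency (> 91.5% coverage during the first year after
the first fill) support the additional analyses.
"""

from __future__ import annotations

import numpy as np

from .config import (
    LEVEL_CONSISTENT,
    LEVEL_NEVER,
    LEVEL_RECENT,
    LEVEL_REMOTE,
    LEVEL_NAMES,
    LevelRules,
    MONTH_DAYS,
    YEAR_DAYS,
)
from .coverage import cumulative_coverage, pdc_at, window_count

__all__ = [
    "months_with_use",
    "classify_levels",
    "classify",
    "classify_llt_sublevel",
    "classify_aht_sublevel",
    "classify_current_use",
    "classify_sensitivity_consistent",
]

#: month-block boundaries (days before the anchor) for the 11/12 criterion
_MONTH_EDGES = np.round(np.arange(13) * MONTH_DAYS).astype(np.int64)


def months_with_use(C: np.ndarray, rows, anchors) -> np.ndarray:
    """Number of the 12 trailing ~30.44-day month blocks with >= 1 covered day."""
    anchors = np.asarray(anchors, dtype=np.int64)
    H = C.shape[1] - 1
    edges = np.clip(anchors[:, None] - _MONTH_EDGES[None, ::-1] + 1, 0, H)
    vals = C[np.asarray(rows)[:, None], edges]
    return np.count_nonzero(np.diff(vals, axis=1) > 0, axis=1)


def classify_levels(C: np.ndarray, rows, anchors, obs_start=0,
                    rules: LevelRules = LevelRules()) -> np.ndarray:
    """Vectorized level codes for (row, anchor) pairs.

    ``C`` is a cumulative coverage matrix (see
    :func:`rxmsm.coverage.cumulative_coverage`); ``rows`` indexes patients and
    ``anchors`` gives the anchor day of each classification.
    """
    anchors = np.asarray(anchors, dtype=np.int64)
    rows = np.broadcast_to(np.asarray(rows, dtype=np.int64), anchors.shape)
    if np.any(anchors < np.asarray(obs_start)):
        raise ValueError("anchor before start of observation")

    last_year = window_count(C, rows, anchors - YEAR_DAYS, anchors) > 0
    ever_before = window_count(C, rows, -1, anchors - YEAR_DAYS) > 0
    pdc = pdc_at(C, rows, anchors, obs_start)
    cand = pdc > rules.consistent_pdc
    if rules.consistent_recency_days is not None:
        cand &= window_count(
            C, rows, anchors - rules.consistent_recency_days, anchors
        ) > 0
    # the 11-of-12-month-blocks check is only needed where the PDC gate holds
    consistent = np.zeros(anchors.shape, dtype=bool)
    if cand.any():
        sel = np.flatnonzero(cand)
        months = months_with_use(C, rows[sel], anchors[sel])
        consistent[sel] = months >= rules.consistent_months

    level = np.full(anchors.shape, LEVEL_NEVER, dtype=np.int8)
    level[ever_before] = LEVEL_REMOTE
    level[last_year] = LEVEL_RECENT
    level[consistent & last_year] = LEVEL_CONSISTENT
    return level


def classify(cov: np.ndarray, anchor: int, obs_start: int = 0,
             rules: LevelRules = LevelRules()) -> str:
    """Level name of one calendar at one anchor (single-patient operation)."""
    C = cumulative_coverage(cov)
    code = classify_levels(C, np.zeros(1, dtype=np.int64),
                           np.asarray([anchor]), obs_start, rules)[0]
    return LEVEL_NAMES[code]


# ---------------------------------------------------------------------------
# Sublevels
# ---------------------------------------------------------------------------

def classify_llt_sublevel(statin_cov: np.ndarray, nonstatin_cov: np.ndarray,
                          anchor: int, level: str) -> str:
    """Statin-only / combination / statin-free sublevel of an LLT level.

    For the consistent level the split is three-way over the covered days of
    the trailing year; for recent/remote levels it is the binary
    statin-containing vs statin-free distinction over the relevant window.
    """
    if level == "never":
        raise ValueError("sublevel undefined for the never level")
    Cs = cumulative_coverage(statin_cov)
    Cn = cumulative_coverage(nonstatin_cov)
    row = np.zeros(1, dtype=np.int64)
    if level == "remote":
        lo, hi = -1, anchor - YEAR_DAYS
    else:
        lo, hi = anchor - YEAR_DAYS, anchor
    s = window_count(Cs, row, lo, hi)[0] > 0
    n = window_count(Cn, row, lo, hi)[0] > 0
    if level == "consistent":
        if s and not n:
            return "statin_only"
        if n and not s:
            return "statin_free"
        return "combination"
    return "statin_containing" if s else "statin_free"


def classify_aht_sublevel(subclass_covs: dict, anchor: int, level: str) -> str:
    """Single vs combination antihypertensive use over the trailing year."""
    if level == "never":
        raise ValueError("sublevel undefined for the never level")
    row = np.zeros(1, dtype=np.int64)
    active = 0
    for cov in subclass_covs.values():
        C = cumulative_coverage(cov)
        active += int(window_count(C, row, anchor - YEAR_DAYS, anchor)[0] > 0)
    return "single" if active <= 1 else "combination"


# ---------------------------------------------------------------------------
# Variants for the additional analyses
# ---------------------------------------------------------------------------

def classify_current_use(cov: np.ndarray, anchor: int) -> bool:
    """Ongoing current use: >= 3 of the past 4 trailing 7-day blocks with use."""
    C = cumulative_coverage(cov)
    row = np.zeros(1, dtype=np.int64)
    weeks = 0
    for j in range(4):
        hi = anchor - 7 * j
        lo = anchor - 7 * (j + 1)
        weeks += int(window_count(C, row, lo, hi)[0] > 0)
    return weeks >= 3


def classify_sensitivity_consistent(cov: np.ndarray, anchor: int,
                                    first_fill_day: int,
                                    rules: LevelRules = LevelRules()) -> bool:
    """Immortal-time sensitivity redefinition of the consistent level.

    True iff the covered fraction between treatment initiation and
    ``min(initiation + 365, anchor)`` exceeds 0.915.
    """
    if first_fill_day is None or first_fill_day > anchor:
        raise ValueError("no treatment initiation before the anchor")
    end = min(first_fill_day + YEAR_DAYS, anchor)
    span = max(end - first_fill_day, 1)
    covered = int(np.count_nonzero(cov[first_fill_day:end]))
    return covered / span > rules.sensitivity_pdc


def sensitivity_consistent_matrix(C: np.ndarray, rows, anchors, first_fill,
                                  rules: LevelRules = LevelRules()) -> np.ndarray:
    """Vectorized since-initiation consistency flag for (row, anchor) pairs.

    ``first_fill`` is the per-row initiation day (large sentinel if never
    filled); anchors at or before initiation yield False.
    """
    anchors = np.asarray(anchors, dtype=np.int64)
    rows = np.broadcast_to(np.asarray(rows, dtype=np.int64), anchors.shape)
    ff = np.asarray(first_fill, dtype=np.int64)[rows]
    end = np.minimum(ff + YEAR_DAYS, anchors)
    span = np.maximum(end - ff, 1)
    covered = window_count(C, rows, ff - 1, end - 1)
    ok = (ff <= anchors) & (covered / span > rules.sensitivity_pdc)
    return ok
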