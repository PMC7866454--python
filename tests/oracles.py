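"""Independent brute-force oracles used by the test suite.

These deliberately re-implement the pill-stock and trailing-window rules as
literal day-by-day simulations, independent of the vectorized interval
arithmetic in the package.
"""

from __future__ import annotations

import numpy as np


def brute_force_coverage(fills, stays, horizon, cap=90):
    """Day-by-day pill-stock simulation for one patient and drug class.

    ``fills``: iterable of (day, days_supply, drug) sorted or not;
    ``stays``: iterable of (admit, discharge) inclusive.  Rules: a fill adds
    supply (same drug stacks remaining stock up to ``cap``; a different drug
    resets), outpatient days consume one day of stock, a day is covered iff
    stock is positive at day start, and inpatient days are covered without
    consuming stock from the first fill of the class onward.
    """
    inpatient = np.zeros(horizon, dtype=bool)
    for a, d in stays:
        inpatient[max(a, 0):min(d + 1, horizon)] = True
    fills = sorted(fills, key=lambda f: f[0])
    by_day = {}
    for day, supply, drug in fills:
        by_day.setdefault(day, []).append((supply, drug))
    first_fill = fills[0][0] if fills else horizon
    stock = 0
    current_drug = None
    cov = np.zeros(horizon, dtype=bool)
    for t in range(horizon):
        for supply, drug in by_day.get(t, ()):
            if drug == current_drug:
                stock = min(stock, cap) + supply
            else:
                stock = supply
                current_drug = drug
        covered = stock > 0 or (inpatient[t] and t >= first_fill)
        if stock > 0 and not inpatient[t]:
            stock -= 1
        cov[t] = covered
    return cov


def brute_force_pdc(cov, anchor, obs_start=0, window=365):
    """Direct covered-day count over (anchor-window, anchor]."""
    lo = max(anchor - window + 1, obs_start, 0)
    covered = int(np.sum(cov[lo:anchor + 1]))
    denom = min(window, anchor - obs_start)
    return covered / max(denom, 1)


def bh_stepup(p):
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, prev)
        adj[i] = val
        prev = val
    return adj
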