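"""Normalization and pooled distribution of eye-reversal timings.

Because reversal-timing distributions differ across observers, each
observer's timings are normalized over all of their trials from both
conditions combined before pooling.  The pooled per-group histograms use a
fixed 0.25 bin width anchored at zero, and unimodality of the pooled
unpredictable-condition distribution is quantified with Hartigan's dip
statistic and a bootstrap p value against the uniform null (the least
favorable unimodal distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIST_BIN_WIDTH = 0.25


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedTimings:
    """Per-trial normalized values plus the per-observer constants used."""

    values: pd.Series            # aligned on the trial-table index
    center: dict                 # observer -> ms subtracted
    scale: dict                  # observer -> ms divided by
    method: str


def normalize_timings(table: pd.DataFrame,
                      method: str = "zscore") -> NormalizedTimings:
    """Normalize each observer's timings over both conditions combined.

    ``method='zscore'`` subtracts the observer's pooled mean and divides by
    the pooled (population) SD; ``method='center'`` only subtracts the mean.
    Only included trials are normalized; observers with zero pooled SD are
    rejected.
    """
    if method not in ("zscore", "center"):
        raise ValueError("method must be 'zscore' or 'center'")
    inc = table[table["included"]]
    values = pd.Series(np.nan, index=table.index, dtype=float)
    center, scale = {}, {}
    for obs, g in inc.groupby("observer"):
        if g["condition"].nunique() < 2:
            logger.warning("observer %s lacks one condition; normalization "
                           "pools whatever trials are present", obs)
        mu = float(g["eye_reversal"].mean())
        sd = float(g["eye_reversal"].std(ddof=0))
        if method == "zscore" and sd == 0:
            raise ValueError(
                f"observer {obs} has zero timing variance; cannot z-score")
        s = sd if method == "zscore" else 1.0
        center[obs], scale[obs] = mu, s
        values.loc[g.index] = (g["eye_reversal"] - mu) / s
    return NormalizedTimings(values=values, center=center, scale=scale,
                             method=method)


# ---------------------------------------------------------------------------
# pooled histogram
# ---------------------------------------------------------------------------

@dataclass
class PooledHistogram:
    """Fixed-width histograms per group with bin edges anchored at 0."""

    bin_edges: np.ndarray
    counts: dict     # group label -> counts per bin
    medians: dict    # group label -> median of the group's values
    group_sizes: dict


def pooled_histogram(values_by_group: dict,
                     bin_width: float = HIST_BIN_WIDTH) -> PooledHistogram:
    """Histogram each group's values on a shared grid of 0-anchored bins."""
    allv = np.concatenate([np.asarray(v, float) for v in
                           values_by_group.values()])
    if not np.all(np.isfinite(allv)):
        raise ValueError("values must be finite")
    lo = np.floor(allv.min() / bin_width) * bin_width
    hi = np.ceil(allv.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, medians, sizes = {}, {}, {}
    for label, v in values_by_group.items():
        v = np.asarray(v, float)
        c, _ = np.histogram(v, bins=edges)
        counts[label] = c
        medians[label] = float(np.median(v))
        sizes[label] = len(v)
    return PooledHistogram(bin_edges=edges, counts=counts, medians=medians,
                           group_sizes=sizes)


# ---------------------------------------------------------------------------
# Hartigan's dip statistic
# ---------------------------------------------------------------------------

def dip_statistic(x) -> float:
    """Hartigan & Hartigan's dip: sup-distance to the closest unimodal CDF.

    Computed with the greatest-convex-minorant / least-concave-majorant
    iteration on the empirical CDF.  Returns 0 for degenerate samples; the
    minimum attainable value for n distinct points is ``1/(2n)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0
    # 1-based arrays to keep the hull recursions readable
    xv = np.concatenate([[0.0], x])
    mn = np.zeros(n + 1, dtype=int)
    mj = np.zeros(n + 1, dtype=int)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or ((xv[j] - xv[mnj]) * (mnj - mnmnj)
                            < (xv[mnj] - xv[mnmnj]) * (j - mnj)):
                break
            mn[j] = mnmnj
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or ((xv[k] - xv[mjk]) * (mjk - mjmjk)
                            < (xv[mjk] - xv[mjmjk]) * (k - mjk)):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0
    gcm = np.zeros(n + 2, dtype=int)
    lcm = np.zeros(n + 2, dtype=int)
    while True:
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = ig = i
        ix = i - 1
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = ih = i
        iv = 2

        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = ((lcmiv - gcmi1 + 1)
                          - (xv[lcmiv] - xv[gcmi1]) * (gcmix - gcmi1)
                          / (xv[gcmix] - xv[gcmi1]))
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = ((xv[gcmix] - xv[lcmiv1]) * (lcmiv - lcmiv1)
                          / (xv[lcmiv] - xv[lcmiv1])
                          - (gcmix - lcmiv1 - 1))
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv
                ix = max(ix, 1)
                iv = min(iv, l_lcm)
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and xv[je] != xv[jb]:
                c = (je - jb) / (xv[je] - xv[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xv[jj] - xv[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and xv[je] != xv[jb]:
                c = (je - jb) / (xv[je] - xv[jb])
                for jj in range(jb, je + 1):
                    t = (xv[jj] - xv[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t
        dip = max(dip, dip_l, dip_u)
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]
    return dip / (2.0 * n)


def unimodality_check(values, n_boot: int = 200, rng=None):
    """Dip statistic with a bootstrap p value against the uniform null.

    Uniform samples of the same size form the null reference (the least
    favorable unimodal case); ``p`` is the fraction of null dips at or above
    the observed one.  This operationalizes a visual unimodality judgment:
    large p means "no evidence of multimodality".
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 50:
        raise ValueError("unimodality check needs n >= 50")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    d_obs = dip_statistic(values)
    null = np.array([dip_statistic(rng.uniform(size=len(values)))
                     for _ in range(n_boot)])
    p = float((np.sum(null >= d_obs) + 1) / (n_boot + 1))
    return d_obs, p
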