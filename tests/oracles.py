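"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain loops / direct definitions,
separate from the package's own algorithms.
"""

import numpy as np
from scipy.optimize import linprog


def scan_onset_and_reversal(t, v, threshold, search_start=-500.0):
    """Exhaustive sample scan applying the event-definition predicates.

    Returns (onset_ms, reversal_ms) or (None, None).  Onset: the first sample
    of the below-threshold run that reaches the first negative sample at or
    after ``search_start``; reversal: linear sub-sample interpolation of that
    zero crossing.
    """
    n = len(t)
    start = None
    for i in range(n):
        if t[i] >= search_start:
            start = i
            break
    if start is None:
        return None, None
    iz = None
    for i in range(start, n):
        if v[i] < 0:
            iz = i
            break
    if iz is None:
        return None, None
    io = iz
    while io - 1 >= start and v[io - 1] < threshold:
        io -= 1
    onset = t[io]
    # reversal: first negative sample after the onset time
    jz = None
    for i in range(n):
        if t[i] >= onset and v[i] < 0:
            jz = i
            break
    if jz is None:
        return onset, None
    if jz == 0 or v[jz - 1] < 0:
        reversal = t[jz]
    else:
        reversal = t[jz - 1] + (t[jz] - t[jz - 1]) * v[jz - 1] / (v[jz - 1] - v[jz])
    return onset, reversal


def vif_by_regression(X):
    """VIF_j = 1/(1-R^2_j) from explicitly regressing j on the others."""
    X = np.asarray(X, float)
    out = []
    for j in range(X.shape[1]):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        out.append(np.inf if ss_res <= 1e-12 * ss_tot else ss_tot / ss_res)
    return np.array(out)


def dip_by_lp(x):
    """Exact dip at small n: best unimodal-CDF fit solved as an LP per mode.

    The fitted CDF is convex left of the mode and concave right of it, with a
    jump allowed only at the mode; the sup-distance constraints use both the
    left and right limits of the empirical CDF at every data point.
    """
    x = np.sort(np.asarray(x, float))
    n = len(x)
    if np.any(np.diff(x) == 0):
        raise ValueError("LP oracle requires distinct values")
    best = np.inf
    for m in range(n):
        nv = n + 2  # g_0..g_{n-1}, g at mode right limit, t
        c = np.zeros(nv)
        c[n + 1] = 1.0
        A, b = [], []
        for i in range(n):
            gr = n if i == m else i
            for F, gi in (((i + 1) / n, gr), (i / n, i)):
                r = np.zeros(nv); r[gi] = 1.0; r[n + 1] = -1.0
                A.append(r); b.append(F)
                r = np.zeros(nv); r[gi] = -1.0; r[n + 1] = -1.0
                A.append(r); b.append(-F)
        for i in range(n - 1):
            lo = n if i == m else i
            r = np.zeros(nv); r[lo] = 1.0; r[i + 1] = -1.0
            A.append(r); b.append(0.0)
        r = np.zeros(nv); r[m] = 1.0; r[n] = -1.0
        A.append(r); b.append(0.0)
        for i in range(m - 1):
            if i + 2 > m:
                break
            x0, x1, x2 = x[i], x[i + 1], x[i + 2]
            r = np.zeros(nv)
            r[i] = 1.0 / (x1 - x0)
            r[i + 1] = -1.0 / (x1 - x0) - 1.0 / (x2 - x1)
            r[i + 2] = 1.0 / (x2 - x1)
            A.append(-r); b.append(0.0)   # convex: slopes nondecreasing
        for i in range(m, n - 2):
            g0 = n if i == m else i
            x0, x1, x2 = x[i], x[i + 1], x[i + 2]
            r = np.zeros(nv)
            r[g0] = 1.0 / (x1 - x0)
            r[i + 1] = -1.0 / (x1 - x0) - 1.0 / (x2 - x1)
            r[i + 2] = 1.0 / (x2 - x1)
            A.append(r); b.append(0.0)    # concave: slopes nonincreasing
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * (n + 1) + [(0, None)],
                      method="highs")
        if res.status == 0 and res.fun < best:
            best = res.fun
    return best
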