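"""Trial-history analyses of eye-reversal timing.

Two complementary routes quantify how preceding trials shape the current
predictive response:

* the **node (tree) method** — trials are grouped by a categorical property of
  the n-1 or n-2 trial (its target velocity, or whether its own reversal
  timing fell in the earliest/latest 20%) and the per-observer group means are
  compared with a paired t test;
* a grid of 15 **linear mixed-effects models** — reversal timing regressed on
  lagged target velocities (stimulus history) and lagged reversal timings
  (behavioral history) up to lag 5, with a per-observer random intercept,
  compared by AIC.

Lagged lookups never cross block boundaries, and the first trials of each
block serve as predictors only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

NODE_FRACTION = 0.2
MAX_LAG = 5
NODE_STIM_LEVELS = (4.0, 28.0)  # slowest / fastest leftward velocities

#: columns a trial table must provide
TRIAL_TABLE_COLUMNS = ("observer", "condition", "block", "trial",
                       "leftward_velocity", "eye_reversal", "included")


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    # keep the caller's index so externally computed labels stay aligned
    return table.sort_values(["observer", "block", "trial"], kind="stable")


# ---------------------------------------------------------------------------
# node method
# ---------------------------------------------------------------------------

def rank_classify(table: pd.DataFrame, frac: float = NODE_FRACTION,
                  min_cell: int = 5) -> pd.Series:
    """Label each included trial UPPER / LOWER / middle within its cell.

    Within every (observer, target velocity) cell the included reversal
    timings are ranked ascending (stable tie-break by trial order); the first
    ``floor(frac * n)`` trials are UPPER (earliest), the last the same number
    LOWER (latest).  Cells smaller than ``min_cell`` are skipped with a
    warning.  Returns a Series aligned on ``table``'s index with NaN for
    excluded or skipped trials.
    """
    table = table.sort_values(["observer", "block", "trial"], kind="stable")
    labels = pd.Series(np.nan, index=table.index, dtype=object)
    inc = table[table["included"]]
    for (obs, vel), cell in inc.groupby(["observer", "leftward_velocity"]):
        n = len(cell)
        if n < min_cell:
            logger.warning("node cell (%s, %g deg/s) has only %d trials; "
                           "skipped", obs, vel, n)
            continue
        k = int(np.floor(frac * n))
        order = cell["eye_reversal"].sort_values(kind="stable").index
        labels.loc[order] = "middle"
        labels.loc[order[:k]] = "UPPER"
        labels.loc[order[n - k:]] = "LOWER"
    return labels


def node_sort(table: pd.DataFrame, lag: int, by: str,
              stim_levels=NODE_STIM_LEVELS,
              labels: pd.Series | None = None) -> pd.DataFrame:
    """Per-observer mean current-trial timing grouped by the n-lag trial.

    ``by='stimulus'`` groups trials by whether the n-lag target velocity was
    the slowest or fastest level; ``by='behavior'`` by whether the n-lag trial
    was classified UPPER or LOWER (``labels`` from :func:`rank_classify`,
    computed here if omitted).  Lags never cross block boundaries and only
    included current trials enter the means.  Returns a frame indexed by
    observer with columns ``group_a_mean`` / ``group_b_mean`` (a = slowest or
    UPPER, b = fastest or LOWER), counts, and the pooled right-node mean.
    """
    if by not in ("stimulus", "behavior"):
        raise ValueError("by must be 'stimulus' or 'behavior'")
    if lag not in (1, 2):
        raise ValueError("node sorting uses lag 1 or 2")
    table = _check_table(table)
    if by == "behavior" and labels is None:
        labels = rank_classify(table)
    rows = []
    for obs, sub in table.groupby("observer"):
        a_vals, b_vals = [], []
        for _, blk in sub.groupby("block"):
            idx = blk.index.to_numpy()
            for j in range(lag, len(idx)):
                cur, prev = blk.iloc[j], blk.iloc[j - lag]
                if not cur["included"]:
                    continue
                if by == "stimulus":
                    if prev["leftward_velocity"] == stim_levels[0]:
                        a_vals.append(cur["eye_reversal"])
                    elif prev["leftward_velocity"] == stim_levels[1]:
                        b_vals.append(cur["eye_reversal"])
                else:
                    lab = labels.loc[idx[j - lag]]
                    if lab == "UPPER":
                        a_vals.append(cur["eye_reversal"])
                    elif lab == "LOWER":
                        b_vals.append(cur["eye_reversal"])
        if not a_vals or not b_vals:
            logger.warning("observer %s has an empty node group; dropped "
                           "from the paired comparison", obs)
            continue
        pooled = a_vals + b_vals
        rows.append({"observer": obs,
                     "group_a_mean": float(np.mean(a_vals)),
                     "group_b_mean": float(np.mean(b_vals)),
                     "n_a": len(a_vals), "n_b": len(b_vals),
                     "right_node_mean": float(np.mean(pooled))})
    return pd.DataFrame(rows).set_index("observer")


def paired_t(group_a, group_b) -> dict:
    """Paired t test with Cohen's d computed on the paired differences."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need equal-length paired vectors with n >= 3")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        logger.warning("paired differences have zero variance")
        p = 0.0 if diff.mean() != 0 else 1.0
        return {"t": np.inf if diff.mean() > 0 else (-np.inf if diff.mean() < 0 else 0.0),
                "df": len(a) - 1, "p": p, "cohens_d": np.inf if diff.mean() != 0 else 0.0}
    t, p = sstats.ttest_rel(a, b)
    return {"t": float(t), "df": len(a) - 1, "p": float(p),
            "cohens_d": float(diff.mean() / sd)}


# ---------------------------------------------------------------------------
# history design and mixed models
# ---------------------------------------------------------------------------

def build_history_design(table: pd.DataFrame, ks: int, kb: int,
                         min_history: int | None = None) -> pd.DataFrame:
    """Lagged-predictor design for the mixed models.

    Each response row pairs the current included trial's timing with the
    target velocities of the ``ks`` preceding trials and the reversal timings
    of the ``kb`` preceding trials of the same block.  Rows are dropped when
    any required lag falls before the block start or on an excluded trial
    (complete-case rule); the first ``min_history`` trials of every block
    (default ``max(ks, kb)``) therefore appear only as predictors.
    """
    if ks == 0 and kb == 0:
        raise ValueError("at least one history type must be included")
    if max(ks, kb) > MAX_LAG:
        raise ValueError(f"lags beyond {MAX_LAG} are not supported")
    min_history = max(ks, kb) if min_history is None else min_history
    table = _check_table(table)
    rows = []
    for (obs, blk_id), blk in table.groupby(["observer", "block"]):
        v = blk["leftward_velocity"].to_numpy()
        rev = blk["eye_reversal"].to_numpy()
        inc = blk["included"].to_numpy()
        for j in range(min_history, len(blk)):
            if not inc[j]:
                continue
            row = {"observer": obs, "block": blk_id,
                   "trial": blk["trial"].iloc[j], "eye_reversal": rev[j]}
            ok = True
            for k in range(1, ks + 1):
                row[f"stim_lag{k}"] = v[j - k]
            for k in range(1, kb + 1):
                if not inc[j - k] or not np.isfinite(rev[j - k]):
                    ok = False
                    break
                row[f"behav_lag{k}"] = rev[j - k]
            if ok:
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LMEResult:
    """One fitted mixed model of the 15-model grid."""

    model_id: int
    predictors: list
    estimates: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    random_intercept_var: float
    residual_var: float
    llf: float
    aic: float
    n_obs: int
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.estimates, "se": self.se,
                             "t": self.tvalues, "p": self.pvalues})


def fit_lme(design: pd.DataFrame, predictors=None,
            model_id: int = 0) -> LMEResult:
    """Random-intercept mixed model of reversal timing, fitted by ML.

    Maximum likelihood (not REML) is used so AIC values are comparable
    across fixed-effect sets.  Wald t statistics use residual degrees of
    freedom ``n - k`` (k = number of fixed effects).  AIC counts every
    estimated parameter: fixed effects, the random-intercept variance and the
    residual variance.
    """
    if design["observer"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 observers")
    if predictors is None:
        predictors = [c for c in design.columns
                      if c.startswith(("stim_lag", "behav_lag"))]
    X = sm.add_constant(design[list(predictors)].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    md = sm.MixedLM(design["eye_reversal"].astype(float), X,
                    groups=design["observer"])
    import warnings as _warnings
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = md.fit(reml=False)
        # gradient optimizers occasionally stall on the zero-variance
        # boundary with a spurious infinite likelihood; derivative-free
        # restarts recover the interior ML solution
        for method in ("powell", "nm"):
            if (np.isfinite(res.llf)
                    and np.all(np.isfinite(np.asarray(res.bse_fe)))):
                break
            res = md.fit(reml=False, method=method)
    if not np.isfinite(res.llf):
        raise ValueError(
            "singular mixed-model fit: non-finite likelihood at "
            f"random-intercept variance {float(res.cov_re.iloc[0, 0]):g}")
    if not res.converged:
        logger.warning("mixed model %d did not converge cleanly", model_id)
    k_fixed = X.shape[1]
    n = len(design)
    fe = res.fe_params
    se = res.bse_fe
    tvals = fe / se
    df_resid = n - k_fixed
    pvals = 2.0 * sstats.t.sf(np.abs(tvals), df=df_resid)
    n_params = k_fixed + 2  # + random-intercept variance + residual variance
    aic = 2.0 * n_params - 2.0 * res.llf
    return LMEResult(model_id=model_id, predictors=list(predictors),
                     estimates=fe, se=se, tvalues=tvals,
                     pvalues=pd.Series(pvals, index=fe.index),
                     df_resid=df_resid,
                     random_intercept_var=float(res.cov_re.iloc[0, 0]),
                     residual_var=float(res.scale), llf=float(res.llf),
                     aic=float(aic), n_obs=n, converged=bool(res.converged))


def model_grid() -> list:
    """The 15 candidate predictor sets: stimulus-only, behavior-only, both."""
    grid = []
    for k in range(1, 6):
        grid.append((k, [f"stim_lag{j}" for j in range(1, k + 1)]))
    for k in range(1, 6):
        grid.append((5 + k, [f"behav_lag{j}" for j in range(1, k + 1)]))
    for k in range(1, 6):
        grid.append((10 + k, [f"stim_lag{j}" for j in range(1, k + 1)]
                     + [f"behav_lag{j}" for j in range(1, k + 1)]))
    return grid


def model_grid_and_select(table: pd.DataFrame):
    """Fit the 15-model grid on a common row set and pick the minimum AIC.

    All models are fitted on the row set of the largest model (lags to n-5)
    so their AICs are comparable.  Returns ``(list[LMEResult], selected_id)``.
    """
    design = build_history_design(table, ks=MAX_LAG, kb=MAX_LAG)
    results = []
    for mid, predictors in model_grid():
        try:
            results.append(fit_lme(design, predictors, model_id=mid))
        except Exception as exc:  # noqa: BLE001 - selection over fitted subset
            logger.warning("model %d failed to fit (%s); selection proceeds "
                           "over the remaining models", mid, exc)
    if not results:
        raise RuntimeError("no mixed model could be fitted")
    selected = min(results, key=lambda r: r.aic).model_id
    return results, selected


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def compute_vif(design: pd.DataFrame, predictors=None) -> pd.Series:
    """Variance inflation factors, ``1 / (1 - R^2_j)`` per predictor.

    Computed from the inverse of the predictor correlation matrix; a
    perfectly collinear set yields ``inf`` for its members, which are named
    in a warning.
    """
    if predictors is None:
        predictors = [c for c in design.columns
                      if c.startswith(("stim_lag", "behav_lag"))]
    if len(predictors) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = design[list(predictors)].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("a predictor is constant; VIF undefined")
    R = np.corrcoef(Xc, rowvar=False)
    try:
        vif = np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        vif = None
    if vif is None or np.any(vif < 0) or not np.all(np.isfinite(vif)):
        # singular correlation matrix: fall back to per-predictor regressions
        vif = np.empty(len(predictors))
        for j in range(len(predictors)):
            others = np.delete(Xc, j, axis=1)
            coef, *_ = np.linalg.lstsq(others, Xc[:, j], rcond=None)
            resid = Xc[:, j] - others @ coef
            ss_res = float(resid @ resid)
            ss_tot = float(Xc[:, j] @ Xc[:, j])
            vif[j] = np.inf if ss_res <= 1e-12 * ss_tot else ss_tot / ss_res
        if np.any(np.isinf(vif)):
            bad = [p for p, v in zip(predictors, vif) if np.isinf(v)]
            logger.warning("perfectly collinear predictors: %s", bad)
    return pd.Series(vif, index=list(predictors))


def within_subject_correlation(x, y, subject):
    """Repeated-observations correlation after removing per-subject means.

    Equivalent to the analysis-of-covariance decomposition: the correlation
    of the subject-mean-centered variables, with
    ``df = N - n_subjects - 1`` and a t-based two-sided p value.  Subjects
    with constant x contribute no within-subject variance.
    """
    df_in = pd.DataFrame({"x": np.asarray(x, float),
                          "y": np.asarray(y, float),
                          "s": np.asarray(subject)})
    if df_in["s"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    sxx = sxy = syy = 0.0
    for _, g in df_in.groupby("s"):
        if len(g) < 3:
            raise ValueError("need at least 3 pairs per subject")
        xc = g["x"] - g["x"].mean()
        yc = g["y"] - g["y"].mean()
        if float(xc @ xc) == 0:
            logger.warning("a subject has constant x; it contributes no "
                           "within-subject variance")
        sxx += float(xc @ xc)
        sxy += float(xc @ yc)
        syy += float(yc @ yc)
    if sxx == 0 or syy == 0:
        raise ValueError("no within-subject variance")
    r = sxy / np.sqrt(sxx * syy)
    dof = len(df_in) - df_in["s"].nunique() - 1
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(dof / (1.0 - r_clip**2))
    p = 2.0 * sstats.t.sf(abs(t), df=dof)
    return float(r), float(p)
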