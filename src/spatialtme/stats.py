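"""Group comparisons, multiplicity correction, ROC model comparison, and
Kaplan-Meier / log-rank survival analysis for the cohort matrix.

Test choice follows the normality-gated policy: two-sided Student's t when
both groups pass Shapiro-Wilk at 0.05, otherwise the Wilcoxon rank-sum
(Mann-Whitney) test; p-values are Benjamini-Hochberg adjusted across the
metric family of one invocation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NON_RESPONDER = "non_responder"
RESPONDER = "responder"


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    metric: str
    mean_responder: float
    mean_nonresponder: float
    test: str  # student_t | welch_t | wilcoxon
    statistic: float
    p_raw: float
    p_bh: float = float("nan")
    significant: bool = False


def _is_normalish(x: np.ndarray, alpha: float = 0.05) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue >= alpha


def compare_groups(
    matrix: pd.DataFrame,
    metrics: "list[str]",
    group_col: str = "response",
    policy: str = "auto",
    alpha: float = 0.05,
    shapiro_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided responder vs non-responder comparison per metric with BH
    adjustment across the family.

    ``policy``: ``"auto"`` (Shapiro-gated t vs Wilcoxon), ``"student_t"``,
    ``"welch_t"``, or ``"wilcoxon"``.  Metrics with <2 observations in either
    group are skipped with a warning; perfectly tied data yield p = 1.
    """
    groups = matrix[group_col]
    results: list[GroupComparison] = []
    for metric in metrics:
        x = matrix.loc[groups == RESPONDER, metric].dropna().to_numpy(dtype=float)
        y = matrix.loc[groups == NON_RESPONDER, metric].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            logger.warning("metric %s skipped: fewer than 2 observations per group", metric)
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            # all observations identical: no evidence against the null
            results.append(
                GroupComparison(metric, float(x.mean()), float(y.mean()),
                                "wilcoxon", 0.0, 1.0)
            )
            continue
        if policy == "auto":
            test = (
                "student_t"
                if _is_normalish(x, shapiro_alpha) and _is_normalish(y, shapiro_alpha)
                else "wilcoxon"
            )
        elif policy in ("student_t", "welch_t", "wilcoxon"):
            test = policy
        else:
            raise ValueError(f"unknown test policy {policy!r}")
        if test == "wilcoxon":
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        elif test == "student_t":
            res = sps.ttest_ind(x, y, equal_var=True)
        else:
            res = sps.ttest_ind(x, y, equal_var=False)
        results.append(
            GroupComparison(
                metric, float(x.mean()), float(y.mean()), test,
                float(res.statistic), float(min(res.pvalue, 1.0)),
            )
        )
    if results:
        p_bh = bh_adjust([r.p_raw for r in results])
        for r, p in zip(results, p_bh):
            r.p_bh = float(p)
            r.significant = bool(p <= alpha)
        logger.info("BH family: %s", [r.metric for r in results])
    return pd.DataFrame([r.__dict__ for r in results])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integers
    (sum of hypergeometric probabilities <= that of the observed table)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table counts must be nonnegative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table counts must be integers")
        t = np.round(t).astype(int)
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# ROC model comparison
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    label: str  # "pdl1_only" | "pdl1_plus_spatial"
    predictors: "list[str]"
    coefficients: dict
    auc: float
    curve: pd.DataFrame  # fpr, tpr
    separation_flagged: bool = False


def auc_rank(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formula; ties get midranks."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = sps.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve from (0,0) to (1,1), one step per distinct score."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / max(int(y.sum()), 1)]
    fpr = np.r_[0.0, fps[distinct] / max(int((~y).sum()), 1)]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def _fit_logistic(X: np.ndarray, y: np.ndarray, names: "list[str]"):
    """Maximum-likelihood logistic fit; falls back to a ridge-stabilised fit
    under (quasi-)separation.  Returns (linear predictor, coef dict, flagged)."""
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    flagged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e6:
            raise RuntimeError("diverged")
    except Exception:
        flagged = True
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e4, max_iter=5000)
        lr.fit(X, y)
        params = np.r_[lr.intercept_, lr.coef_.ravel()]
    eta = Xc @ params
    coefs = {"const": float(params[0])}
    coefs.update({n: float(b) for n, b in zip(names, params[1:])})
    return eta, coefs, flagged


def roc_compare(
    matrix: pd.DataFrame,
    outcome_col: str = "response",
    positive: str = NON_RESPONDER,
    spatial_predictors: "tuple[str, ...]" = ("eng_ec_ctl", "eng_htl_ctl"),
) -> tuple[RocResult, RocResult, float]:
    """Logistic models predicting non-response from TPS alone vs TPS plus the
    spatial engagement metrics; returns both fits and the AUC difference
    (combined minus TPS-only)."""
    df = matrix.dropna(subset=["tps_pct", *spatial_predictors, outcome_col])
    y = (df[outcome_col] == positive).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    results = []
    for label, predictors in (
        ("pdl1_only", ["tps_pct"]),
        ("pdl1_plus_spatial", ["tps_pct", *spatial_predictors]),
    ):
        X = df[predictors].to_numpy(dtype=float)
        eta, coefs, flagged = _fit_logistic(X, y, predictors)
        results.append(
            RocResult(
                label=label,
                predictors=predictors,
                coefficients=coefs,
                auc=auc_rank(eta, y),
                curve=roc_curve_points(eta, y),
                separation_flagged=flagged,
            )
        )
    return results[0], results[1], results[1].auc - results[0].auc


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    curves: pd.DataFrame  # stratum, time, at_risk, survival
    chi_sq: float
    p_value: float
    medians: dict  # stratum -> median survival (NaN when never below 0.5)
    strata: "list[str]"


def km_logrank(
    survival: pd.DataFrame,
    time_col: str = "time_months",
    event_col: str = "event",
    stratum_col: str = "stratum",
) -> KMResult:
    """Product-limit curves per stratum plus the k-group log-rank test.

    Empty strata are dropped with a warning; requires >=1 event overall and
    >=2 non-empty strata.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = survival.dropna(subset=[time_col, event_col, stratum_col]).copy()
    if int(df[event_col].sum()) < 1:
        raise ValueError("need at least one event for the log-rank test")
    sizes = df.groupby(stratum_col, observed=True).size()
    empty = [s for s in survival[stratum_col].dropna().unique() if sizes.get(s, 0) == 0]
    if empty:
        logger.warning("empty strata excluded: %s", empty)
    strata = list(sizes.index)
    if len(strata) < 2:
        raise ValueError("need >=2 non-empty strata")
    curve_frames = []
    medians = {}
    for s in strata:
        sub = df[df[stratum_col] == s]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], event_observed=sub[event_col], label=str(s))
        et = kmf.event_table
        curve_frames.append(
            pd.DataFrame(
                {
                    "stratum": str(s),
                    "time": et.index.to_numpy(dtype=float),
                    "at_risk": et["at_risk"].to_numpy(dtype=float),
                    "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
                }
            )
        )
        med = kmf.median_survival_time_
        medians[s] = float(med) if np.isfinite(med) else float("nan")
    lr = multivariate_logrank_test(df[time_col], df[stratum_col], df[event_col])
    return KMResult(
        curves=pd.concat(curve_frames, ignore_index=True),
        chi_sq=float(lr.test_statistic),
        p_value=float(lr.p_value),
        medians=medians,
        strata=[str(s) for s in strata],
    )
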