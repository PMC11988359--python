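"""Inferential layer: group comparisons, ROC/AUC analysis, combined models.

Per-lesion records (one row per lesion with ROI-mean parameters and group
labels) feed: unpaired t-tests per parameter (Welch by default — the group
standard deviations are unequal), empirical ROC analysis with DeLong
confidence intervals and a Youden-optimal cutoff, paired DeLong tests to
compare AUCs of two markers measured on the same lesions, in-sample
logistic regression to combine predictors, and immunohistochemical
subgroup comparisons among malignant lesions (Ki67 dichotomized at 14%).

The empirical AUC equals the normalized Mann–Whitney U statistic; the
DeLong variance uses the standard structural components of that U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "RocResult",
    "CombinedModel",
    "unpaired_t",
    "roc_analysis",
    "delong_compare",
    "combined_model",
    "ihc_subgroup_compare",
    "group_comparison_table",
]

#: Parameters compared between groups, in reporting order.
DEFAULT_PARAMS = ("v_in", "d", "cellularity", "d_ex",
                  "adc_pgse", "adc_ogse25", "adc_ogse50")


@dataclass(frozen=True)
class TTestResult:
    """Unpaired two-sample t-test summary."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    method: str


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary: AUC with DeLong 95% CI and the
    Youden-optimal operating point."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    orientation: int  # +1: larger score predicts positive; -1: flipped


@dataclass
class CombinedModel:
    """In-sample logistic combination of several predictors."""

    predictors: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    probabilities: np.ndarray
    roc: RocResult


def unpaired_t(group_a, group_b, method: str = "welch") -> TTestResult:
    """Two-sided unpaired t-test (``welch`` or ``student``)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method not in ("welch", "student"):
        raise ValueError("method must be 'welch' or 'student'")
    equal_var = method == "student"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return TTestResult(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=a.size,
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=b.size,
        t=float(res.statistic), df=float(df), p=float(res.pvalue), method=method,
    )


# ---------------------------------------------------------------------------
# Empirical AUC and DeLong machinery
# ---------------------------------------------------------------------------

def _mw_components(pos: np.ndarray, neg: np.ndarray):
    """Mann–Whitney kernel matrix and its structural components.

    psi(x, y) = 1 if x > y, 0.5 if tied, else 0; AUC = mean(psi);
    V10[i] = mean over negatives, V01[j] = mean over positives.
    """
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(), psi.mean(axis=1), psi.mean(axis=0)


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(scores, labels, ci: float = 0.95) -> RocResult:
    """Empirical ROC of a continuous score against binary labels.

    The score is oriented so AUC ≥ 0.5 (orientation −1 marks a flip);
    the AUC equals the normalized Mann–Whitney U; its CI is Wald-type
    with the DeLong variance, clipped to [0, 1]; the reported cutoff
    maximizes the Youden index J = sensitivity + specificity − 1 and is
    expressed on the original score scale.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc0, _, _ = _mw_components(s[y], s[~y])
    orientation = 1 if auc0 >= 0.5 else -1
    so = s * orientation
    auc, v10, v01 = _mw_components(so[y], so[~y])
    se = np.sqrt(_delong_variance(v10, v01))
    z = sps.norm.ppf(0.5 + ci / 2)
    lo, hi = np.clip([auc - z * se, auc + z * se], 0.0, 1.0)

    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, so)
    j = tpr - fpr
    k = int(np.argmax(j))
    return RocResult(
        auc=float(auc), ci_low=float(lo), ci_high=float(hi),
        cutoff=float(orientation * thr[k]),
        sensitivity=float(tpr[k]), specificity=float(1.0 - fpr[k]),
        orientation=orientation,
    )


def delong_compare(scores1, scores2, labels) -> float:
    """Two-sided p-value of the paired DeLong test for equal AUCs.

    Both scores must be measured on the same lesions; each is oriented
    so its AUC ≥ 0.5 before comparison (matching how single-marker AUCs
    are reported).
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s1.shape != s2.shape or s1.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    comps = []
    for s in (s1, s2):
        auc, v10, v01 = _mw_components(s[y], s[~y])
        if auc < 0.5:
            auc, v10, v01 = 1 - auc, 1 - v10, 1 - v01
        comps.append((auc, v10, v01))
    (a1, v10_1, v01_1), (a2, v10_2, v01_2) = comps
    m, n = v10_1.size, v01_1.size
    var = _delong_variance(v10_1, v01_1) + _delong_variance(v10_2, v01_2)
    if m > 1:
        var -= 2 * np.cov(v10_1, v10_2, ddof=1)[0, 1] / m
    if n > 1:
        var -= 2 * np.cov(v01_1, v01_2, ddof=1)[0, 1] / n
    if var <= 0 or a1 == a2:
        return 1.0
    z = (a1 - a2) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def combined_model(
    records: pd.DataFrame,
    predictors: tuple[str, ...],
    label_col: str = "group",
    positive: str = "malignant",
) -> CombinedModel:
    """In-sample logistic regression combining several predictors.

    Predictors are standardized (z-scores) and fitted by unpenalized
    maximum likelihood; the ROC is computed on the fitted in-sample
    probabilities, so a single-predictor model reproduces that
    predictor's empirical AUC exactly (probabilities are a monotone
    transform of the standardized score).
    """
    missing = [p for p in predictors if records[p].isna().any()]
    if missing:
        raise ValueError(f"missing values in predictors: {missing}")
    X = records.loc[:, list(predictors)].to_numpy(dtype=float)
    y = (records[label_col] == positive).to_numpy()
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor cannot be standardized")
    Xz = (X - mu) / sd

    from sklearn.linear_model import LogisticRegression

    # C = inf disables regularization: plain maximum likelihood
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    clf.fit(Xz, y)
    prob = clf.predict_proba(Xz)[:, 1]
    return CombinedModel(
        predictors=tuple(predictors),
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        probabilities=prob,
        roc=roc_analysis(prob, y),
    )


#: Ki67 positivity threshold (fraction of stained nuclei).
KI67_CUT = 0.14


def ihc_subgroup_compare(
    records: pd.DataFrame,
    marker: str,
    parameters: tuple[str, ...] = DEFAULT_PARAMS,
    method: str = "welch",
) -> pd.DataFrame:
    """Positive-vs-negative comparison of each parameter for one marker.

    Only malignant lesions are used. The marker column may be boolean
    (ER/PR/HER2 status) or numeric (Ki67 index, dichotomized at 14%).
    Returns one row per (marker, parameter) pair.
    """
    mal = records[records["group"] == "malignant"]
    col = mal[marker]
    if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
        status = col >= KI67_CUT
    else:
        status = col.astype(bool)
    if status.all() or not status.any():
        raise ValueError(f"both {marker} levels must be present")
    rows = []
    for par in parameters:
        if par not in mal.columns:
            continue
        res = unpaired_t(mal.loc[status, par], mal.loc[~status, par], method)
        rows.append({"marker": marker, "parameter": par,
                     "mean_positive": res.mean_a, "sd_positive": res.sd_a,
                     "mean_negative": res.mean_b, "sd_negative": res.sd_b,
                     "t": res.t, "p": res.p})
    return pd.DataFrame(rows)


def group_comparison_table(
    records: pd.DataFrame,
    parameters: tuple[str, ...] = DEFAULT_PARAMS,
    method: str = "welch",
    holm: bool = False,
) -> pd.DataFrame:
    """Malignant-vs-benign summary: means ± sd, p, AUC with CI and the
    Youden operating point, one row per parameter.

    ``holm=True`` adds Holm-adjusted p-values; by default p-values are
    reported unadjusted.
    """
    mal = records[records["group"] == "malignant"]
    ben = records[records["group"] == "benign"]
    y = (records["group"] == "malignant").to_numpy()
    rows = []
    for par in parameters:
        if par not in records.columns:
            continue
        tt = unpaired_t(mal[par], ben[par], method)
        roc = roc_analysis(records[par].to_numpy(), y)
        rows.append({
            "parameter": par,
            "malignant_mean": tt.mean_a, "malignant_sd": tt.sd_a,
            "benign_mean": tt.mean_b, "benign_sd": tt.sd_b,
            "p": tt.p, "auc": roc.auc,
            "auc_ci_low": roc.ci_low, "auc_ci_high": roc.ci_high,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
        })
    table = pd.DataFrame(rows)
    if holm and not table.empty:
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        table["p_holm"] = adj
    return table
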