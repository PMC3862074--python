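"""Univariate screening, correlation pruning and discriminant risk models.

The statistics mirror a two-group (low-risk vs high-risk) observational
design: every index is screened with a two-tailed Mann-Whitney U-test
(exact enumeration for small tie-free samples, tie- and
continuity-corrected normal approximation otherwise) at p < 0.05 with a
stricter multiple-testing level of p < 0.01; significant indices are
pruned of Pearson-correlated redundancy (|r| > 0.7 against an already
retained, more significant index) and five-index parameter sets are
searched exhaustively under a composition constraint (clinical-only,
non-clinical-only, or 3+2 / 2+3 mixes).  Each set is scored by a linear
discriminant on standardized features (pooled covariance) whose scores
feed a ROC curve; SENS/SPEC/PPA are read at the maximal-Youden-J
operating point and reported in percent together with the trapezoid AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from statsmodels.stats.diagnostic import lilliefors

from .errors import HRVError, InfeasibleCompositionError

__all__ = [
    "ClassifierReport",
    "descriptive_stats",
    "normality_test",
    "mann_whitney_u",
    "screen",
    "pearson_prune",
    "lda_roc",
    "optimal_set_search",
    "CLINICAL_INDICES",
]

#: Clinical covariates as used in the discriminant sets.
CLINICAL_INDICES = ("BMI", "LVEF", "LVDD", "LVSD", "NT-proBNP", "NYHA")

GROUP_LOW = "IHF_LR"
GROUP_HIGH = "IHF_HR"


@dataclass
class ClassifierReport:
    index_set: tuple
    composition: str  # clinical | nonclinical | mixed1 | mixed2
    sens_pct: float
    spec_pct: float
    auc_pct: float
    ppa_pct: float
    threshold: float = float("nan")
    n_evaluated: int = 1
    scores: Optional[np.ndarray] = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "composition": self.composition,
            "indices": list(self.index_set),
            "SENS": self.sens_pct,
            "SPEC": self.spec_pct,
            "AUC": self.auc_pct,
            "PPA": self.ppa_pct,
        }


def descriptive_stats(values: Sequence[float]) -> dict:
    """Median, quartiles (linear interpolation), mean and sample sd."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise HRVError("descriptive stats of an empty group")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }


def normality_test(values: Sequence[float]) -> float:
    """Lilliefors-corrected one-sample KS test against a fitted normal.

    Returns the p-value; a degenerate (constant) sample is reported as
    maximally non-normal (p = 0).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise HRVError("normality test needs n >= 5")
    if np.ptp(v) == 0:
        return 0.0
    _, p = lilliefors(v, dist="norm")
    return float(p)


def mann_whitney_u(x, y, mode: str = "auto") -> dict:
    """Two-tailed Mann-Whitney U-test.

    ``exact`` enumerates the permutation distribution, ``asymptotic``
    uses the tie-corrected normal approximation with continuity
    correction; ``auto`` picks exact for tie-free samples with
    min(n) <= 25.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise HRVError("Mann-Whitney test needs two non-empty samples")
    if mode == "auto":
        ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        mode = "exact" if (min(x.size, y.size) <= 25 and not ties) else "asymptotic"
    method = {"exact": "exact", "asymptotic": "asymptotic"}[mode]
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return {"U": float(res.statistic), "p_two_tailed": float(res.pvalue)}


def screen(
    cohort: pd.DataFrame,
    feature_cols: Sequence[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Univariate group comparison of every index.

    Returns one row per index with group descriptives, the two-tailed
    U-test p-value and significance flags at 0.05 and the stricter 0.01
    multiple-testing level.  Indices that are constant overall or have
    missing values in a group get p = NaN.
    """
    lr = cohort[cohort[group_col] == GROUP_LOW]
    hr = cohort[cohort[group_col] == GROUP_HIGH]
    rows = []
    for col in feature_cols:
        a = lr[col].dropna().to_numpy(dtype=float)
        b = hr[col].dropna().to_numpy(dtype=float)
        row = {"index": col}
        if a.size and b.size:
            for tag, v in (("lr", a), ("hr", b)):
                d = descriptive_stats(v)
                row.update({f"{tag}_{k}": val for k, val in d.items()})
            if np.ptp(np.concatenate([a, b])) == 0:
                row["p"] = np.nan
            else:
                row["p"] = mann_whitney_u(a, b)["p_two_tailed"]
        else:
            row["p"] = np.nan
        p = row["p"]
        row["sig05"] = bool(p < 0.05) if np.isfinite(p) else False
        row["sig01"] = bool(p < 0.01) if np.isfinite(p) else False
        rows.append(row)
    return pd.DataFrame(rows).set_index("index")


def pearson_prune(
    features: pd.DataFrame,
    candidates: Sequence[str],
    r_threshold: float = 0.7,
    p_values: Optional[dict] = None,
) -> list[str]:
    """Greedy removal of Pearson-redundant candidates.

    Candidates are visited in ascending-p order (or the given order when
    ``p_values`` is None); a candidate correlated with |r| above the
    threshold to an already retained index is dropped.
    """
    order = list(candidates)
    if p_values is not None:
        order = sorted(order, key=lambda c: (p_values[c], c))
    retained: list[str] = []
    for cand in order:
        x = features[cand].to_numpy(dtype=float)
        ok = True
        for kept in retained:
            y = features[kept].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                continue
            r = np.corrcoef(x[mask], y[mask])[0, 1]
            if abs(r) > r_threshold:
                ok = False
                break
        if ok:
            retained.append(cand)
    return retained


def _lda_scores(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Discriminant scores from a pooled-covariance linear discriminant.

    Features are standardized; the direction is S_pooled^-1 (mu1 - mu0)
    with a small ridge added when the pooled covariance is singular.
    Higher scores point toward the positive (high-risk) class.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    X0, X1 = Xs[y == 0], Xs[y == 1]
    n0, n1 = len(X0), len(X1)
    S = ((n0 - 1) * np.cov(X0, rowvar=False, ddof=1)
         + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1)) / (n0 + n1 - 2)
    S = np.atleast_2d(S)
    diff = X1.mean(axis=0) - X0.mean(axis=0)
    try:
        w = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; ridge-regularized", stacklevel=2)
        w = np.linalg.solve(S + ridge * np.eye(S.shape[0]), diff)
    return Xs @ w


def lda_roc(
    cohort: pd.DataFrame,
    index_set: Sequence[str],
    composition: str = "custom",
    group_col: str = "group",
) -> ClassifierReport:
    """Fit a linear discriminant on an index set and report ROC metrics.

    The operating point is the ROC threshold maximizing Youden's
    J = SENS + SPEC - 1; SENS, SPEC, PPA (= TP/(TP+FP)) and the
    trapezoid AUC are reported in percent.
    """
    cols = list(index_set)
    sub = cohort[cols + [group_col]].dropna()
    y = (sub[group_col] == GROUP_HIGH).to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise HRVError("both groups must be present for classification")
    scores = _lda_scores(sub[cols].to_numpy(dtype=float), y)
    fpr, tpr, thr = roc_curve(y, scores)
    auc_frac = _trapezoid_auc(fpr, tpr)
    j = tpr - fpr
    k = int(np.argmax(j))
    sens = tpr[k]
    spec = 1.0 - fpr[k]
    pred = scores >= thr[k]
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    ppa = tp / (tp + fp) if (tp + fp) else 0.0
    return ClassifierReport(
        index_set=tuple(cols),
        composition=composition,
        sens_pct=100.0 * sens,
        spec_pct=100.0 * spec,
        auc_pct=100.0 * auc_frac,
        ppa_pct=100.0 * ppa,
        threshold=float(thr[k]),
        scores=scores,
    )


#: (n clinical, n non-clinical) for each five-index composition class.
COMPOSITIONS = {
    "clinical": (5, 0),
    "nonclinical": (0, 5),
    "mixed1": (3, 2),
    "mixed2": (2, 3),
}


def optimal_set_search(
    cohort: pd.DataFrame,
    clinical_pool: Sequence[str],
    nonclinical_pool: Sequence[str],
    composition: str,
    group_col: str = "group",
) -> ClassifierReport:
    """Exhaustive search for the best five-index set of a composition.

    Every admissible combination is scored by :func:`lda_roc`; the
    maximum-AUC set wins, with ties broken by higher SENS and then by
    lexicographic index names, so the result does not depend on the
    candidate ordering.
    """
    n_clin, n_non = COMPOSITIONS[composition]
    if len(clinical_pool) < n_clin or len(nonclinical_pool) < n_non:
        raise InfeasibleCompositionError(
            f"{composition} needs {n_clin} clinical + {n_non} non-clinical "
            f"candidates; have {len(clinical_pool)} + {len(nonclinical_pool)}"
        )
    best: Optional[ClassifierReport] = None
    best_key: tuple = ()
    n_eval = 0
    # pools sorted and itertools.combinations emits sets in lexicographic
    # order, so strict improvement keeps the lexicographically smallest
    # winner on metric ties -> result independent of candidate ordering
    for clin in combinations(sorted(clinical_pool), n_clin):
        for non in combinations(sorted(nonclinical_pool), n_non):
            idx_set = clin + non
            rep = lda_roc(cohort, idx_set, composition, group_col)
            rep.scores = None
            n_eval += 1
            key = (round(rep.auc_pct, 10), round(rep.sens_pct, 10))
            if best is None or key > best_key:
                best, best_key = rep, key
    best.n_evaluated = n_eval
    return best
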